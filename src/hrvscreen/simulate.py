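"""Synthetic RR-interval cohorts under the rest/task/rest paradigm.

Each simulated heart produces beats recursively — the next beat falls one
current RR interval after the previous one — where the instantaneous RR is
a state-dependent mean plus two sinusoidal modulations (a 0.1 Hz
low-frequency oscillation and a respiratory-band oscillation) plus white
Gaussian noise:

    RR(t) = mean_rr(state) + lf_amp(state) sin(2 pi 0.1 t + phi1)
                           + hf_amp(state) sin(2 pi f_resp t + phi2) + eps

A sinusoidal modulation of amplitude A ms therefore contributes a band
power of A**2/2 ms^2, giving closed-form truth for every pipeline stage.

Autonomic *reactivity* is the change of mean RR and modulation amplitudes
across states.  A subject's ``blunting`` in [0, 1] shrinks all state
deviations from the pre-task baseline: 0 reproduces the full healthy
response (heart rate and LF/HF up, HF down during the task), 1 removes the
response entirely — the pattern reported for depressed patients.  Cohort
generation draws per-subject parameters from group distributions (healthy
reactive, depressed blunted with a sympathetically shifted baseline) and
attaches a self-rating depression scale (SDS) score tied to blunting, so
the simulated severity correlates with the screening logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import ProtocolSchedule, RRSeries, default_schedule

__all__ = [
    "StateProfile",
    "SubjectParams",
    "GroupDistribution",
    "CohortConfig",
    "SimulatedSubject",
    "simulate_rr",
    "simulate_cohort",
]

LF_FREQ = 0.1  # Hz, fixed low-frequency (Mayer-wave) modulation


@dataclass
class StateProfile:
    """One value per experimental state, keyed rest_before/task/rest_after."""

    rest_before: float
    task: float
    rest_after: float

    def get(self, state: str) -> float:
        return getattr(self, state)


@dataclass
class SubjectParams:
    """Generative parameters for one subject.

    mean_rr : state-wise mean RR (ms), in [400, 1500].
    lf_amp, hf_amp : state-wise modulation amplitudes (ms), each below
        mean_rr/4 so intervals stay positive.
    resp_freq : respiratory modulation frequency (Hz), within the HF band.
    noise_sd : white-noise standard deviation on RR (ms).
    blunting : in [0, 1]; shrinks task/recovery deviations from baseline.
    """

    mean_rr: StateProfile
    lf_amp: StateProfile
    hf_amp: StateProfile
    resp_freq: float = 0.25
    noise_sd: float = 8.0
    blunting: float = 0.0

    def __post_init__(self):
        for state in ("rest_before", "task", "rest_after"):
            m = self.mean_rr.get(state)
            if not 400 <= m <= 1500:
                raise ValueError(f"mean_rr[{state}] = {m} outside [400, 1500] ms")
            for prof, nm in ((self.lf_amp, "lf_amp"), (self.hf_amp, "hf_amp")):
                a = prof.get(state)
                if a < 0:
                    raise ValueError(f"{nm}[{state}] must be >= 0")
                if a >= m / 4:
                    raise ValueError(f"{nm}[{state}] = {a} too large vs mean_rr {m}")
        if not 0.2 <= self.resp_freq <= 0.35:
            raise ValueError("resp_freq must lie in [0.2, 0.35] Hz")
        if not 0.0 <= self.blunting <= 1.0:
            raise ValueError("blunting must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def effective(self, which: str, state: str) -> float:
        """State value after blunting shrinks the deviation from baseline."""
        prof: StateProfile = getattr(self, which)
        base = prof.get("rest_before")
        return base + (1.0 - self.blunting) * (prof.get(state) - base)


def simulate_rr(
    params: SubjectParams,
    schedule: ProtocolSchedule | None = None,
    seed: int | np.random.Generator | None = None,
) -> RRSeries:
    """Generate one RR recording over the schedule; deterministic per seed."""
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi1, phi2 = rng.uniform(0.0, 2 * np.pi, size=2)

    times = []
    t = schedule.start
    end = schedule.end
    while t < end:
        times.append(t)
        state = schedule.state_at(t).name
        rr = (
            params.effective("mean_rr", state)
            + params.effective("lf_amp", state) * np.sin(2 * np.pi * LF_FREQ * t + phi1)
            + params.effective("hf_amp", state)
            * np.sin(2 * np.pi * params.resp_freq * t + phi2)
            + rng.normal(0.0, params.noise_sd)
        )
        if rr <= 0:
            raise ValueError("parameters produced a non-positive RR interval")
        t += rr / 1000.0
    times.append(t)  # final beat closes the last interval
    times = np.asarray(times)
    return RRSeries(beat_times=times, intervals=np.diff(times) * 1000.0)


@dataclass
class GroupDistribution:
    """Group-level means and dispersions from which subjects are drawn.

    ``*_mean``/``*_sd`` describe the baseline (pre-task) lognormal-free
    Gaussian draws, truncated to valid ranges.  ``task_*_factor`` set the
    fully-reactive task response; recovery returns to baseline.  Blunting
    is drawn uniformly on ``blunting_range``.
    """

    mean_rr_mean: float = 900.0
    mean_rr_sd: float = 90.0
    hf_amp_mean: float = 33.0
    hf_amp_sd: float = 10.0
    lf_amp_mean: float = 22.0
    lf_amp_sd: float = 6.0
    task_rr_factor: float = 0.88  # heart rate rises ~14% during the task
    task_hf_factor: float = 0.5   # vagal withdrawal halves HF modulation
    task_lf_factor: float = 1.5   # sympathetic activation boosts LF
    reactivity_jitter: float = 0.09  # per-subject spread of the task factors
    blunting_range: tuple[float, float] = (0.0, 0.7)
    noise_sd: float = 8.0

    def draw(self, rng: np.random.Generator) -> SubjectParams:
        rr0 = float(np.clip(rng.normal(self.mean_rr_mean, self.mean_rr_sd), 500, 1400))
        hf0 = float(np.clip(rng.normal(self.hf_amp_mean, self.hf_amp_sd), 5.0, rr0 / 5))
        lf0 = float(np.clip(rng.normal(self.lf_amp_mean, self.lf_amp_sd), 3.0, rr0 / 5))
        jit = lambda f: float(np.clip(f + rng.normal(0, self.reactivity_jitter), 0.1, 3.0))
        return SubjectParams(
            mean_rr=StateProfile(rr0, rr0 * jit(self.task_rr_factor), rr0 * 0.99),
            hf_amp=StateProfile(hf0, hf0 * jit(self.task_hf_factor), hf0 * 0.95),
            lf_amp=StateProfile(lf0, lf0 * jit(self.task_lf_factor), lf0 * 1.05),
            resp_freq=float(rng.uniform(0.2, 0.35)),
            noise_sd=self.noise_sd,
            blunting=float(rng.uniform(*self.blunting_range)),
        )


def _default_mdd_group() -> GroupDistribution:
    # Baseline shifted toward sympathetic dominance (faster heart rate,
    # weaker respiratory modulation) and strongly blunted reactivity.
    return GroupDistribution(
        mean_rr_mean=865.0,
        hf_amp_mean=29.0,
        lf_amp_mean=23.0,
        blunting_range=(0.3, 1.0),
    )


@dataclass
class CohortConfig:
    """Cohort recipe: group sizes, group distributions, SDS model, seed.

    Defaults mirror the study design this simulator emulates: 44 depressed
    and 47 healthy subjects.  SDS scores follow 35 + 25*severity + noise
    for the depressed group (severity = blunting) and centre on 40 for
    healthy subjects, clipped to the 20-80 scale.
    """

    n_mdd: int = 44
    n_healthy: int = 47
    mdd: GroupDistribution = field(default_factory=_default_mdd_group)
    healthy: GroupDistribution = field(default_factory=GroupDistribution)
    sds_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mdd < 1 or self.n_healthy < 1:
            raise ValueError("group sizes must be positive")


@dataclass
class SimulatedSubject:
    id: str
    diagnosis: str
    sds: int
    params: SubjectParams
    rr: RRSeries


def simulate_cohort(
    config: CohortConfig | None = None,
    schedule: ProtocolSchedule | None = None,
) -> list[SimulatedSubject]:
    """Draw a full cohort of RR recordings with diagnoses and SDS scores."""
    cfg = config or CohortConfig()
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(cfg.seed)
    subjects: list[SimulatedSubject] = []
    plan = [("MDD", cfg.mdd, cfg.n_mdd), ("healthy", cfg.healthy, cfg.n_healthy)]
    for diagnosis, group, count in plan:
        for i in range(count):
            params = group.draw(rng)
            rr = simulate_rr(params, schedule, seed=rng)
            if diagnosis == "MDD":
                sds_raw = 35.0 + 25.0 * params.blunting + rng.normal(0, cfg.sds_noise_sd)
            else:
                sds_raw = 40.0 + rng.normal(0, cfg.sds_noise_sd)
            sds = int(np.clip(round(sds_raw), 20, 80))
            subjects.append(
                SimulatedSubject(
                    id=f"{'mdd' if diagnosis == 'MDD' else 'hc'}{i + 1:03d}",
                    diagnosis=diagnosis,
                    sds=sds,
                    params=params,
                    rr=rr,
                )
            )
    return subjects
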