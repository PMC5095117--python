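"""Map sliding HRV indices onto the rest/task/rest paradigm.

Each experimental state contributes three features — mean HR, mean HF power
and mean LF/HF — averaged over index samples whose timestamps fall in the
closed interval [onset + 30 s, onset + 60 s].  The 30-s lead-in skips the
settling of the sliding spectral window across the state transition, so
every averaged sample reflects the new state only.  The nine features feed
the logistic screening model in a fixed canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .signal_io import ProtocolSchedule, RRSeries
from .spectral import HRVIndexSeries, SpectralConfig, sliding_hrv

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "SubjectRecord",
    "StateCoverageError",
    "state_average",
    "extract_features",
    "read_feature_table",
    "write_feature_table",
]

#: Canonical feature order used everywhere (tables, model serialization).
FEATURE_NAMES = (
    "hr_before",
    "hr_task",
    "hr_after",
    "hf_before",
    "hf_task",
    "hf_after",
    "lfhf_before",
    "lfhf_task",
    "lfhf_after",
)

#: Averaging window relative to each state onset (closed interval, seconds).
AVERAGE_WINDOW = (30.0, 60.0)

_STATE_SUFFIX = {"rest_before": "before", "task": "task", "rest_after": "after"}


class StateCoverageError(ValueError):
    """An experimental state has no valid index samples to average."""


@dataclass
class FeatureVector:
    """The nine screening inputs: HR (bpm), HF (ms^2), LF/HF per state."""

    hr_before: float
    hr_task: float
    hr_after: float
    hf_before: float
    hf_task: float
    hf_after: float
    lfhf_before: float
    lfhf_task: float
    lfhf_after: float

    def __post_init__(self):
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"feature {name} must be finite, got {v}")
        for name in FEATURE_NAMES:
            if name.startswith(("hf", "lfhf")) and getattr(self, name) < 0:
                raise ValueError(f"feature {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_mapping(cls, mapping) -> "FeatureVector":
        return cls(**{n: float(mapping[n]) for n in FEATURE_NAMES})


@dataclass
class SubjectRecord:
    """One subject: identifier, diagnosis, optional SDS score, features."""

    id: str
    diagnosis: str  # "MDD", "healthy" or "unknown"
    features: FeatureVector
    sds: int | None = None

    def __post_init__(self):
        if self.diagnosis not in ("MDD", "healthy", "unknown"):
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.sds is not None and not (20 <= self.sds <= 80):
            raise ValueError(f"SDS score {self.sds} outside scale range 20-80")


def state_average(
    series: HRVIndexSeries, schedule: ProtocolSchedule
) -> FeatureVector:
    """Average valid index samples in [onset+30, onset+60] per state."""
    eps = 1e-9
    values: dict[str, float] = {}
    for state in schedule.states:
        suffix = _STATE_SUFFIX.get(state.name)
        if suffix is None:
            raise ValueError(f"unexpected state name {state.name!r}")
        lo = state.onset + AVERAGE_WINDOW[0]
        hi = state.onset + AVERAGE_WINDOW[1]
        mask = (
            series.valid
            & (series.timestamps >= lo - eps)
            & (series.timestamps <= hi + eps)
        )
        if not np.any(mask):
            raise StateCoverageError(
                f"insufficient data for state {state.name!r}: "
                f"no valid samples in [{lo:g}, {hi:g}] s"
            )
        values[f"hr_{suffix}"] = float(np.mean(series.hr[mask]))
        values[f"hf_{suffix}"] = float(np.mean(series.hf[mask]))
        values[f"lfhf_{suffix}"] = float(np.mean(series.lfhf[mask]))
    return FeatureVector.from_mapping(values)


def extract_features(
    rr: RRSeries,
    schedule: ProtocolSchedule | None = None,
    config: SpectralConfig | None = None,
) -> FeatureVector:
    """Full pipeline: sliding HRV indices, then per-state averaging.

    The recording must cover the schedule (to within one index step);
    deterministic for a fixed configuration.
    """
    from .signal_io import default_schedule

    schedule = schedule or default_schedule()
    cfg = config or SpectralConfig()
    if rr.beat_times[0] > schedule.start + 1e-9:
        raise ValueError("recording starts after the schedule onset")
    if rr.beat_times[-1] < schedule.end - cfg.step_s:
        raise ValueError(
            f"recording ends at {rr.beat_times[-1]:.1f} s but the schedule "
            f"runs to {schedule.end:g} s (incomplete {schedule.states[-1].name})"
        )
    return state_average(sliding_hrv(rr, cfg), schedule)


# ---------------------------------------------------------------------------
# Feature tables: id, diagnosis, sds, then the nine canonical columns.


def write_feature_table(records: list[SubjectRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"id": rec.id, "diagnosis": rec.diagnosis, "sds": rec.sds}
        row.update(dict(zip(FEATURE_NAMES, rec.features.as_array())))
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "diagnosis", "sds", *FEATURE_NAMES]).to_csv(
        path, index=False
    )


def read_feature_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = {"id", "diagnosis", *FEATURE_NAMES} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sds = row.get("sds")
        sds = None if sds is None or pd.isna(sds) else int(sds)
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                diagnosis=str(row["diagnosis"]),
                sds=sds,
                features=FeatureVector.from_mapping(row),
            )
        )
    return records
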