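"""Maximum-entropy (Burg autoregressive) spectral analysis of the RR tachogram.

The RR tachogram is resampled to an even grid by cubic-spline interpolation,
an autoregressive model is fitted by the Burg recursion (the maximum-entropy
spectral estimator), and band powers are integrated from the resulting AR
power spectral density.  A sliding 30-s window stepped every 2 s yields the
HF, LF, LF/HF and heart-rate index traces that the screening paradigm
averages per experimental state.

Spectra are one-sided: integrating the density over [0, Nyquist] recovers
the variance of the (mean-removed) tachogram, so a sinusoidal RR modulation
of amplitude A ms contributes a band power of A**2/2 ms**2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .signal_io import RRSeries

__all__ = [
    "EvenlySampledSeries",
    "ARModel",
    "PowerSpectrum",
    "Band",
    "LF_BAND",
    "HF_BAND",
    "HRVIndexSeries",
    "SpectralConfig",
    "resample_tachogram",
    "fit_burg",
    "ar_psd",
    "band_power",
    "mean_hr",
    "sliding_hrv",
]

#: LF/HF band power below which LF/HF is treated as undefined.
HF_FLOOR_MS2 = 1e-12


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi] in Hz."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0 <= self.lo < self.hi):
            raise ValueError("band must satisfy 0 <= lo < hi")


#: Low-frequency band, indexing baroreflex/sympathovagal oscillations.
LF_BAND = Band(0.04, 0.15)
#: High-frequency (respiratory) band, indexing parasympathetic modulation.
HF_BAND = Band(0.15, 0.40)


@dataclass
class EvenlySampledSeries:
    """Mean-removed tachogram values (ms) on an even time grid."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0


@dataclass
class ARModel:
    """Autoregressive model with polynomial A(z) = 1 + a1 z^-1 + ... + ap z^-p.

    The driving noise has variance ``innovation_variance``; stability means
    all roots of A lie strictly inside the unit circle.
    """

    order: int
    coefficients: np.ndarray
    innovation_variance: float

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if self.order != self.coefficients.size:
            raise ValueError("order must equal number of coefficients")
        if self.innovation_variance < 0:
            raise ValueError("innovation_variance must be >= 0")

    def is_stable(self) -> bool:
        if self.order == 0:
            return True
        roots = np.roots(np.concatenate(([1.0], self.coefficients)))
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class PowerSpectrum:
    """One-sided PSD (ms^2/Hz) on an ascending grid over [0, Nyquist]."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies.shape != self.density.shape:
            raise ValueError("frequency and density grids must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be ascending")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.density, self.frequencies))


@dataclass
class HRVIndexSeries:
    """Sliding-window HRV indices, one row every ``step`` seconds.

    ``timestamps`` are window right-edges; each row holds the HF and LF band
    powers (ms^2), their ratio, and the mean heart rate (bpm) of the 30-s
    window ending at that time.  ``valid`` marks windows that met the
    beat-count/artifact criteria and had defined LF/HF.
    """

    timestamps: np.ndarray
    hf: np.ndarray
    lf: np.ndarray
    lfhf: np.ndarray
    hr: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.timestamps,
                "hf_ms2": self.hf,
                "lf_ms2": self.lf,
                "lfhf": self.lfhf,
                "hr_bpm": self.hr,
                "valid": self.valid,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HRVIndexSeries":
        return cls(
            timestamps=df["t_s"].to_numpy(float),
            hf=df["hf_ms2"].to_numpy(float),
            lf=df["lf_ms2"].to_numpy(float),
            lfhf=df["lfhf"].to_numpy(float),
            hr=df["hr_bpm"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
        )


@dataclass
class SpectralConfig:
    """Knobs of the tachogram -> index pipeline.

    resample_rate : Hz of the even tachogram grid (4 Hz is conventional).
    ar_order      : AR order; None selects min(floor(N/10), 12) per window.
    window_s      : spectral window length (s).
    step_s        : index step (s).
    grid_step     : PSD frequency grid resolution (Hz).
    """

    resample_rate: float = 4.0
    ar_order: int | None = None
    window_s: float = 30.0
    step_s: float = 2.0
    grid_step: float = 0.001


def _tachogram_spline(rr: RRSeries) -> CubicSpline:
    # RR(t): each interval attached to the beat that starts it
    return CubicSpline(rr.beat_times[:-1], rr.intervals)


def resample_tachogram(
    rr: RRSeries, window: tuple[float, float], rate: float = 4.0
) -> EvenlySampledSeries:
    """Cubic-spline resample RR(t) on an even grid over ``window``, mean-removed.

    The output has ``floor((end-start)*rate) + 1`` samples.  Requires at
    least 4 beats inside the window and the window inside the recording.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    eps = 1e-9
    if start < rr.beat_times[0] - eps or end > rr.beat_times[-1] + eps:
        raise ValueError("window outside recording")
    n_in = int(np.count_nonzero((rr.beat_times >= start - eps) & (rr.beat_times <= end + eps)))
    if n_in < 4:
        raise ValueError(f"too few beats in window: {n_in} < 4")
    n = int(np.floor((end - start) * rate)) + 1
    grid = start + np.arange(n) / rate
    values = _tachogram_spline(rr)(grid)
    values = values - values.mean()
    return EvenlySampledSeries(values=values, rate=rate, t0=start)


def fit_burg(series: EvenlySampledSeries | np.ndarray, order: int) -> ARModel:
    """Fit an AR(order) model by the Burg (maximum-entropy) recursion.

    Minimizes the summed forward and backward prediction error at each
    stage; all reflection coefficients satisfy |k| < 1 so the model is
    stable by construction.
    """
    x = series.values if isinstance(series, EvenlySampledSeries) else np.asarray(series, float)
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n:
        raise ValueError(f"order {order} must be < series length {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance input")

    a = np.zeros(0)
    e = float(x @ x) / n
    f = x[1:].astype(float)  # forward prediction errors
    b = x[:-1].astype(float)  # backward prediction errors
    for _ in range(order):
        den = f @ f + b @ b
        if den <= 0:
            a = np.concatenate([a, np.zeros(order - a.size)])
            break
        k = -2.0 * (f @ b) / den
        a = np.concatenate([a + k * a[::-1], [k]])
        e *= 1.0 - k * k
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return ARModel(order=order, coefficients=a, innovation_variance=max(e, 0.0))


def ar_psd(model: ARModel, rate: float, grid_step: float = 0.001) -> PowerSpectrum:
    """One-sided AR power spectral density on [0, Nyquist].

    density(f) = 2 * sigma^2 * dt / |1 + sum_k a_k exp(-2 pi i f k dt)|^2.
    """
    if not model.is_stable():
        raise ValueError("unstable AR model")
    dt = 1.0 / rate
    nyq = rate / 2.0
    freqs = np.arange(0.0, nyq + grid_step / 2.0, grid_step)
    if model.order == 0:
        density = np.full_like(freqs, 2.0 * model.innovation_variance * dt)
        return PowerSpectrum(frequencies=freqs, density=density)

    # refine the grid around each pole so that very narrow spectral lines
    # (pole radius close to 1) are still integrated accurately
    roots = np.roots(np.concatenate(([1.0], model.coefficients)))
    extra = []
    for root in roots:
        if root.imag < -1e-12:
            continue  # conjugate pair handled by its upper-half twin
        f_pole = abs(np.angle(root)) / (2 * np.pi) * rate
        hw = max((1.0 - np.abs(root)) * rate / (2 * np.pi), 1e-9)
        extra.append(f_pole + hw * np.tan(np.linspace(-1.47, 1.47, 81)))
    cand = np.concatenate(extra)
    cand = cand[(cand > 0.0) & (cand < nyq)]
    freqs = np.unique(np.concatenate([freqs, cand]))

    k = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) * dt)  # (n_freq, order)
    denom = np.abs(1.0 + phase @ model.coefficients) ** 2
    density = 2.0 * model.innovation_variance * dt / denom
    return PowerSpectrum(frequencies=freqs, density=density)


def band_power(spectrum: PowerSpectrum, band: Band) -> float:
    """Trapezoidal integral of the density over [band.lo, band.hi] (ms^2)."""
    f, d = spectrum.frequencies, spectrum.density
    if band.lo < f[0] - 1e-12 or band.hi > f[-1] + 1e-12:
        raise ValueError("band outside spectrum grid")
    inner = (f > band.lo) & (f < band.hi)
    fs = np.concatenate(([band.lo], f[inner], [band.hi]))
    ds = np.concatenate(
        ([np.interp(band.lo, f, d)], d[inner], [np.interp(band.hi, f, d)])
    )
    return float(np.trapezoid(ds, fs))


def mean_hr(rr: RRSeries, window: tuple[float, float]) -> float:
    """Mean heart rate (bpm) as 60000 / mean RR over intervals fully inside."""
    start, end = window
    eps = 1e-9
    inside = (rr.beat_times[:-1] >= start - eps) & (rr.beat_times[1:] <= end + eps)
    if np.count_nonzero(inside) < 1 or np.count_nonzero(
        (rr.beat_times >= start - eps) & (rr.beat_times <= end + eps)
    ) < 2:
        raise ValueError("too few beats in window for heart rate")
    return 60000.0 / float(np.mean(rr.intervals[inside]))


def _default_order(n: int) -> int:
    # ~N/10 capped at 12: enough poles for two spectral lines plus noise
    # floor on a 121-sample window, without the variance blow-up of high
    # orders on short windows
    return max(4, min(n // 10, 12))


def sliding_hrv(rr: RRSeries, config: SpectralConfig | None = None) -> HRVIndexSeries:
    """Compute HF/LF/LF-HF/HR every ``step_s`` over the preceding ``window_s``.

    Timestamps start at ``t0 + window_s`` (the first fully-filled window)
    and advance by ``step_s`` until the end of the recording.  A window is
    flagged invalid when it has fewer than 4 beats, contains an artifact
    interval, or its HF power is below the defined-ratio floor.
    """
    cfg = config or SpectralConfig()
    t0 = float(rr.beat_times[0])
    t_end = float(rr.beat_times[-1])
    if t_end - t0 < cfg.window_s:
        raise ValueError("recording shorter than one spectral window")

    spline = _tachogram_spline(rr)
    timestamps = np.arange(t0 + cfg.window_s, t_end + 1e-9, cfg.step_s)
    n_t = timestamps.size
    hf = np.full(n_t, np.nan)
    lf = np.full(n_t, np.nan)
    lfhf = np.full(n_t, np.nan)
    hr = np.full(n_t, np.nan)
    valid = np.zeros(n_t, dtype=bool)

    n_grid = int(np.floor(cfg.window_s * cfg.resample_rate)) + 1
    rel_grid = np.arange(n_grid) / cfg.resample_rate
    eps = 1e-9
    for i, t in enumerate(timestamps):
        start = t - cfg.window_s
        in_win = (rr.beat_times >= start - eps) & (rr.beat_times <= t + eps)
        if np.count_nonzero(in_win) < 4:
            continue
        iv_in = (rr.beat_times[:-1] >= start - eps) & (rr.beat_times[1:] <= t + eps)
        if np.any(rr.artifact_flags[iv_in]):
            continue
        values = spline(start + rel_grid)
        values = values - values.mean()
        if np.ptp(values) == 0:
            hf[i] = lf[i] = 0.0
            hr[i] = mean_hr(rr, (start, t))
            continue
        order = cfg.ar_order if cfg.ar_order is not None else _default_order(n_grid)
        model = fit_burg(values, order)
        spec = ar_psd(model, cfg.resample_rate, cfg.grid_step)
        lf[i] = band_power(spec, LF_BAND)
        hf[i] = band_power(spec, HF_BAND)
        hr[i] = mean_hr(rr, (start, t))
        if hf[i] > HF_FLOOR_MS2:
            lfhf[i] = lf[i] / hf[i]
            valid[i] = True
    return HRVIndexSeries(
        timestamps=timestamps, hf=hf, lf=lf, lfhf=lfhf, hr=hr, valid=valid
    )
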