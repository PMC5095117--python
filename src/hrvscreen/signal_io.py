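"""Heartbeat data containers and I/O.

Reads and writes R-R interval (RR) series, validates them, derives beats
from raw single-lead ECG, and applies conventional artifact cleaning.
Times are 0-based seconds from recording start; intervals are milliseconds.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ParseError",
    "SignalQualityError",
    "ECGRecord",
    "RRSeries",
    "ProtocolSchedule",
    "ProtocolState",
    "default_schedule",
    "read_rr",
    "write_rr",
    "detect_r_peaks",
    "clean_rr",
    "CleaningReport",
]

# Conventional HRV artifact limits: physiologic RR range and maximum
# fractional jump relative to the local median.
DEFAULT_ABS_RANGE_MS = (300.0, 2000.0)
DEFAULT_REL_JUMP = 0.2
MAX_CORRUPT_FRACTION = 0.5


class ParseError(ValueError):
    """Malformed heartbeat file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} at line {line}"
        super().__init__(message)


class SignalQualityError(ValueError):
    """Signal unusable: flat ECG, too-corrupted RR series, etc."""


@dataclass
class ECGRecord:
    """Raw single-lead ECG: sample amplitudes (mV) at a fixed rate."""

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("ECG record needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate


@dataclass
class RRSeries:
    """Beat times (s) with the R-R intervals (ms) between them.

    ``intervals[i] == (beat_times[i+1] - beat_times[i]) * 1000`` and every
    interval is strictly positive.  ``artifact_flags`` marks intervals that
    were identified (and replaced) as artifacts by :func:`clean_rr`.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    artifact_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.intervals.size, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.intervals.size != self.beat_times.size - 1:
            raise ValueError("need len(intervals) == len(beat_times) - 1")
        if self.artifact_flags.size != self.intervals.size:
            raise ValueError("artifact_flags must match intervals")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")
        recon = np.diff(self.beat_times) * 1000.0
        if not np.allclose(recon, self.intervals, rtol=1e-9, atol=1e-6):
            raise ValueError("intervals inconsistent with beat_times")

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0) -> "RRSeries":
        """Build a series from intervals alone, placing the first beat at t0."""
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0 + np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
        return cls(beat_times=beat_times, intervals=intervals_ms)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class ProtocolState:
    name: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class ProtocolSchedule:
    """Ordered, contiguous experimental states (rest / mental task / rest)."""

    states: list[ProtocolState]

    def __post_init__(self):
        if not self.states:
            raise ValueError("schedule needs at least one state")
        prev_end = None
        for st in self.states:
            if st.duration <= 0:
                raise ValueError(f"state {st.name!r} has non-positive duration")
            if prev_end is not None and not np.isclose(st.onset, prev_end):
                raise ValueError("states must be contiguous and non-overlapping")
            prev_end = st.end

    @property
    def start(self) -> float:
        return self.states[0].onset

    @property
    def end(self) -> float:
        return self.states[-1].end

    def state_at(self, t: float) -> ProtocolState:
        for st in self.states:
            if st.onset <= t < st.end:
                return st
        if np.isclose(t, self.end):
            return self.states[-1]
        raise ValueError(f"time {t} s outside schedule")

    def shifted(self, dt: float) -> "ProtocolSchedule":
        return ProtocolSchedule(
            [ProtocolState(s.name, s.onset + dt, s.duration) for s in self.states]
        )

    @classmethod
    def from_dict(cls, spec: dict) -> "ProtocolSchedule":
        states = [
            ProtocolState(name, float(v["onset"]), float(v["duration"]))
            for name, v in spec.items()
        ]
        states.sort(key=lambda s: s.onset)
        return cls(states)


def default_schedule() -> ProtocolSchedule:
    """100 s rest, 100 s mental task, 120 s rest (onsets 0/100/200 s)."""
    return ProtocolSchedule(
        [
            ProtocolState("rest_before", 0.0, 100.0),
            ProtocolState("task", 100.0, 100.0),
            ProtocolState("rest_after", 200.0, 120.0),
        ]
    )


# ---------------------------------------------------------------------------
# RR file I/O
#
# plain:     one interval in ms per line; '#' starts a comment
# delimited: header "time_s,rr_ms"; time_s is the beat time ending the interval


def _open_maybe(source, mode):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(os.fspath(source), mode), True


def read_rr(source, dialect: str = "plain") -> RRSeries:
    """Read an RR series from a file path or text stream."""
    if dialect not in ("plain", "delimited"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, close = _open_maybe(source, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    if dialect == "plain":
        intervals = []
        for ln, raw in enumerate(lines, start=1):
            text = raw.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                val = float(text)
            except ValueError:
                raise ParseError(f"non-numeric token {text!r}", ln) from None
            if val <= 0:
                raise ParseError("non-positive interval", ln)
            intervals.append(val)
        if not intervals:
            raise ParseError("no RR intervals found")
        return RRSeries.from_intervals(intervals)

    # delimited
    data_lines = [(ln, raw) for ln, raw in enumerate(lines, start=1) if raw.strip()]
    if not data_lines:
        raise ParseError("empty delimited file")
    header_ln, header = data_lines[0]
    cols = [c.strip() for c in header.split(",")]
    if cols != ["time_s", "rr_ms"]:
        raise ParseError("expected header 'time_s,rr_ms'", header_ln)
    times, intervals = [], []
    for ln, raw in data_lines[1:]:
        parts = [p.strip() for p in raw.split(",")]
        if len(parts) != 2:
            raise ParseError(f"expected 2 columns, got {len(parts)}", ln)
        try:
            t, rr = float(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(f"non-numeric token in {raw!r}", ln) from None
        if rr <= 0:
            raise ParseError("non-positive interval", ln)
        if times and t <= times[-1]:
            raise ParseError("non-monotonic beat time", ln)
        times.append(t)
        intervals.append(rr)
    if not intervals:
        raise ParseError("no RR intervals found")
    beat_times = np.concatenate(([times[0] - intervals[0] / 1000.0], times))
    return RRSeries(beat_times=beat_times, intervals=np.asarray(intervals))


def write_rr(rr: RRSeries, sink, dialect: str = "plain") -> None:
    """Write an RR series so that :func:`read_rr` reproduces it exactly."""
    if dialect not in ("plain", "delimited"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, close = _open_maybe(sink, "w")
    try:
        if dialect == "plain":
            for v in rr.intervals:
                fh.write(f"{float(v)!r}\n")
        else:
            fh.write("time_s,rr_ms\n")
            for t, v in zip(rr.beat_times[1:], rr.intervals):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# R-peak detection (derivative + adaptive threshold, Pan-Tompkins style)


def detect_r_peaks(ecg: ECGRecord, min_rr_ms: float = 300.0) -> RRSeries:
    """Detect R peaks in a single-lead ECG and return the beat series.

    Band-pass filter (5-30 Hz), differentiate, square, and integrate over a
    short moving window; candidate beats are local maxima of the integrated
    energy above an adaptive threshold, refined to the local maximum of the
    raw signal, with a refractory period of ``min_rr_ms``.
    """
    fs = ecg.sampling_rate
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz too low (need >= 100 Hz)")
    x = ecg.samples - np.mean(ecg.samples)
    if np.max(np.abs(x)) < 1e-12 or np.std(x) < 1e-12:
        raise SignalQualityError("no peaks detected: flat signal")

    hi = min(30.0, 0.45 * fs)
    sos = _sig.butter(2, [5.0, hi], btype="bandpass", fs=fs, output="sos")
    filt = _sig.sosfiltfilt(sos, x)
    energy = np.convolve(
        np.square(np.gradient(filt)), np.ones(max(1, int(0.08 * fs))), mode="same"
    )

    min_dist = max(1, int(round(min_rr_ms / 1000.0 * fs)))
    height = 0.2 * np.max(energy)
    locs, _ = _sig.find_peaks(energy, height=height, distance=min_dist)
    if locs.size < 2:
        raise SignalQualityError("no peaks detected")

    # refine each candidate to the raw-signal local maximum (R apex)
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for loc in locs:
        lo, hi_i = max(0, loc - half), min(x.size, loc + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi_i])))
    refined = np.unique(refined)

    # enforce refractory period on the refined beat times
    kept = [refined[0]]
    for idx in refined[1:]:
        if (idx - kept[-1]) / fs * 1000.0 >= min_rr_ms:
            kept.append(idx)
    kept = np.asarray(kept)
    if kept.size < 2:
        raise SignalQualityError("no peaks detected")
    beat_times = ecg.t0 + kept / fs
    intervals = np.diff(beat_times) * 1000.0
    return RRSeries(beat_times=beat_times, intervals=intervals)


# ---------------------------------------------------------------------------
# Artifact cleaning


@dataclass
class CleaningReport:
    n_intervals: int
    n_flagged: int

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_intervals if self.n_intervals else 0.0


def _local_median(values: np.ndarray, i: int, exclude: np.ndarray) -> float:
    """Median of the nearest usable neighbours of index i (window of 5)."""
    n = values.size
    lo, hi = max(0, i - 2), min(n, i + 3)
    window = [j for j in range(lo, hi) if j != i and not exclude[j]]
    if not window:
        usable = values[~exclude]
        return float(np.median(usable)) if usable.size else float(values[i])
    return float(np.median(values[window]))


def clean_rr(
    rr: RRSeries,
    abs_range_ms: tuple[float, float] = DEFAULT_ABS_RANGE_MS,
    rel_jump: float = DEFAULT_REL_JUMP,
) -> tuple[RRSeries, CleaningReport]:
    """Flag and repair artifact intervals.

    An interval is an artifact when it falls outside ``abs_range_ms`` or
    deviates more than ``rel_jump`` (fractionally) from the median of its
    5-interval neighbourhood.  Flagged intervals are replaced by the local
    median of unflagged neighbours; beat times are rebuilt by cumulative sum.
    Raises :class:`SignalQualityError` when more than half are flagged.
    """
    x = rr.intervals.copy()
    n = x.size
    lo, hi = abs_range_ms
    flags = (x < lo) | (x > hi)
    med = np.empty(n)
    for i in range(n):
        w0, w1 = max(0, i - 2), min(n, i + 3)
        med[i] = np.median(x[w0:w1])
    with np.errstate(divide="ignore", invalid="ignore"):
        flags |= np.abs(x - med) / np.where(med > 0, med, np.inf) > rel_jump

    if n and flags.sum() / n > MAX_CORRUPT_FRACTION:
        raise SignalQualityError(
            f"signal too corrupted: {flags.sum()}/{n} intervals flagged"
        )

    repaired = x.copy()
    for i in np.flatnonzero(flags):
        repaired[i] = _local_median(x, i, flags)
    out = RRSeries.from_intervals(repaired, t0=float(rr.beat_times[0]))
    out.artifact_flags = flags.copy()
    return out, CleaningReport(n_intervals=n, n_flagged=int(flags.sum()))
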