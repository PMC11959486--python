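"""Miniature EJP trace QC, event detection and summary statistics.

A recording passes quality control only if its resting membrane potential
is at or below a cutoff (−60 mV by default, inclusive).  Event detection
is a documented threshold-above-local-baseline surrogate for the
proprietary detector used interactively in the field: the baseline is a
blockwise robust (10th-percentile) estimate interpolated back to the
sample grid, candidate events are upward excursions exceeding the
threshold above that baseline, amplitudes are peak minus local baseline,
and peaks closer than a refractory interval (``tau_hint``) are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "MejpTrace",
    "EventList",
    "QCResult",
    "qc_trace",
    "detect_mejps",
    "mejp_summary",
    "amplitude_distribution",
    "read_trace_csv",
]

#: fraction of the voltage distribution used as the resting-potential
#: estimate; robust to (depolarizing) events, deterministic.
RMP_QUANTILE = 0.10


@dataclass
class MejpTrace:
    """Uniformly sampled intracellular voltage trace.

    ``resting_potential`` is estimated at construction as the 10th
    percentile of the voltage unless supplied explicitly.
    """

    time: np.ndarray  # s
    voltage: np.ndarray  # mV
    sampling_rate: float  # Hz
    resting_potential: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be matching 1D arrays")
        if len(self.time) < 2:
            raise ValueError("trace must contain at least two samples")
        if not np.isfinite(self.voltage).all():
            raise ValueError("voltages must be finite")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace must be uniformly sampled")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.resting_potential is None:
            self.resting_potential = float(np.quantile(self.voltage, RMP_QUANTILE))

    @property
    def duration(self) -> float:
        return len(self.time) / self.sampling_rate


@dataclass
class EventList:
    """Detected (or ground-truth) events: times and amplitudes."""

    times: np.ndarray  # s, strictly increasing
    amplitudes: np.ndarray  # mV, peak minus local baseline

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str
    resting_potential: float

    def __bool__(self) -> bool:
        return self.passed


def qc_trace(trace: MejpTrace, rmp_cutoff: float = -60.0) -> QCResult:
    """Pass iff the resting membrane potential is at or below the cutoff.

    The cutoff is inclusive: a trace resting exactly at −60 mV passes.
    """
    rmp = float(trace.resting_potential)
    if rmp <= rmp_cutoff:
        return QCResult(True, f"RMP {rmp:.2f} mV <= {rmp_cutoff:.2f} mV", rmp)
    return QCResult(False, f"RMP {rmp:.2f} mV above cutoff {rmp_cutoff:.2f} mV", rmp)


def _local_baseline(voltage: np.ndarray, sampling_rate: float, block_s: float = 0.25,
                    quantile: float = 0.10) -> np.ndarray:
    """Blockwise robust baseline, linearly interpolated to the sample grid."""
    n = len(voltage)
    block = max(1, int(round(block_s * sampling_rate)))
    n_blocks = max(1, n // block)
    centers, values = [], []
    for b in range(n_blocks):
        lo = b * block
        hi = n if b == n_blocks - 1 else lo + block
        centers.append(0.5 * (lo + hi))
        values.append(np.quantile(voltage[lo:hi], quantile))
    if len(values) == 1:
        return np.full(n, values[0])
    return np.interp(np.arange(n), centers, values)


def detect_mejps(
    trace: MejpTrace,
    threshold_mV: float,
    tau_hint: float = 0.040,
    *,
    smooth_s: float = 0.002,
    min_prominence_frac: float = 0.8,
) -> EventList:
    """Detect upward mEJP-like events above a local baseline.

    ``threshold_mV`` is the minimum height above the local baseline;
    peaks also need a prominence of ``min_prominence_frac × threshold``
    so that noise wiggles riding on an event's decay are not counted
    twice.  Peaks closer than a quarter of ``tau_hint`` are merged (the
    larger one is kept) — near-coincident events are therefore reported
    as one, a documented limitation.
    """
    if threshold_mV <= 0:
        raise ValueError("threshold must be positive")
    fs = trace.sampling_rate
    baseline = _local_baseline(trace.voltage, fs)
    d = trace.voltage - baseline
    win = max(1, int(round(smooth_s * fs)))
    if win > 1:
        d = np.convolve(d, np.ones(win) / win, mode="same")
    distance = max(1, int(round(0.25 * tau_hint * fs)))
    peaks, _ = scipy.signal.find_peaks(
        d,
        height=threshold_mV,
        distance=distance,
        prominence=min_prominence_frac * threshold_mV,
    )
    return EventList(times=trace.time[peaks], amplitudes=d[peaks])


def mejp_summary(events: EventList, duration: float) -> tuple[float, float]:
    """Frequency (Hz) and mean amplitude (mV) of an event list."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    freq = len(events) / duration
    mean_amp = float(np.mean(events.amplitudes)) if len(events) else float("nan")
    return freq, mean_amp


def amplitude_distribution(
    events: EventList, bin_edges: np.ndarray, cut: float = 0.8
) -> tuple[np.ndarray, float]:
    """Fraction of events per amplitude bin, plus the fraction above a cut.

    The first/last bins absorb amplitudes below/above the outermost
    edges, so the fractions always sum to 1.  "Above the cut" is strict
    (amplitude > cut).
    """
    if len(events) == 0:
        raise ValueError("empty event list")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    amps = events.amplitudes
    idx = np.clip(np.searchsorted(edges, amps, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    fractions = counts / len(amps)
    frac_above = float(np.mean(amps > cut))
    return fractions, frac_above


def read_trace_csv(
    path: str | Path, sampling_rate: float | None = None
) -> MejpTrace:
    """Read a trace from CSV: two columns (time_s, voltage_mV) or a
    single voltage column plus an explicit sampling rate."""
    df = pd.read_csv(path)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t))) if sampling_rate is None else sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("single-column trace requires a sampling rate")
        v = df.iloc[:, 0].to_numpy(float)
        t = np.arange(len(v)) / sampling_rate
        fs = sampling_rate
    return MejpTrace(time=t, voltage=v, sampling_rate=fs)
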