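"""Event-related deep-brain activity (ER-DBA) index and dip analysis.

The DBA index is the occipital alpha-2 (10–13 Hz) power envelope: each
channel is band-passed with a zero-phase 3rd-order Butterworth filter,
squared, smoothed with a short moving average, and the O1/O2 power series
are then averaged.  Epoching the index around stimulus onset and baseline
correcting against the pre-stimulus window yields per-condition
event-related traces whose transient post-stimulus *dip* — depth and
latency — is read as the cognitive cost of the trial.

Notes on the numerics: the moving-average window is ``round(fs * 32.25 ms)``
samples (8 samples at 256 Hz, i.e. 31.25 ms — the nominal value is not an
integer number of samples at 256 Hz, so the rounded width is reported).
Filtering is forward–backward so dip latencies carry no filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .physio_io import (
    BASELINE_WINDOW_MS,
    Channel,
    Recording,
    baseline_correct,
    epoch_series,
    grand_average,
)

__all__ = [
    "ALPHA2_BAND_HZ",
    "DbaTrace",
    "DipMetrics",
    "dba_index",
    "delta_trace",
    "dip_metrics",
    "er_dba",
    "grand_average_traces",
]

ALPHA2_BAND_HZ = (10.0, 13.0)
SMOOTHING_WINDOW_MS = 32.25
DIP_SEARCH_WINDOW_MS = (0.0, 1000.0)


@dataclass
class DbaTrace:
    """Per-condition event-related DBA trace: mean power +- SEM over time."""

    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    condition: str
    baseline_power: float = float("nan")  # pre-onset raw power (for fractional depths)


@dataclass(frozen=True)
class DipMetrics:
    """Depth and latency of the post-onset minimum of a baseline-corrected trace."""

    depth: float
    latency_ms: float
    search_window_ms: tuple[float, float] = DIP_SEARCH_WINDOW_MS


def dba_index(recording: Recording, channels: tuple[str, str] = ("O1", "O2")) -> Channel:
    """Alpha-2 power index: band-pass, square, smooth, average the channels."""
    missing = [c for c in channels if c not in recording]
    if missing:
        raise KeyError(f"recording lacks channel(s) {missing}")
    chans = [recording.get(c) for c in channels]
    fs = chans[0].fs
    if any(c.fs != fs for c in chans):
        raise ValueError("DBA channels must share a sampling rate")
    sos = butter(3, ALPHA2_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    window = max(int(round(fs * SMOOTHING_WINDOW_MS / 1000.0)), 1)
    powers = []
    for c in chans:
        band = sosfiltfilt(sos, c.data)
        powers.append(uniform_filter1d(band**2, size=window, mode="nearest"))
    return Channel(label="DBA", data=np.mean(powers, axis=0), fs=fs, unit="uV^2")


def er_dba(dba: Channel, events) -> dict[str, DbaTrace]:
    """Condition-wise event-related DBA traces for one subject.

    Epochs the power index on the −500…2000 ms axis, baseline-corrects each
    trial against −500…0 ms and averages within condition.  The pre-onset raw
    power (before correction) is kept as ``baseline_power`` so dip depths can
    be expressed fractionally.
    """
    epochs = epoch_series(dba.data, dba.fs, events)
    lo, hi = BASELINE_WINDOW_MS
    base_mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    corrected = baseline_correct(epochs)
    traces: dict[str, DbaTrace] = {}
    for cond, arr in corrected.epochs.items():
        n = arr.shape[0]
        raw = epochs.epochs[cond]
        traces[cond] = DbaTrace(
            time_ms=epochs.time_ms,
            mean=arr.mean(axis=0),
            sem=arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(arr.shape[1], np.nan),
            n=n,
            condition=cond,
            baseline_power=float(raw[:, base_mask].mean()),
        )
    return traces


def grand_average_traces(per_subject: list[dict[str, DbaTrace]]) -> dict[str, DbaTrace]:
    """Grand average of subject-mean traces (SEM across subjects).

    A condition enters the grand average with the subjects that have at
    least one trial of it; ``n`` records that subject count.
    """
    conditions: list[str] = []
    for d in per_subject:
        for k in d:
            if k not in conditions:
                conditions.append(k)
    out: dict[str, DbaTrace] = {}
    for cond in conditions:
        traces = [d[cond] for d in per_subject if cond in d]
        mean, sem = grand_average([t.mean for t in traces])
        out[cond] = DbaTrace(
            time_ms=traces[0].time_ms,
            mean=mean,
            sem=sem,
            n=len(traces),
            condition=cond,
            baseline_power=float(np.mean([t.baseline_power for t in traces])),
        )
    return out


def dip_metrics(
    trace: DbaTrace, search_window_ms: tuple[float, float] = DIP_SEARCH_WINDOW_MS
) -> DipMetrics:
    """Depth (>= 0) and latency of the post-onset minimum within the window."""
    lo, hi = search_window_ms
    mask = (trace.time_ms >= lo) & (trace.time_ms < hi)
    if not mask.any():
        raise ValueError(f"dip search window {search_window_ms} contains no samples")
    seg = trace.mean[mask]
    t_seg = trace.time_ms[mask]
    i = int(np.argmin(seg))
    minimum = float(seg[i])
    depth = -minimum if minimum < 0 else 0.0
    return DipMetrics(depth=depth, latency_ms=float(t_seg[i]), search_window_ms=search_window_ms)


def delta_trace(a: DbaTrace, b: DbaTrace) -> DbaTrace:
    """Pointwise difference a − b; SEMs combine in quadrature."""
    if a.time_ms.shape != b.time_ms.shape or not np.allclose(a.time_ms, b.time_ms):
        raise ValueError("traces must share a time vector")
    return DbaTrace(
        time_ms=a.time_ms,
        mean=a.mean - b.mean,
        sem=np.sqrt(a.sem**2 + b.sem**2),
        n=min(a.n, b.n),
        condition=f"{a.condition} - {b.condition}",
        baseline_power=a.baseline_power,
    )
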