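"""Event-related potentials at the vertex electrode (Cz).

Traces are band-passed 0.05–45 Hz (zero-phase), epoched on the −500…2000 ms
axis, baseline-corrected and averaged per event condition.  Component
amplitudes are measured as the signed extremum inside fixed windows — the
maximum for positive components (P200, P300, LPC/P600) and the minimum for
negative ones (N200, N400) — together with its latency.  A window-mean
measure is available as an option.  Overlapping windows are measured
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .physio_io import Channel, Recording, baseline_correct, epoch_series, grand_average

__all__ = ["ERP_BAND_HZ", "ERP_WINDOWS_MS", "ErpTrace", "component_amplitudes", "erp_traces"]

ERP_BAND_HZ = (0.05, 45.0)

#: measurement windows (ms) and polarity (+1 = positive-going component)
ERP_WINDOWS_MS: dict[str, tuple[float, float, int]] = {
    "P200": (150.0, 275.0, +1),
    "N200": (200.0, 350.0, -1),
    "P300": (300.0, 400.0, +1),
    "N400": (250.0, 550.0, -1),
    "LPC": (450.0, 800.0, +1),
}


@dataclass
class ErpTrace:
    """Per-condition mean ERP +- SEM on the epoch time axis."""

    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    condition: str


def _bandpass(data: np.ndarray, fs: float) -> np.ndarray:
    sos = butter(3, ERP_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data)


def erp_traces(cz: Channel | Recording, events, channel: str = "Cz") -> dict[str, ErpTrace]:
    """Condition-wise ERP traces from the Cz channel (one subject)."""
    if isinstance(cz, Recording):
        cz = cz.get(channel)
    filtered = _bandpass(cz.data, cz.fs)
    epochs = baseline_correct(epoch_series(filtered, cz.fs, events))
    out: dict[str, ErpTrace] = {}
    for cond, arr in epochs.epochs.items():
        n = arr.shape[0]
        out[cond] = ErpTrace(
            time_ms=epochs.time_ms,
            mean=arr.mean(axis=0),
            sem=arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(arr.shape[1], np.nan),
            n=n,
            condition=cond,
        )
    return out


def grand_average_erp(per_subject: list[dict[str, ErpTrace]]) -> dict[str, ErpTrace]:
    """Grand-average subject-mean ERP traces (SEM across subjects)."""
    conds: list[str] = []
    for d in per_subject:
        for k in d:
            if k not in conds:
                conds.append(k)
    out = {}
    for cond in conds:
        traces = [d[cond] for d in per_subject if cond in d]
        mean, sem = grand_average([t.mean for t in traces])
        out[cond] = ErpTrace(traces[0].time_ms, mean, sem, len(traces), cond)
    return out


def component_amplitudes(trace: ErpTrace, measure: str = "peak") -> pd.DataFrame:
    """Component table for one trace: window, amplitude and peak latency.

    ``measure='peak'`` reports the polarity-consistent extremum; ``'mean'``
    reports the window mean (latency then is the window centre).
    """
    if measure not in ("peak", "mean"):
        raise ValueError("measure must be 'peak' or 'mean'")
    rows = []
    for name, (lo, hi, pol) in ERP_WINDOWS_MS.items():
        mask = (trace.time_ms >= lo) & (trace.time_ms <= hi)
        if not mask.any():
            raise ValueError(f"trace does not span the {name} window ({lo}-{hi} ms)")
        seg = trace.mean[mask]
        t_seg = trace.time_ms[mask]
        if measure == "mean":
            amp, lat = float(seg.mean()), float((lo + hi) / 2)
        else:
            i = int(np.argmax(pol * seg))
            amp, lat = float(seg[i]), float(t_seg[i])
        rows.append(
            {
                "component": name,
                "window_lo_ms": lo,
                "window_hi_ms": hi,
                "polarity": pol,
                "amplitude": amp,
                "peak_latency_ms": lat,
            }
        )
    return pd.DataFrame(rows)
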