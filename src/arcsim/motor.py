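"""EMG-power and accelerometry pipelines: lateralisation and step timing.

EMG power pools the two muscles of one leg: band-pass 20–500 Hz (zero-phase
Butterworth, upper edge clipped below Nyquist), moving RMS per channel, then
``power = (RMS1^2 + RMS2^2) / 2``.  Event-related traces are computed for
the stepping and supporting leg separately — which leg is which varies trial
by trial — and their difference Δ = step − support measures lateralisation;
a sign reversal of Δ after stimulus onset marks the redirection of an
initially location-driven activation toward the instructed side.

Step timing comes from the horizontal acceleration axis: low-pass 5 Hz,
then within each trial take the first two opposite-signed extrema exceeding
a prominence threshold (3x the pre-onset noise level by default).  The
first extremum is the anticipatory postural adjustment (APA), the second
the foot-off; APA polarity encodes the executed step side, which replaces
video scoring for relevance labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .physio_io import (
    BASELINE_WINDOW_MS,
    EPOCH_TMAX_MS,
    EPOCH_TMIN_MS,
    Channel,
    Recording,
)

__all__ = [
    "EMG_BAND_HZ",
    "EmgPowerTrace",
    "StepTiming",
    "acc_step_timing",
    "emg_power",
    "er_emg",
    "label_performance",
]

EMG_BAND_HZ = (20.0, 500.0)
RMS_WINDOW_MS = 50.0
ACC_LOWPASS_HZ = 5.0


@dataclass
class EmgPowerTrace:
    """Step/support EMG power (means +- SEM) and their difference for one condition."""

    time_ms: np.ndarray
    step_mean: np.ndarray
    step_sem: np.ndarray
    support_mean: np.ndarray
    support_sem: np.ndarray
    n: int
    condition: str

    @property
    def delta(self) -> np.ndarray:
        return self.step_mean - self.support_mean


@dataclass(frozen=True)
class StepTiming:
    """Detected step landmarks of one trial (ms from stimulus onset)."""

    apa_ms: float
    footoff_ms: float
    step_side: int

    def __post_init__(self) -> None:
        if not 0 < self.apa_ms < self.footoff_ms:
            raise ValueError("expected 0 < apa_ms < footoff_ms")


def emg_power(
    emg1: Channel | np.ndarray,
    emg2: Channel | np.ndarray,
    fs: float | None = None,
    rms_window_ms: float = RMS_WINDOW_MS,
    band_hz: tuple[float, float] = EMG_BAND_HZ,
) -> Channel:
    """Two-muscle EMG power series ``(RMS1^2 + RMS2^2) / 2`` for one leg."""
    if isinstance(emg1, Channel):
        if isinstance(emg2, Channel) and emg2.fs != emg1.fs:
            raise ValueError("EMG channels must share a sampling rate")
        fs = emg1.fs
    if fs is None:
        raise ValueError("fs is required for raw-array input")
    x1 = emg1.data if isinstance(emg1, Channel) else np.asarray(emg1, dtype=float)
    x2 = emg2.data if isinstance(emg2, Channel) else np.asarray(emg2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("EMG channels must have equal length")
    lo, hi = band_hz
    hi = min(hi, 0.98 * fs / 2.0)  # keep the upper edge strictly below Nyquist
    sos = butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    window = max(int(round(fs * rms_window_ms / 1000.0)), 1)
    ms1 = uniform_filter1d(sosfiltfilt(sos, x1) ** 2, size=window, mode="nearest")
    ms2 = uniform_filter1d(sosfiltfilt(sos, x2) ** 2, size=window, mode="nearest")
    return Channel(label="EMG_power", data=(ms1 + ms2) / 2.0, fs=fs, unit="uV^2")


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    raise TypeError("events must be a DataFrame with onset_ms/event_condition/step_side")


def _extract(x: np.ndarray, fs: float, onset_ms: float,
             tmin_ms: float = EPOCH_TMIN_MS, tmax_ms: float = EPOCH_TMAX_MS):
    center = int(round(onset_ms * fs / 1000.0))
    n0 = int(round(tmin_ms * fs / 1000.0))
    n1 = int(round(tmax_ms * fs / 1000.0))
    lo, hi = center + n0, center + n1
    if lo < 0 or hi > x.size:
        return None
    return x[lo:hi]


def er_emg(
    power_right: Channel,
    power_left: Channel,
    events,
) -> dict[str, EmgPowerTrace]:
    """Condition-wise step/support EMG power traces (one subject).

    ``events`` must provide ``onset_ms``, ``event_condition`` and
    ``step_side`` (0 = right, 1 = left) per trial; the stepping leg's power
    trace is taken from the corresponding side, the supporting leg's from
    the other.  Trials are baseline-corrected (−500…0 ms) before averaging.
    """
    ev = _events_frame(events)
    if power_right.fs != power_left.fs:
        raise ValueError("power series must share a sampling rate")
    fs = power_right.fs
    n0 = int(round(EPOCH_TMIN_MS * fs / 1000.0))
    n1 = int(round(EPOCH_TMAX_MS * fs / 1000.0))
    time_ms = np.arange(n0, n1) * 1000.0 / fs
    base = (time_ms >= BASELINE_WINDOW_MS[0]) & (time_ms < BASELINE_WINDOW_MS[1])

    grouped: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for onset, cond, side in zip(ev["onset_ms"], ev["event_condition"], ev["step_side"]):
        side = int(side)
        step_series = power_left if side == 1 else power_right
        supp_series = power_right if side == 1 else power_left
        step = _extract(step_series.data, fs, float(onset))
        supp = _extract(supp_series.data, fs, float(onset))
        if step is None or supp is None:
            continue
        step = step - step[base].mean()
        supp = supp - supp[base].mean()
        grouped.setdefault(str(cond), []).append((step, supp))

    out: dict[str, EmgPowerTrace] = {}
    for cond, pairs in grouped.items():
        steps = np.vstack([p[0] for p in pairs])
        supps = np.vstack([p[1] for p in pairs])
        n = steps.shape[0]
        sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(a.shape[1], np.nan)
        out[cond] = EmgPowerTrace(
            time_ms=time_ms,
            step_mean=steps.mean(axis=0),
            step_sem=sem(steps),
            support_mean=supps.mean(axis=0),
            support_sem=sem(supps),
            n=n,
            condition=cond,
        )
    return out


def acc_step_timing(
    acc: Recording | Channel,
    events,
    channel: str = "ACC_X",
    lowpass_hz: float = ACC_LOWPASS_HZ,
    prominence_factor: float = 3.0,
    search_window_ms: tuple[float, float] = (0.0, 1500.0),
) -> pd.DataFrame:
    """Per-trial APA and foot-off latencies from the horizontal axis.

    Returns one row per event with ``apa_ms``, ``footoff_ms``, ``step_side``
    and ``resolved``; trials where two qualifying opposite-signed extrema
    cannot be found are flagged unresolved (NaN latencies), not guessed.
    """
    ch = acc.get(channel) if isinstance(acc, Recording) else acc
    fs = ch.fs
    sos = butter(3, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, ch.data)

    ev = _events_frame(events)
    lo_ms, hi_ms = search_window_ms
    rows = []
    for idx, onset in zip(ev["index"], ev["onset_ms"]):
        onset = float(onset)
        seg = _extract(x, fs, onset, tmin_ms=lo_ms, tmax_ms=hi_ms)
        pre = _extract(x, fs, onset, tmin_ms=-500.0, tmax_ms=0.0)
        row = {"index": int(idx), "apa_ms": np.nan, "footoff_ms": np.nan,
               "step_side": -1, "resolved": False}
        if seg is not None:
            noise = pre.std() if pre is not None else seg.std() / 10.0
            # floor at 25% of the trial's own peak: zero-phase filtering puts
            # ringing side lobes (~8% of a lobe) around each true extremum,
            # and those must not outrank a true peak just because the
            # pre-onset noise happens to be low; true lobes stay above half
            # the trial maximum after filtering
            prom = max(prominence_factor * max(noise, 1e-12), 0.25 * np.abs(seg).max())
            peaks_pos, _ = find_peaks(seg, prominence=prom)
            peaks_neg, _ = find_peaks(-seg, prominence=prom)
            extrema = sorted(
                [(p, 1) for p in peaks_pos] + [(p, -1) for p in peaks_neg]
            )
            if len(extrema) >= 2:
                first_i, first_sign = extrema[0]
                second = next((e for e in extrema[1:] if e[1] == -first_sign), None)
                if second is not None:
                    row.update(
                        apa_ms=lo_ms + first_i * 1000.0 / fs,
                        footoff_ms=lo_ms + second[0] * 1000.0 / fs,
                        step_side=0 if first_sign > 0 else 1,
                        resolved=True,
                    )
        rows.append(row)
    return pd.DataFrame(rows)


def label_performance(timing: pd.DataFrame, events) -> pd.DataFrame:
    """Relevance labels from detected step sides: relevant <=> side == symbol.

    Unresolved trials get a null label and are counted in the returned
    frame's ``resolved`` column rather than silently dropped.
    """
    ev = _events_frame(events)
    merged = ev.merge(timing, on="index", suffixes=("", "_detected"))
    relevant = pd.array(
        merged["step_side_detected" if "step_side_detected" in merged else "step_side"]
        == merged["symbol"],
        dtype="boolean",
    )
    relevant[~merged["resolved"].astype(bool)] = pd.NA
    out = merged.copy()
    out["relevant_detected"] = relevant
    return out


def rt_summary_from_timing(timing_events: pd.DataFrame) -> pd.DataFrame:
    """APA / foot-off mean +- SEM per event condition from detected timings."""
    rows = []
    resolved = timing_events[timing_events["resolved"].astype(bool)]
    for cond, grp in resolved.groupby("event_condition"):
        n = len(grp)
        rows.append(
            {
                "event_condition": cond,
                "n_trials": n,
                "apa_mean_ms": grp["apa_ms"].mean(),
                "apa_sem_ms": grp["apa_ms"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "footoff_mean_ms": grp["footoff_ms"].mean(),
                "footoff_sem_ms": grp["footoff_ms"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
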