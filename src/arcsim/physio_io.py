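"""Recording containers, EDF I/O, epoching and baseline correction.

Recordings are lightweight per-channel containers (label, samples, sampling
rate, unit) so EEG at 256 Hz and EMG at 1024 Hz can live in the same file
format.  Storage is EDF (European Data Format): 16-bit samples under an
ASCII header, with per-signal sampling rates.  The reader/writer here covers
the plain-EDF subset this package produces — one data record per second,
integer per-record sample counts — and round-trips samples within one
digitisation step.

Epoching cuts condition-labelled windows on the analysis time axis used
throughout: −500 ms to 2000 ms around stimulus onset, half-open at the right
edge so every epoch has exactly ``2.5 * fs`` samples.  Baseline correction
subtracts each trial's pre-onset (−500…0 ms) mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "EdfFormatError",
    "EpochSet",
    "Recording",
    "baseline_correct",
    "epoch",
    "epoch_series",
    "grand_average",
    "read_edf",
    "write_edf",
]

EPOCH_TMIN_MS = -500.0
EPOCH_TMAX_MS = 2000.0
BASELINE_WINDOW_MS = (-500.0, 0.0)

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """File is not parseable as the EDF subset this package writes."""


@dataclass
class Channel:
    """One channel: label, samples, sampling rate and physical unit."""

    label: str
    data: np.ndarray
    fs: float
    unit: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("channel data must be 1-d")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.data.size / self.fs


@dataclass
class Recording:
    """A set of synchronously started channels (rates may differ)."""

    channels: list[Channel]
    start: str = "01.01.00 00.00.00"  # fixed EDF date.time for reproducible files

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def get(self, label: str) -> Channel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(f"channel {label!r} not in recording (has {self.labels})")

    def __contains__(self, label: str) -> bool:
        return label in self.labels


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise EdfFormatError(f"EDF field overflow: {text!r} > {width} bytes")
    return b.ljust(width)


def _fit_phys_max(amax: float) -> float:
    """Smallest short-printable value >= amax (fits an 8-char EDF field signed)."""
    if amax == 0:
        return 1.0
    for mult in (1.0, 1.01, 1.1):
        for fmt in (".6g", ".4g", ".1e"):
            s = f"{amax * mult:{fmt}}"
            if len(s) <= 7:
                v = float(s)
                if v >= amax:
                    return v
    return float(np.ceil(amax))


def write_edf(recording: Recording, path) -> None:
    """Write a recording as plain EDF (1-second data records, 16-bit).

    Channel sampling rates must be positive integers.  Channels shorter than
    a whole number of seconds are zero-padded to the next record boundary
    (EDF stores an integer number of records); the padding is returned on
    read.
    """
    path = Path(path)
    chans = recording.channels
    if not chans:
        raise ValueError("cannot write an empty recording")
    for c in chans:
        if abs(c.fs - round(c.fs)) > 1e-9:
            raise EdfFormatError(f"channel {c.label!r}: non-integer rate {c.fs}")
    n_records = max(int(np.ceil(c.duration_s)) for c in chans)
    n_records = max(n_records, 1)

    # physical range: symmetric about zero, serialised then re-parsed so the
    # scale used for digitisation is exactly the one a reader reconstructs
    scales = []
    offsets = []
    for c in chans:
        amax = float(np.max(np.abs(c.data))) if c.data.size else 0.0
        pmax = _fit_phys_max(amax)
        scales.append((pmax - (-pmax)) / (_DIG_MAX - _DIG_MIN))
        offsets.append(pmax)

    date, time = recording.start.split()
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(date, 8),
            _pad(time, 8),
            _pad(str(256 * (1 + len(chans))), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(len(chans)), 4),
        ]
    )
    sig_fields = [
        [_pad(c.label, 16) for c in chans],
        [_pad("", 80) for _ in chans],
        [_pad(c.unit, 8) for c in chans],
        [_pad(f"{-off:.6g}"[:8], 8) for off in offsets],
        [_pad(f"{off:.6g}"[:8], 8) for off in offsets],
        [_pad(str(_DIG_MIN), 8) for _ in chans],
        [_pad(str(_DIG_MAX), 8) for _ in chans],
        [_pad("", 80) for _ in chans],
        [_pad(str(int(round(c.fs))), 8) for c in chans],
        [_pad("", 32) for _ in chans],
    ]

    digital = []
    for c, scale in zip(chans, scales):
        total = int(round(c.fs)) * n_records
        padded = np.zeros(total)
        padded[: c.data.size] = c.data
        d = np.round(padded / scale).astype(np.int64)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for fields in sig_fields:
            fh.write(b"".join(fields))
        for rec in range(n_records):
            for c, d in zip(chans, digital):
                spr = int(round(c.fs))
                fh.write(d[rec * spr : (rec + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (plain EDF, no annotations)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: truncated EDF header")

    def f(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    try:
        n_records = int(f(236, 244))
        record_dur = float(f(244, 252))
        ns = int(f(252, 256))
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed fixed header ({exc})") from exc
    start = f"{f(168, 176)} {f(176, 184)}"

    base = 256
    if len(raw) < base + 256 * ns:
        raise EdfFormatError(f"{path}: header claims {ns} signals, file too short")

    labels, units, pmins, pmaxs, dmins, dmaxs, sprs = [], [], [], [], [], [], []
    for i in range(ns):
        try:
            labels.append(raw[base + 16 * i : base + 16 * (i + 1)].decode("ascii").strip())
            units.append(raw[base + 96 * ns + 8 * i : base + 96 * ns + 8 * (i + 1)].decode("ascii").strip())
            pmins.append(float(raw[base + 104 * ns + 8 * i : base + 104 * ns + 8 * (i + 1)]))
            pmaxs.append(float(raw[base + 112 * ns + 8 * i : base + 112 * ns + 8 * (i + 1)]))
            dmins.append(int(raw[base + 120 * ns + 8 * i : base + 120 * ns + 8 * (i + 1)]))
            dmaxs.append(int(raw[base + 128 * ns + 8 * i : base + 128 * ns + 8 * (i + 1)]))
            sprs.append(int(raw[base + 216 * ns + 8 * i : base + 216 * ns + 8 * (i + 1)]))
        except ValueError as exc:
            raise EdfFormatError(
                f"{path}: malformed signal header for channel index {i}"
                f" (label {labels[i] if len(labels) > i else '?'})"
            ) from exc

    data_start = base + 256 * ns
    rec_len = sum(sprs)
    body = np.frombuffer(raw, dtype="<i2", offset=data_start)
    if body.size < rec_len * n_records:
        raise EdfFormatError(f"{path}: data section shorter than header promises")
    body = body[: rec_len * n_records].reshape(n_records, rec_len)

    channels = []
    pos = 0
    for i in range(ns):
        spr = sprs[i]
        dig = body[:, pos : pos + spr].reshape(-1).astype(float)
        pos += spr
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (dig - dmins[i]) * scale + pmins[i]
        channels.append(
            Channel(label=labels[i], data=phys, fs=spr / record_dur, unit=units[i])
        )
    return Recording(channels=channels, start=start)


# ---------------------------------------------------------------------------
# epoching

@dataclass
class EpochSet:
    """Condition-keyed epoch arrays sharing one relative time axis."""

    time_ms: np.ndarray
    epochs: dict[str, np.ndarray]  # condition -> (n_trials, n_samples)
    fs: float
    n_skipped: int = 0

    @property
    def conditions(self) -> list[str]:
        return list(self.epochs)

    def counts(self) -> dict[str, int]:
        return {k: v.shape[0] for k, v in self.epochs.items()}


def _event_pairs(events) -> list[tuple[float, str]]:
    """Normalise events to (onset_ms, condition-label) pairs."""
    if isinstance(events, pd.DataFrame):
        col = "event_condition" if "event_condition" in events else "sequence_condition"
        return list(zip(events["onset_ms"].astype(float), events[col].astype(str)))
    out = []
    for ev in events:
        if hasattr(ev, "onset_ms"):
            out.append((float(ev.onset_ms), str(ev.sequence_condition)))
        else:
            onset, label = ev
            out.append((float(onset), str(label)))
    return out


def epoch_series(
    x: np.ndarray,
    fs: float,
    events,
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
) -> EpochSet:
    """Cut condition-labelled epochs out of a 1-d series.

    Onsets map to samples by nearest-sample rounding; windows are half-open
    ``[tmin, tmax)`` so every epoch has the same length.  Events whose window
    leaves the recording are skipped with a warning and counted in
    ``n_skipped``.
    """
    x = np.asarray(x, dtype=float)
    n0 = int(round(tmin_ms * fs / 1000.0))
    n1 = int(round(tmax_ms * fs / 1000.0))
    time_ms = np.arange(n0, n1) * 1000.0 / fs
    grouped: dict[str, list[np.ndarray]] = {}
    skipped = 0
    for onset_ms, label in _event_pairs(events):
        center = int(round(onset_ms * fs / 1000.0))
        lo, hi = center + n0, center + n1
        if lo < 0 or hi > x.size:
            skipped += 1
            continue
        grouped.setdefault(label, []).append(x[lo:hi])
    if skipped:
        warnings.warn(f"epoching skipped {skipped} out-of-bounds event(s)", stacklevel=2)
    epochs = {k: np.vstack(v) for k, v in grouped.items()}
    return EpochSet(time_ms=time_ms, epochs=epochs, fs=fs, n_skipped=skipped)


def epoch(
    recording: Recording,
    events,
    channel: str,
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
) -> EpochSet:
    """Epoch one named channel of a recording."""
    ch = recording.get(channel)
    return epoch_series(ch.data, ch.fs, events, tmin_ms=tmin_ms, tmax_ms=tmax_ms)


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = BASELINE_WINDOW_MS) -> EpochSet:
    """Subtract each trial's mean over ``window_ms`` (default −500…0 ms)."""
    lo, hi = window_ms
    mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    corrected = {
        k: v - v[:, mask].mean(axis=1, keepdims=True) for k, v in epochs.epochs.items()
    }
    return EpochSet(
        time_ms=epochs.time_ms, epochs=corrected, fs=epochs.fs, n_skipped=epochs.n_skipped
    )


def grand_average(subject_means: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Grand average across subjects: unweighted mean and SEM of subject means."""
    stack = np.vstack([np.atleast_1d(m) for m in subject_means])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
    return mean, sem
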