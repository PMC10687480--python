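"""Seeded synthetic EEG / EMG / acceleration recordings with ground truth.

The generator turns a simulated session (a list of trial records) into
multichannel recordings that embody the statistical structure the analysis
pipeline assumes, so every downstream estimate can be scored against known
ground truth:

* **EEG, occipital (O1, O2)** — pink noise plus an alpha-band carrier
  (10–13 Hz) whose amplitude envelope is multiplicatively suppressed after
  each stimulus by a smooth Gaussian bump.  Bump depth is a linear function
  of the trial's cognitive cost (``d = d0 + d1 * cost``), so costly
  (incongruent-perceived) trials produce deeper event-related power dips.
  Relevant responses get the full dip near 500 ms; incongruent relevant
  trials additionally get an early shoulder (~250 ms) so their traces
  depart from the congruent ones earlier.  Irrelevant responses get no dip —
  except irrelevant C(C) trials, which get an early-shifted one (~300 ms).
* **EEG, vertex (Cz)** — pink noise plus Gaussian-windowed event-related
  deflections at the classical component latencies; only the P200 amplitude
  depends on congruency by default.
* **EMG (4 channels, two muscles per leg)** — band-limited noise modulated
  by side- and condition-dependent envelopes: early lateralisation toward
  the stimulus-location side from ~120 ms, an envelope exchange toward the
  instructed side at ~200 ms on relevant incongruent trials, a late (~600
  ms) inversion on irrelevant C(C) trials, and no exchange otherwise.
* **Acceleration (3 axes)** — the horizontal axis carries a smooth biphasic
  waveform per trial: an anticipatory-postural peak at the trial's APA time
  and an opposite-signed foot-off peak at its foot-off time, with polarity
  encoding the executed step side.

All generators are pure functions of (records, params, seed); per-subject
variability is a multiplicative lognormal gain on signal amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .behavior_sim import TrialRecord
from .physio_io import Channel, Recording, write_edf
from .task_design import UNDEFINED

__all__ = [
    "ErpComponentSpec",
    "SynthParams",
    "ground_truth_frame",
    "subject_gains",
    "synth_acc",
    "synth_eeg",
    "synth_emg",
    "synth_subject",
    "write_dataset",
]


@dataclass(frozen=True)
class ErpComponentSpec:
    """One synthetic ERP deflection: centre latency, width and signed amplitude."""

    latency_ms: float
    sigma_ms: float
    amplitude: float  # sign encodes polarity (uV)


def _default_erp_components() -> dict[str, ErpComponentSpec]:
    # centred in the classical measurement windows; only P200 varies with
    # congruency (its amplitude here is the congruent value)
    return {
        "P200": ErpComponentSpec(210.0, 22.0, 3.0),
        "N200": ErpComponentSpec(290.0, 28.0, -4.0),
        "P300": ErpComponentSpec(360.0, 32.0, 5.0),
        "N400": ErpComponentSpec(470.0, 50.0, -3.0),
        "LPC": ErpComponentSpec(640.0, 80.0, 4.0),
    }


@dataclass(frozen=True)
class SynthParams:
    """Generator settings (amplitudes in uV for EEG, arbitrary units elsewhere)."""

    eeg_fs: float = 256.0
    emg_fs: float = 1024.0
    acc_fs: float = 256.0

    # occipital alpha carrier and its cost-driven dip
    alpha_freq_hz: float = 11.5
    alpha_amp: float = 20.0
    dip_map: tuple[float, float] = (0.05, 0.2)  # depth = d0 + d1 * cost_nats
    dip_latency_ms: float = 500.0
    dip_width_ms: float = 300.0  # FWHM of the Gaussian envelope bump
    early_dip_fraction: float = 0.3  # incongruent-trial shoulder, rel. to main depth
    early_dip_latency_ms: float = 250.0
    early_dip_width_ms: float = 200.0
    irrelevant_cc_dip_latency_ms: float = 300.0
    eeg_noise_sd: float = 10.0  # pink-noise amplitude, O1/O2

    # vertex ERP
    erp_components: dict[str, ErpComponentSpec] = field(
        default_factory=_default_erp_components
    )
    p200_amp_congruent: float = 3.0
    p200_amp_incongruent: float = 6.0
    cz_noise_sd: float = 3.0

    # EMG envelopes
    emg_tonic: float = 0.1
    emg_burst_amp: float = 1.0
    emg_other_amp: float = 0.4
    emg_onset_ms: float = 120.0
    emg_exchange_ms: float = 200.0
    emg_irrelevant_cc_invert_ms: float = 600.0
    emg_transition_tau_ms: float = 30.0
    emg_muscle_gains: tuple[float, float] = (1.0, 0.7)  # tibialis, gastrocnemius
    emg_sensor_noise_sd: float = 0.02

    # acceleration
    apa_lobe_amp: float = 1.0
    footoff_lobe_amp: float = 1.5
    # narrow enough that the 5 Hz-filtered lobes remain two cleanly
    # separated peaks: overlapping tails would pull each detected peak
    # toward the other in a congruency-dependent way
    apa_lobe_width_ms: float = 80.0
    footoff_lobe_width_ms: float = 100.0
    acc_noise_sd: float = 0.05

    # cohort
    n_subjects: int = 17
    subject_gain_sigma: float = 0.2

    def __post_init__(self) -> None:
        if min(self.eeg_fs, self.emg_fs, self.acc_fs) <= 0:
            raise ValueError("sampling rates must be positive")
        if not 10.0 <= self.alpha_freq_hz <= 13.0:
            raise ValueError("alpha_freq_hz must lie in the alpha-2 band (10-13 Hz)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def subject_gains(params: SynthParams, seed: int) -> np.ndarray:
    """Per-subject multiplicative amplitude gains (lognormal, median 1)."""
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=0.0, sigma=params.subject_gain_sigma, size=params.n_subjects)


# ---------------------------------------------------------------------------
# helpers

def _duration_samples(records: list[TrialRecord], fs: float) -> int:
    last = max(r.event.onset_ms for r in records)
    dur_s = int(np.ceil((last + 3000.0) / 1000.0))  # whole seconds: exact EDF records
    return int(round(dur_s * fs))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_gaussian_bump(
    out: np.ndarray, fs: float, center_ms: float, sigma_ms: float, amplitude: float
) -> None:
    """Accumulate a Gaussian bump in place, evaluated on a local window only."""
    sigma = sigma_ms * fs / 1000.0
    center = center_ms * fs / 1000.0
    lo = max(int(center - 5 * sigma), 0)
    hi = min(int(center + 5 * sigma) + 1, out.size)
    if hi <= lo:
        return
    idx = np.arange(lo, hi)
    out[lo:hi] += amplitude * np.exp(-0.5 * ((idx - center) / sigma) ** 2)


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def trial_dip_depth(record: TrialRecord, params: SynthParams) -> float:
    """Fractional envelope dip implied by a trial's cognitive cost."""
    d0, d1 = params.dip_map
    return float(np.clip(d0 + d1 * record.cost_nats, 0.0, 0.95))


def _dip_schedule(records: list[TrialRecord], params: SynthParams):
    """(center_ms, sigma_ms, depth) bumps to carve out of the alpha envelope."""
    bumps = []
    for r in records:
        depth = trial_dip_depth(r, params)
        if r.relevant:
            bumps.append(
                (r.event.onset_ms + params.dip_latency_ms, params.dip_width_ms / _FWHM, depth)
            )
            if r.event.stimulus.congruency_theta == 1:
                bumps.append(
                    (
                        r.event.onset_ms + params.early_dip_latency_ms,
                        params.early_dip_width_ms / _FWHM,
                        depth * params.early_dip_fraction,
                    )
                )
        elif r.event.sequence_condition == "C(C)":
            # irrelevant C(C): early-shifted dip; other irrelevant trials: none
            bumps.append(
                (
                    r.event.onset_ms + params.irrelevant_cc_dip_latency_ms,
                    params.dip_width_ms / _FWHM,
                    depth,
                )
            )
    return bumps


# ---------------------------------------------------------------------------
# generators

def synth_eeg(
    records: list[TrialRecord],
    params: SynthParams,
    seed: int,
    subject_gain: float = 1.0,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesise O1, O2 and Cz and return the recording plus ground truth."""
    _require_labels(records)
    fs = params.eeg_fs
    n = _duration_samples(records, fs)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    envelope = np.ones(n)
    for center, sigma, depth in _dip_schedule(records, params):
        _add_gaussian_bump(envelope, fs, center, sigma, -depth)
    np.clip(envelope, 0.0, None, out=envelope)

    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * params.alpha_freq_hz * t + phase)
    alpha = params.alpha_amp * subject_gain * envelope * carrier

    channels = []
    for label in ("O1", "O2"):
        noise = params.eeg_noise_sd * subject_gain * _pink_noise(n, rng)
        channels.append(Channel(label=label, data=alpha + noise, fs=fs, unit="uV"))

    cz = params.cz_noise_sd * subject_gain * _pink_noise(n, rng)
    for r in records:
        for name, comp in params.erp_components.items():
            amp = comp.amplitude
            if name == "P200":
                amp = (
                    params.p200_amp_incongruent
                    if r.event.stimulus.congruency_theta == 1
                    else params.p200_amp_congruent
                )
            _add_gaussian_bump(
                cz, fs, r.event.onset_ms + comp.latency_ms, comp.sigma_ms, amp * subject_gain
            )
    channels.append(Channel(label="Cz", data=cz, fs=fs, unit="uV"))

    return Recording(channels=channels), ground_truth_frame(records, params)


def _sigmoid_rise(t_ms: np.ndarray, t0_ms: float, tau_ms: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t_ms - t0_ms) / tau_ms))


def _emg_side_envelopes(
    r: TrialRecord, t_ms: np.ndarray, params: SynthParams
) -> tuple[np.ndarray, np.ndarray]:
    """(right, left) power envelopes of one trial on a local time axis (ms)."""
    theta = r.event.stimulus.congruency_theta
    loc = r.event.stimulus.location_p
    early = {loc: params.emg_burst_amp, 1 - loc: params.emg_other_amp}

    swap_ms: float | None = None
    if r.relevant and theta == 1:
        swap_ms = params.emg_exchange_ms
    elif not r.relevant and r.event.sequence_condition == "C(C)":
        swap_ms = params.emg_irrelevant_cc_invert_ms
    late = {s: early[1 - s] for s in (0, 1)} if swap_ms is not None else dict(early)

    t_on = params.emg_onset_ms
    t_off = r.footoff_ms + 300.0
    tau = params.emg_transition_tau_ms
    envs = []
    for side in (0, 1):
        env = early[side] * _sigmoid_rise(t_ms, t_on, tau)
        if swap_ms is not None:
            env += (late[side] - early[side]) * _sigmoid_rise(t_ms, swap_ms, tau)
        env -= late[side] * _sigmoid_rise(t_ms, t_off, tau)
        envs.append(np.clip(env, 0.0, None))
    return envs[0], envs[1]


def synth_emg(
    records: list[TrialRecord],
    params: SynthParams,
    seed: int,
    subject_gain: float = 1.0,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesise four EMG channels (tibialis/gastrocnemius, right/left)."""
    _require_labels(records)
    fs = params.emg_fs
    n = _duration_samples(records, fs)
    rng = np.random.default_rng(seed)

    env = {0: np.full(n, params.emg_tonic), 1: np.full(n, params.emg_tonic)}
    for r in records:
        onset = r.event.onset_ms
        lo = max(int((onset - 200.0) * fs / 1000.0), 0)
        hi = min(int((onset + r.footoff_ms + 900.0) * fs / 1000.0), n)
        t_ms = np.arange(lo, hi) * 1000.0 / fs - onset
        right, left = _emg_side_envelopes(r, t_ms, params)
        env[0][lo:hi] += right
        env[1][lo:hi] += left

    nyq = fs / 2.0
    sos = butter(3, [20.0, min(500.0, 0.98 * nyq)], btype="bandpass", fs=fs, output="sos")
    channels = []
    for side, side_name in ((0, "R"), (1, "L")):
        for gain, muscle in zip(params.emg_muscle_gains, ("TA", "GC")):
            carrier = sosfiltfilt(sos, rng.standard_normal(n))
            carrier /= max(carrier.std(), 1e-12)
            data = subject_gain * gain * env[side] * carrier
            data += params.emg_sensor_noise_sd * rng.standard_normal(n)
            channels.append(
                Channel(label=f"EMG_{muscle}_{side_name}", data=data, fs=fs, unit="uV")
            )
    return Recording(channels=channels), ground_truth_frame(records, params)


def synth_acc(
    records: list[TrialRecord],
    params: SynthParams,
    seed: int,
    subject_gain: float = 1.0,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesise tri-axial acceleration; X is the horizontal stepping axis."""
    _require_labels(records)
    fs = params.acc_fs
    n = _duration_samples(records, fs)
    rng = np.random.default_rng(seed)

    x = np.zeros(n)
    for r in records:
        polarity = 1.0 if r.final_side == 0 else -1.0
        _add_gaussian_bump(
            x, fs, r.event.onset_ms + r.apa_ms, params.apa_lobe_width_ms / _FWHM,
            polarity * params.apa_lobe_amp * subject_gain,
        )
        _add_gaussian_bump(
            x, fs, r.event.onset_ms + r.footoff_ms, params.footoff_lobe_width_ms / _FWHM,
            -polarity * params.footoff_lobe_amp * subject_gain,
        )
    x += params.acc_noise_sd * rng.standard_normal(n)
    y = params.acc_noise_sd * rng.standard_normal(n)
    z = params.acc_noise_sd * rng.standard_normal(n)
    rec = Recording(
        channels=[
            Channel("ACC_X", x, fs, unit="m/s2"),
            Channel("ACC_Y", y, fs, unit="m/s2"),
            Channel("ACC_Z", z, fs, unit="m/s2"),
        ]
    )
    return rec, ground_truth_frame(records, params)


def synth_subject(
    records: list[TrialRecord],
    params: SynthParams,
    seed: int,
    subject_gain: float = 1.0,
) -> tuple[dict[str, Recording], pd.DataFrame]:
    """All three modalities for one subject, with independent sub-seeds."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    eeg, truth = synth_eeg(records, params, seeds[0], subject_gain)
    emg, _ = synth_emg(records, params, seeds[1], subject_gain)
    acc, _ = synth_acc(records, params, seeds[2], subject_gain)
    return {"eeg": eeg, "emg": emg, "acc": acc}, truth


def ground_truth_frame(records: list[TrialRecord], params: SynthParams) -> pd.DataFrame:
    """Per-trial ground truth sufficient to score every pipeline output."""
    rows = []
    for r in records:
        theta = r.event.stimulus.congruency_theta
        has_dip = r.relevant or r.event.sequence_condition == "C(C)"
        if r.relevant:
            dip_latency = params.dip_latency_ms
        elif has_dip:
            dip_latency = params.irrelevant_cc_dip_latency_ms
        else:
            dip_latency = float("nan")
        rows.append(
            {
                "index": r.event.index,
                "onset_ms": r.event.onset_ms,
                "sequence_condition": r.event.sequence_condition,
                "event_condition": r.event_condition,
                "congruency": theta,
                "relevant": r.relevant,
                "cost_nats": r.cost_nats,
                "dip_depth_frac": trial_dip_depth(r, params) if has_dip else 0.0,
                "dip_latency_ms": dip_latency,
                "p200_amp": params.p200_amp_incongruent if theta else params.p200_amp_congruent,
                "apa_ms": r.apa_ms,
                "footoff_ms": r.footoff_ms,
                "step_side": r.final_side,
            }
        )
    return pd.DataFrame(rows)


def _require_labels(records: list[TrialRecord]) -> None:
    if not records:
        raise ValueError("no trial records supplied")
    unlabeled = sum(
        r.event_condition == UNDEFINED and r.event.sequence_condition != UNDEFINED
        for r in records
    )
    if unlabeled:
        raise ValueError("records must carry event-condition labels")


def write_dataset(
    recordings: dict[str, Recording],
    truth: pd.DataFrame,
    events: pd.DataFrame,
    out_dir,
) -> dict[str, Path]:
    """Write per-modality EDF files plus events and ground-truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, rec in recordings.items():
        paths[name] = out_dir / f"{name}.edf"
        write_edf(rec, paths[name])
    paths["events"] = out_dir / "events.csv"
    events.to_csv(paths["events"], index=False)
    paths["ground_truth"] = out_dir / "ground_truth.csv"
    truth.to_csv(paths["ground_truth"], index=False)
    return paths
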