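"""Synthetic physiology: determinism, spectra and recoverable structure."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from arcsim.erdba import dba_index, dip_metrics, er_dba
from arcsim.motor import emg_power, er_emg
from arcsim.physio_io import read_edf
from arcsim.synth_physio import (
    SynthParams,
    ground_truth_frame,
    subject_gains,
    synth_acc,
    synth_eeg,
    synth_emg,
    synth_subject,
    write_dataset,
)

PARAMS = SynthParams()


def test_generators_are_pure_functions_of_seed(short_records):
    for gen in (synth_eeg, synth_emg, synth_acc):
        a, _ = gen(short_records, PARAMS, seed=123)
        b, _ = gen(short_records, PARAMS, seed=123)
        c, _ = gen(short_records, PARAMS, seed=124)
        for ca, cb in zip(a.channels, b.channels):
            assert np.array_equal(ca.data, cb.data)
        assert any(
            not np.array_equal(ca.data, cc.data) for ca, cc in zip(a.channels, c.channels)
        )


def test_eeg_alpha_band_dominates_beta_band(short_records):
    rec, _ = synth_eeg(short_records, PARAMS, seed=1)
    f, pxx = periodogram(rec.get("O1").data, fs=PARAMS.eeg_fs)
    alpha = pxx[(f >= 10) & (f <= 13)].mean()
    beta = pxx[(f >= 13) & (f <= 26)].mean()
    assert alpha > 5 * beta


def test_dip_square_law_recovered_on_clean_carrier(short_records):
    # noiseless carrier: the ER-DBA fractional dip approximates the
    # square-law image 1-(1-d)^2 of the embedded envelope depth (the narrow
    # band-pass attenuates a 300 ms notch by some ten percent at most)
    clean = replace(PARAMS, eeg_noise_sd=0.0, cz_noise_sd=0.0)
    rec, truth = synth_eeg(short_records, clean, seed=2)
    ev = pd.DataFrame(
        {
            "onset_ms": [r.event.onset_ms for r in short_records],
            "event_condition": [r.event_condition for r in short_records],
        }
    )
    ev = ev[ev["event_condition"] != "UNDEFINED"]
    traces = er_dba(dba_index(rec), ev)
    cond = "C(C)-relevant"
    m = dip_metrics(traces[cond])
    frac = m.depth / traces[cond].baseline_power
    gen = truth[truth["event_condition"] == cond]
    expected = float((1 - (1 - gen["dip_depth_frac"]) ** 2).mean())
    assert frac == pytest.approx(expected, rel=0.2)
    assert abs(m.latency_ms - 500.0) < 100.0


def test_zero_dip_map_leaves_band_power_flat(short_records):
    flat = replace(PARAMS, dip_map=(0.0, 0.0), eeg_noise_sd=0.0, cz_noise_sd=0.0)
    rec, truth = synth_eeg(short_records, flat, seed=3)
    assert (truth["dip_depth_frac"] == 0).all()
    ev = pd.DataFrame(
        {
            "onset_ms": [r.event.onset_ms for r in short_records],
            "event_condition": ["all"] * len(short_records),
        }
    )
    traces = er_dba(dba_index(rec), ev)["all"]
    # residual double-carrier ripple over 20 epochs stays ~0.35/sqrt(20)
    assert np.abs(traces.mean).max() < 0.15 * traces.baseline_power


def test_emg_delta_reverses_only_for_relevant_incongruent(short_records):
    rec, _ = synth_emg(short_records, PARAMS, seed=4)
    p_right = emg_power(rec.get("EMG_TA_R"), rec.get("EMG_GC_R"))
    p_left = emg_power(rec.get("EMG_TA_L"), rec.get("EMG_GC_L"))
    ev = pd.DataFrame(
        {
            "onset_ms": [r.event.onset_ms for r in short_records],
            "event_condition": [r.event_condition for r in short_records],
            "step_side": [r.final_side for r in short_records],
        }
    )
    ev = ev[ev["event_condition"] != "UNDEFINED"]
    traces = er_emg(p_right, p_left, ev)

    cong = traces["C(C)-relevant"]
    window = (cong.time_ms > 120) & (cong.time_ms < 600)
    assert cong.delta[window].min() > 0  # lateralised to the step side throughout

    incong = next(traces[c] for c in ("I(C)-relevant", "I(I)-relevant") if c in traces)
    d, t = incong.delta, incong.time_ms
    early = d[(t > 120) & (t < 180)]
    late = d[(t > 300) & (t < 600)]
    assert early.mean() < 0  # initial burst follows the (wrong) location side
    assert late.min() > 0
    crossings = t[:-1][(np.sign(d[:-1]) < 0) & (np.sign(d[1:]) >= 0)]
    crossings = crossings[(crossings > 100) & (crossings < 400)]
    assert len(crossings) and abs(crossings[0] - PARAMS.emg_exchange_ms) < 100


def test_silent_emg_envelopes_give_flat_delta(short_records):
    silent = replace(PARAMS, emg_burst_amp=0.0, emg_other_amp=0.0, emg_tonic=0.0)
    rec, _ = synth_emg(short_records, silent, seed=5)
    p_right = emg_power(rec.get("EMG_TA_R"), rec.get("EMG_GC_R"))
    p_left = emg_power(rec.get("EMG_TA_L"), rec.get("EMG_GC_L"))
    delta = p_right.data - p_left.data
    assert np.abs(delta).max() < 10 * silent.emg_sensor_noise_sd**2


def test_acc_noiseless_peaks_sit_at_generated_latencies(short_records):
    clean = replace(PARAMS, acc_noise_sd=0.0)
    rec, truth = synth_acc(short_records, clean, seed=6)
    x = rec.get("ACC_X")
    fs = x.fs
    r = short_records[2]
    i0 = int(round(r.event.onset_ms * fs / 1000))
    seg = x.data[i0 : i0 + int(1.5 * fs)]
    polarity = 1.0 if r.final_side == 0 else -1.0
    apa_idx = int(np.argmax(polarity * seg))
    assert apa_idx * 1000 / fs == pytest.approx(r.apa_ms, abs=1000 / fs)
    foot_idx = int(np.argmin(polarity * seg))
    assert foot_idx * 1000 / fs == pytest.approx(r.footoff_ms, abs=1000 / fs)
    del truth


def test_subject_gains_are_lognormal_median_one():
    gains = subject_gains(replace(PARAMS, n_subjects=4001), seed=0)
    assert gains.shape == (4001,)
    assert np.median(gains) == pytest.approx(1.0, rel=0.05)
    assert (gains > 0).all()


def test_ground_truth_covers_every_trial(short_records):
    truth = ground_truth_frame(short_records, PARAMS)
    assert len(truth) == len(short_records)
    irrelevant = truth[~truth["relevant"] & (truth["sequence_condition"] != "C(C)")]
    assert (irrelevant["dip_depth_frac"] == 0).all()


def test_write_dataset_round_trip(tmp_path, short_records, short_events):
    recordings, truth = synth_subject(short_records, PARAMS, seed=7)
    paths = write_dataset(recordings, truth, short_events, tmp_path / "ds")
    assert set(paths) == {"eeg", "emg", "acc", "events", "ground_truth"}
    back = read_edf(paths["eeg"])
    assert back.labels == ["O1", "O2", "Cz"]
    orig = recordings["eeg"].get("O1").data
    step = 2 * np.abs(orig).max() / 65535
    assert np.abs(back.get("O1").data[: orig.size] - orig).max() <= step * 1.01
    events_back = pd.read_csv(paths["events"])
    assert len(events_back) == len(short_events)
    # regeneration with the logged seed reproduces the files byte for byte
    recordings2, truth2 = synth_subject(short_records, PARAMS, seed=7)
    write_dataset(recordings2, truth2, short_events, tmp_path / "ds2")
    assert (tmp_path / "ds" / "eeg.edf").read_bytes() == (tmp_path / "ds2" / "eeg.edf").read_bytes()


def test_synth_params_validation():
    with pytest.raises(ValueError):
        SynthParams(alpha_freq_hz=20.0)
    with pytest.raises(ValueError):
        SynthParams(n_subjects=0)
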