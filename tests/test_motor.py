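"""EMG power formula, lateralisation traces and accelerometric step timing."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfiltfilt

from arcsim.motor import (
    acc_step_timing,
    emg_power,
    er_emg,
    label_performance,
    rt_summary_from_timing,
)
from arcsim.physio_io import Channel
from arcsim.synth_physio import SynthParams, synth_acc

FS = 1024.0


def _band_noise(n, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    sos = butter(3, [20.0, 500.0], btype="bandpass", fs=FS, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return sd * x / x.std()


def test_emg_power_of_constant_envelope_noise_is_rms_squared():
    r = 3.0
    x1 = Channel("a", _band_noise(int(20 * FS), 0, sd=r), FS)
    x2 = Channel("b", _band_noise(int(20 * FS), 1, sd=r), FS)
    p = emg_power(x1, x2)
    mid = p.data[int(2 * FS) : int(18 * FS)]
    assert mid.mean() == pytest.approx(r**2, rel=0.05)


def test_emg_power_scaling_and_symmetry():
    x1 = Channel("a", _band_noise(int(4 * FS), 2), FS)
    x2 = Channel("b", _band_noise(int(4 * FS), 3), FS)
    base = emg_power(x1, x2).data
    doubled = emg_power(
        Channel("a", 2 * x1.data, FS), Channel("b", 2 * x2.data, FS)
    ).data
    assert np.allclose(doubled, 4 * base, rtol=1e-9)
    swapped = emg_power(x2, x1).data
    assert np.allclose(swapped, base)
    zero = emg_power(Channel("a", np.zeros(4096), FS), Channel("b", np.zeros(4096), FS))
    assert np.allclose(zero.data, 0.0)


def test_emg_power_rejects_mismatched_inputs():
    a = Channel("a", np.zeros(1024), 1024.0)
    with pytest.raises(ValueError):
        emg_power(a, Channel("b", np.zeros(1024), 512.0))
    with pytest.raises(ValueError):
        emg_power(a, Channel("b", np.zeros(2048), 1024.0))


def test_er_emg_identical_sides_has_zero_delta():
    x = Channel("p", np.abs(_band_noise(int(30 * FS), 4)) + 1.0, FS)
    ev = pd.DataFrame(
        {
            "onset_ms": [8000.0, 16000.0],
            "event_condition": ["A", "A"],
            "step_side": [0, 1],
        }
    )
    traces = er_emg(x, Channel("q", x.data.copy(), FS), ev)
    assert np.allclose(traces["A"].delta, 0.0)
    assert traces["A"].n == 2


@pytest.fixture(scope="module")
def separated_records(short_design):
    """Noise-free latencies: lobes well separated, detection can be exact."""
    from arcsim.behavior_sim import AgentParams, simulate_session

    agent = AgentParams(apa_latency_sd_ms=20.0, footoff_sd_ms=0.0)
    return simulate_session(short_design, agent, 5)


def _acc_fixture(records, noise=None):
    params = SynthParams() if noise is None else replace(SynthParams(), acc_noise_sd=noise)
    rec, truth = synth_acc(records, params, seed=11)
    events = pd.DataFrame(
        {
            "index": [r.event.index for r in records],
            "onset_ms": [r.event.onset_ms for r in records],
            "event_condition": [r.event_condition for r in records],
            "symbol": [r.event.stimulus.symbol_q for r in records],
            "relevant": [r.relevant for r in records],
        }
    )
    return rec, truth, events


def test_step_timing_noiseless_is_sample_exact(separated_records):
    rec, truth, events = _acc_fixture(separated_records, noise=0.0)
    timing = acc_step_timing(rec, events)
    merged = events.merge(timing, on="index")
    assert merged["resolved"].all()
    apa_err = np.abs(merged["apa_ms"] - truth["apa_ms"].values)
    foot_err = np.abs(merged["footoff_ms"] - truth["footoff_ms"].values)
    # exact up to sampling and the slight peak pull the 5 Hz low-pass gives
    # the two opposite-signed lobes on each other: within two samples
    assert apa_err.max() <= 2 * 1000.0 / 256.0
    assert foot_err.max() <= 2 * 1000.0 / 256.0
    assert (merged["step_side"].values == truth["step_side"].values).all()


def test_step_timing_under_default_noise(separated_records):
    rec, truth, events = _acc_fixture(separated_records)
    timing = acc_step_timing(rec, events)
    merged = events.merge(timing, on="index")
    res = merged[merged["resolved"]]
    assert len(res) >= 0.95 * len(merged)
    errs = np.abs(merged["apa_ms"].values - truth["apa_ms"].values)
    assert np.nanmedian(errs) <= 10.0


def test_polarity_flip_detects_opposite_side(separated_records):
    rec, truth, events = _acc_fixture(separated_records, noise=0.0)
    flipped = Channel("ACC_X", -rec.get("ACC_X").data, rec.get("ACC_X").fs)
    timing = acc_step_timing(flipped, events)
    assert (timing["step_side"].values == 1 - truth["step_side"].values).all()


def test_flat_trace_is_flagged_unresolved():
    ev = pd.DataFrame({"index": [0], "onset_ms": [5000.0], "event_condition": ["A"]})
    timing = acc_step_timing(Channel("ACC_X", np.zeros(int(20 * 256)), 256.0), ev)
    assert not timing["resolved"].iloc[0]
    assert np.isnan(timing["apa_ms"].iloc[0])


def test_performance_labels_match_simulator_relevance(separated_records):
    rec, _, events = _acc_fixture(separated_records, noise=0.0)
    timing = acc_step_timing(rec, events)
    labelled = label_performance(timing, events)
    res = labelled[labelled["resolved"].astype(bool)]
    assert (res["relevant_detected"].astype(bool) == res["relevant"]).all()


def test_rt_summary_reports_conditions(separated_records):
    rec, _, events = _acc_fixture(separated_records, noise=0.0)
    labelled = label_performance(acc_step_timing(rec, events), events)
    summary = rt_summary_from_timing(labelled)
    assert summary["n_trials"].sum() == len(events)  # includes the UNDEFINED first trial
    assert (summary["footoff_mean_ms"] > summary["apa_mean_ms"]).all()
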