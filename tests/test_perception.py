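"""Signal detection, sensitivity integrals and threshold mediation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from arcsim.perception import (
    NoFixedPointError,
    PerceptionParams,
    ThresholdState,
    classify,
    sample_signal,
    sensitivity,
    signal_density,
    threshold_fixed_point,
    update_threshold,
)

SYMMETRIC = PerceptionParams(sigma0=0.5, sigma1=0.5, kappa=0.25, vth_init=0.5)


def trapezoid_sensitivity(theta, vth, params):
    """Independent oracle: prior-odds weighting of trapezoid-integrated masses."""
    def mass(mean, sigma, lo, hi):
        n = max(int(np.ceil((hi - lo) / (sigma / 1000.0))), 2)
        xs = np.linspace(lo, hi, n + 1)
        ys = np.exp(-0.5 * ((xs - mean) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        return np.trapezoid(ys, xs)

    below_c = mass(params.V0, params.sigma0, params.V0 - 8 * params.sigma0, vth)
    above_i = mass(params.V1, params.sigma1, vth, params.V1 + 8 * params.sigma1)
    if theta == 1:
        return 1.0 / (1.0 + (1.0 / params.kappa) * below_c / above_i)
    return 1.0 / (1.0 + params.kappa * above_i / below_c)


def test_signal_density_is_unit_area_gaussian():
    p = SYMMETRIC
    assert signal_density(p.V1, 1, p) == pytest.approx(1 / (p.sigma1 * np.sqrt(2 * np.pi)))
    assert signal_density(p.V0 + 0.3, 0, p) == pytest.approx(signal_density(p.V0 - 0.3, 0, p))
    area, _ = quad(lambda v: signal_density(v, 0, p), -10, 10)
    assert area == pytest.approx(1.0, abs=1e-9)


def test_sample_signal_moments_and_determinism():
    p = SYMMETRIC
    draws = sample_signal(1, p, np.random.default_rng(0), size=10_000)
    assert abs(draws.mean() - p.V1) < 3 * p.sigma1 / np.sqrt(10_000)
    assert draws.var() == pytest.approx(p.sigma1**2, rel=0.05)
    a = sample_signal(0, p, np.random.default_rng(7))
    b = sample_signal(0, p, np.random.default_rng(7))
    assert a == b


def test_classifier_threshold_rule_and_error_rate():
    assert classify(1.5, 0.5) == 1
    assert classify(-0.5, 0.5) == 0
    assert classify(0.5, 0.5) == 1  # tie goes to incongruent
    # with the symmetric configuration each class is misclassified with
    # Gaussian tail mass Phi(-1) = 0.1587
    p = SYMMETRIC
    rng = np.random.default_rng(42)
    n = 100_000
    miss = np.mean(sample_signal(1, p, rng, size=n) < 0.5)
    fa = np.mean(sample_signal(0, p, rng, size=n) >= 0.5)
    expected = norm.cdf(-1.0)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(miss - expected) < 4 * se
    assert abs(fa - expected) < 4 * se


def test_sensitivity_matches_hand_computed_example():
    # V0=0, V1=1, sigma=0.5, vth=0.5, kappa=0.25: both masses are 0.8413,
    # so S(incongruent) = 1/(1 + 4) = 0.2 and S(congruent) = 1/1.25 = 0.8
    assert sensitivity(1, 0.5, SYMMETRIC) == pytest.approx(0.2, abs=1e-4)
    assert sensitivity(0, 0.5, SYMMETRIC) == pytest.approx(0.8, abs=1e-4)


def test_sensitivity_limits_and_range():
    p = SYMMETRIC
    assert sensitivity(1, -1e6, p) == pytest.approx(1.0)
    assert sensitivity(0, 1e6, p) == pytest.approx(1.0)
    for vth in np.linspace(-1.0, 2.0, 13):
        for theta in (0, 1):
            assert 0.0 < sensitivity(theta, vth, p) <= 1.0


@pytest.mark.parametrize("vth", [-0.25, 0.2, 0.5, 0.8, 1.3])
@pytest.mark.parametrize("kappa", [0.1, 0.25, 1.0])
def test_sensitivity_agrees_with_numerical_integration(vth, kappa):
    params = PerceptionParams(sigma0=0.3, sigma1=0.45, kappa=kappa)
    for theta in (0, 1):
        oracle = trapezoid_sensitivity(theta, vth, params)
        assert sensitivity(theta, vth, params) == pytest.approx(oracle, abs=1e-6)


def test_threshold_single_step_updates_are_exact():
    p = PerceptionParams(retention=1.0, gamma=0.05, vth_init=0.5)
    s = ThresholdState.initial(p)
    assert update_threshold(s, 0, p).vth == pytest.approx(0.55)
    assert update_threshold(s, 1, p).vth == pytest.approx(0.45)
    assert update_threshold(s, 0, p).history == (0.5,)


def test_threshold_converges_geometrically_to_fixed_point():
    p = PerceptionParams(retention=0.9, gamma=0.1, vth_init=0.5)
    fp = threshold_fixed_point(0, p)
    assert fp == pytest.approx(1.0)
    assert threshold_fixed_point(1, p) == pytest.approx(-1.0)
    s = ThresholdState.initial(p)
    gaps = []
    for _ in range(40):
        gaps.append(abs(s.vth - fp))
        s = update_threshold(s, 0, p)
    assert abs(s.vth - fp) < 1e-2
    ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
    assert np.allclose(ratios, p.retention, atol=1e-9)  # geometric, rate = retention


def test_threshold_fixed_point_edge_cases():
    assert threshold_fixed_point(0, PerceptionParams(retention=0.9, gamma=0.0)) == 0.0
    with pytest.raises(NoFixedPointError):
        threshold_fixed_point(0, PerceptionParams(retention=1.0, gamma=0.1))


def test_threshold_drift_modulates_detection_monotonically():
    # congruent repetitions raise the threshold, which strictly lowers the
    # chance of detecting a subsequent incongruent signal (and vice versa)
    p = PerceptionParams()
    s = ThresholdState.initial(p)
    detect = [norm.sf(s.vth, loc=p.V1, scale=p.sigma1)]
    for _ in range(10):
        s = update_threshold(s, 0, p)
        detect.append(norm.sf(s.vth, loc=p.V1, scale=p.sigma1))
    assert all(b < a for a, b in zip(detect, detect[1:]))

    s = ThresholdState.initial(p)
    false_alarm = [norm.sf(s.vth, loc=p.V0, scale=p.sigma0)]
    for _ in range(10):
        s = update_threshold(s, 1, p)
        false_alarm.append(norm.sf(s.vth, loc=p.V0, scale=p.sigma0))
    assert all(b > a for a, b in zip(false_alarm, false_alarm[1:]))


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.99), st.floats(min_value=0.0, max_value=0.5))
def test_fixed_point_is_invariant_under_update(retention, gamma):
    p = PerceptionParams(retention=retention, gamma=gamma, vth_init=0.0)
    fp = threshold_fixed_point(0, p)
    s = ThresholdState(vth=fp)
    assert update_threshold(s, 0, p).vth == pytest.approx(fp, abs=1e-12)


def test_parameter_validation():
    with pytest.raises(ValueError):
        PerceptionParams(V0=1.0, V1=0.0)
    with pytest.raises(ValueError):
        PerceptionParams(sigma0=-0.1)
    with pytest.raises(ValueError):
        PerceptionParams(retention=1.5)
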