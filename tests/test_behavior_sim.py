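"""Closed-loop agent: respond-then-adapt structure, error and cost accounting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from arcsim.behavior_sim import (
    EVENT_CONDITIONS,
    AgentParams,
    error_rates_by_condition,
    label_event_conditions,
    records_to_frame,
    rt_summary_by_condition,
    simulate_session,
    simulate_trial,
)
from arcsim.perception import PerceptionParams, ThresholdState
from arcsim.task_design import SessionDesign, session_i, session_ii


def test_respond_then_adapt_structure(short_records):
    for r in short_records:
        assert r.initial_side == r.event.stimulus.location_p
        assert (r.final_side != r.initial_side) == (r.theta_hat == 1)
        assert r.relevant == (r.final_side == r.event.stimulus.symbol_q)


def test_perfect_discrimination_makes_no_errors():
    # widely separated classes and a frozen threshold: every trial relevant
    p = PerceptionParams(sigma0=0.01, sigma1=0.01, retention=1.0, gamma=0.0)
    agent = AgentParams(perception=p)
    records = simulate_session(session_i(seed=3), agent, 8)
    assert all(r.relevant for r in records)
    rates = error_rates_by_condition(records)
    assert (rates["error_rate"].dropna() == 0).all()


def test_missed_detection_produces_location_compatible_error(agent):
    # forcing theta_hat = 0 removes adaptation: every incongruent trial is
    # an error, so the error rate equals the incongruent frequency exactly
    no_adapt = replace(agent, force_theta_hat=0)
    records = simulate_session(session_i(seed=3), no_adapt, 8)
    for r in records:
        assert r.final_side == r.event.stimulus.location_p
    errors = sum(not r.relevant for r in records)
    assert errors / len(records) == pytest.approx(0.2)


def test_cost_accounting_tracks_perceived_congruency(agent):
    model_shannon = -math.log(0.2)
    records = simulate_session(session_i(seed=1), agent, 11)
    for r in records:
        expected = agent.cost_baseline_nats + (model_shannon if r.theta_hat else 0.0)
        assert r.cost_nats == pytest.approx(expected)


def test_huge_sensory_noise_degrades_to_chance_classification(agent):
    noisy = replace(
        agent,
        perception=PerceptionParams(sigma0=1e6, sigma1=1e6, retention=1.0, gamma=0.0),
    )
    records = simulate_session(session_i(seed=2), noisy, 3)
    frac_detect = np.mean([r.theta_hat for r in records])
    assert 0.4 < frac_detect < 0.6  # threshold is irrelevant at infinite spread


def test_event_condition_labels(short_records):
    labels = {r.event_condition for r in short_records}
    assert labels <= set(EVENT_CONDITIONS) | {"UNDEFINED"}
    relabelled = label_event_conditions(short_records)
    for r in relabelled:
        if r.event_condition != "UNDEFINED":
            seq, perf = r.event_condition.split("-")
            assert seq == r.event.sequence_condition
            assert perf == ("relevant" if r.relevant else "irrelevant")
    assert len(EVENT_CONDITIONS) == 8


def test_all_relevant_session_populates_only_relevant_labels():
    p = PerceptionParams(sigma0=0.01, sigma1=0.01, retention=1.0, gamma=0.0)
    records = simulate_session(session_ii(seed=2), AgentParams(perception=p), 4)
    labels = {r.event_condition for r in records} - {"UNDEFINED"}
    assert labels == {"C(C)-relevant"}


def test_error_rates_from_hand_labelled_fixture(agent):
    # 20-trial session, counted by hand from the trial table
    records = simulate_session(
        SessionDesign(label="I", n_congruent=16, n_incongruent=4, seed=11), agent, 5
    )
    frame = records_to_frame(records)
    rates = error_rates_by_condition(records).set_index("sequence_condition")
    for cond in ("C(C)", "C(I)", "I(C)", "I(I)"):
        sel = frame[frame["sequence_condition"] == cond]
        assert rates.loc[cond, "n_trials"] == len(sel)
        if len(sel):
            assert rates.loc[cond, "error_rate"] == pytest.approx(
                1.0 - sel["relevant"].mean()
            )
        else:
            assert np.isnan(rates.loc[cond, "error_rate"])


def test_noiseless_reversal_cost_appears_in_foot_off_contrast():
    p = PerceptionParams(sigma0=0.01, sigma1=0.01, retention=1.0, gamma=0.0)
    agent = AgentParams(
        perception=p, apa_latency_sd_ms=0.0, footoff_sd_ms=0.0, reversal_cost_ms=100.0
    )
    records = simulate_session(session_i(seed=6), agent, 9)
    rt = rt_summary_by_condition(records).set_index("event_condition")
    delta = rt.loc["I(I)-relevant", "footoff_mean_ms"] - rt.loc["C(C)-relevant", "footoff_mean_ms"]
    assert delta == pytest.approx(100.0)
    assert rt.loc["I(I)-relevant", "apa_mean_ms"] == rt.loc["C(C)-relevant", "apa_mean_ms"]


def test_identical_seed_replays_identical_records(agent):
    a = simulate_session(session_i(seed=4), agent, 13)
    b = simulate_session(session_i(seed=4), agent, 13)
    assert a == b


def test_sequence_effects_over_seeds(agent):
    """Switch trials err more than repeat trials; cost separates error types."""
    switch_rates, repeat_rates = [], []
    ic_costs, ci_costs = [], []
    for seed in range(8):
        records = simulate_session(session_i(seed=seed), agent, 300 + seed)
        er = error_rates_by_condition(records).set_index("sequence_condition")
        switch_rates.append(
            er.loc[["I(C)", "C(I)"], "n_errors"].sum() / er.loc[["I(C)", "C(I)"], "n_trials"].sum()
        )
        repeat_rates.append(
            er.loc[["C(C)", "I(I)"], "n_errors"].sum() / er.loc[["C(C)", "I(I)"], "n_trials"].sum()
        )
        for r in records:
            if not r.relevant:
                if r.event.sequence_condition == "I(C)":
                    ic_costs.append(r.cost_nats)
                elif r.event.sequence_condition == "C(I)":
                    ci_costs.append(r.cost_nats)
    assert np.mean(switch_rates) > np.mean(repeat_rates)
    assert np.mean(ic_costs) < np.mean(ci_costs)


def test_mean_cost_ordering_across_conditions(agent):
    costs = {"I(I)-relevant": [], "C(C)-relevant": [], "C(I)": [], "C(C)": []}
    for seed in range(8):
        for r in simulate_session(session_i(seed=seed), agent, 700 + seed):
            if r.event_condition in costs:
                costs[r.event_condition].append(r.cost_nats)
            if r.event.sequence_condition in ("C(I)", "C(C)"):
                costs[r.event.sequence_condition].append(r.cost_nats)
    assert np.mean(costs["I(I)-relevant"]) > np.mean(costs["C(C)-relevant"])
    assert np.mean(costs["C(I)"]) > np.mean(costs["C(C)"])


def test_agent_parameter_validation():
    with pytest.raises(ValueError):
        AgentParams(update_on="oracle")
    with pytest.raises(ValueError):
        AgentParams(apa_latency_mean_ms=-10.0)


def test_single_trial_threads_threshold_state(agent):
    state = ThresholdState.initial(agent.perception)
    rng = np.random.default_rng(0)
    from arcsim.task_design import generate_session

    ev = generate_session(session_i(seed=0))[0]
    record, new_state = simulate_trial(state, ev, agent, rng)
    assert len(new_state.history) == 1
    assert new_state.history[0] == state.vth
    assert record.footoff_ms > record.apa_ms > 0
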