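"""Closed-loop trial simulation of the ARC agent.

Each trial unfolds respond-then-adapt:

1. The stimulus location triggers the rapid anticipatory response
   (``initial_side = location_p``) unconditionally — this is the APA, whose
   latency is congruency-independent by construction.
2. A sensory congruency signal is sampled and thresholded, giving the
   perceived congruency ``theta_hat``.
3. If ``theta_hat = 1`` the reversal operator is applied, so the executed
   side is the mirror of the rapid one; the reversal adds a fixed motor cost
   to the foot-off latency.
4. Cognitive cost is booked as a baseline plus the free energy of the
   *perceived* trial: nothing extra when the trial is taken to be congruent,
   the Shannon surprise of the reversed code when incongruence is perceived
   and active inference engages.  A missed incongruent trial therefore
   produces a fast, cheap, *wrong* response (the I(C) error), while a false
   alarm on a congruent trial produces a costly conflicted one (the C(I)
   error).
5. The discrimination threshold is mediated by the perceived congruency
   (the agent has no oracle access to the true label).

A response is *relevant* (correct) when the executed side matches the
instructed symbol side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arc_core import InternalModel, free_energy
from .perception import (
    PerceptionParams,
    ThresholdState,
    classify,
    sample_signal,
    update_threshold,
)
from .task_design import (
    SEQUENCE_CONDITIONS,
    UNDEFINED,
    SessionDesign,
    Stimulus,
    TrialEvent,
    generate_session,
)

__all__ = [
    "AgentParams",
    "TrialRecord",
    "error_rates_by_condition",
    "EVENT_CONDITIONS",
    "label_event_conditions",
    "records_to_frame",
    "rt_summary_by_condition",
    "simulate_session",
    "simulate_trial",
]

#: the eight event conditions: sequence condition x performance class
EVENT_CONDITIONS = tuple(
    f"{seq}-{perf}" for seq in SEQUENCE_CONDITIONS for perf in ("relevant", "irrelevant")
)


@dataclass(frozen=True)
class AgentParams:
    """Perceptual, timing and cost parameters of the simulated agent.

    APA latency defaults to 300 ms (the early postural peak), foot-off to a
    500 ms base delayed by ``reversal_cost_ms`` (default 100 ms) whenever the
    reversal is applied.

    ``update_on`` selects what drives the threshold-mediation rule.  The
    default, ``"true"``, consolidates the threshold on the congruency as
    resolved by trial end (semantic processing and outcome feedback always
    reveal it); classification itself remains purely perceptual.  The
    alternative ``"perceived"`` feeds the classifier's own output back into
    the rule — a closed loop in which a false alarm lowers the threshold
    and so breeds further false alarms; for realistic error rates that loop
    has a reachable all-error absorbing state, which no behaving cohort
    shows, so it is offered for sensitivity analyses rather than as the
    default.
    """

    perception: PerceptionParams = field(default_factory=PerceptionParams)
    apa_latency_mean_ms: float = 300.0
    apa_latency_sd_ms: float = 20.0
    footoff_base_ms: float = 500.0
    footoff_sd_ms: float = 50.0
    reversal_cost_ms: float = 100.0
    cost_baseline_nats: float = 0.5
    update_on: str = "true"
    force_theta_hat: int | None = None  # 0/1 pins perception (ablation runs)

    def __post_init__(self) -> None:
        if min(self.apa_latency_mean_ms, self.footoff_base_ms) <= 0:
            raise ValueError("latency means must be positive")
        if min(self.apa_latency_sd_ms, self.footoff_sd_ms) < 0:
            raise ValueError("latency sds must be non-negative")
        if self.update_on not in ("perceived", "true"):
            raise ValueError("update_on must be 'perceived' or 'true'")

    def internal_model(self) -> InternalModel:
        return InternalModel.from_kappa(max(self.perception.kappa, 1e-6))


@dataclass(frozen=True)
class TrialRecord:
    """Everything the simulator knows about one executed trial."""

    event: TrialEvent
    v: float
    theta_hat: int
    initial_side: int
    final_side: int
    relevant: bool
    apa_ms: float
    footoff_ms: float
    cost_nats: float
    event_condition: str = UNDEFINED


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian latency truncated at zero (redraw; latencies stay positive)."""
    if sd == 0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    return mean


def simulate_trial(
    state: ThresholdState,
    event: TrialEvent,
    agent: AgentParams,
    rng: np.random.Generator,
) -> tuple[TrialRecord, ThresholdState]:
    """Run one trial and return its record plus the updated threshold state."""
    stim = event.stimulus
    params = agent.perception

    v = float(sample_signal(stim.congruency_theta, params, rng))
    theta_hat = classify(v, state.vth)
    if agent.force_theta_hat is not None:
        theta_hat = agent.force_theta_hat

    initial_side = stim.location_p
    final_side = initial_side ^ theta_hat  # Psi applied iff incongruence perceived
    relevant = final_side == stim.symbol_q

    # cost of the trial as experienced: free energy of the perceived stimulus,
    # with active inference applied whenever incongruence was perceived
    perceived = Stimulus(location_p=stim.location_p, symbol_q=stim.location_p ^ theta_hat)
    cost = agent.cost_baseline_nats + free_energy(
        perceived, adapted=True, model=agent.internal_model()
    ).total

    apa = _truncated_normal(rng, agent.apa_latency_mean_ms, agent.apa_latency_sd_ms)
    footoff_mean = agent.footoff_base_ms + agent.reversal_cost_ms * theta_hat
    footoff = _truncated_normal(rng, footoff_mean, agent.footoff_sd_ms)
    footoff = max(footoff, apa + 1.0)  # foot-off follows the postural peak

    driver = theta_hat if agent.update_on == "perceived" else stim.congruency_theta
    new_state = update_threshold(state, driver, params)

    record = TrialRecord(
        event=event,
        v=v,
        theta_hat=theta_hat,
        initial_side=initial_side,
        final_side=final_side,
        relevant=relevant,
        apa_ms=apa,
        footoff_ms=footoff,
        cost_nats=cost,
    )
    return record, new_state


def simulate_session(
    design: SessionDesign,
    agent: AgentParams,
    seed: int | np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate a whole session, threading threshold state across trials.

    ``seed`` controls the agent's perceptual/timing noise; the trial sequence
    itself is drawn from ``design.seed``.  Records come back with their
    eight-way event-condition labels attached.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = generate_session(design)
    state = ThresholdState.initial(agent.perception)
    records: list[TrialRecord] = []
    for ev in events:
        rec, state = simulate_trial(state, ev, agent, rng)
        records.append(rec)
    return label_event_conditions(records)


def label_event_conditions(records: list[TrialRecord]) -> list[TrialRecord]:
    """Attach the eight-way label: sequence condition x relevant/irrelevant.

    The first trial of a session has no sequence condition and keeps the
    UNDEFINED label; it is excluded from every conditioned summary.
    """
    out = []
    for rec in records:
        seq = rec.event.sequence_condition
        if seq == UNDEFINED:
            label = UNDEFINED
        elif seq not in SEQUENCE_CONDITIONS:
            raise ValueError(f"record has unknown sequence condition {seq!r}")
        else:
            label = f"{seq}-{'relevant' if rec.relevant else 'irrelevant'}"
        out.append(replace(rec, event_condition=label))
    return out


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flat per-trial table (the `simulate` output format)."""
    return pd.DataFrame(
        {
            "index": [r.event.index for r in records],
            "onset_ms": [r.event.onset_ms for r in records],
            "location": [r.event.stimulus.location_p for r in records],
            "symbol": [r.event.stimulus.symbol_q for r in records],
            "congruency": [r.event.stimulus.congruency_theta for r in records],
            "sequence_condition": [r.event.sequence_condition for r in records],
            "v": [r.v for r in records],
            "theta_hat": [r.theta_hat for r in records],
            "initial_side": [r.initial_side for r in records],
            "final_side": [r.final_side for r in records],
            "relevant": [r.relevant for r in records],
            "apa_ms": [r.apa_ms for r in records],
            "footoff_ms": [r.footoff_ms for r in records],
            "cost_nats": [r.cost_nats for r in records],
            "event_condition": [r.event_condition for r in records],
        }
    )


def _labelled(records: list[TrialRecord]) -> list[TrialRecord]:
    # session-initial trials have no sequence condition and are excluded by
    # design; any other unlabeled record means labelling never ran
    missing = sum(
        r.event_condition == UNDEFINED and r.event.sequence_condition != UNDEFINED
        for r in records
    )
    if missing:
        raise ValueError(f"{missing} records lack event-condition labels")
    return [r for r in records if r.event_condition != UNDEFINED]


def error_rates_by_condition(records: list[TrialRecord]) -> pd.DataFrame:
    """Irrelevant-response fraction per sequence condition.

    Returns one row per sequence condition with columns ``n_trials``,
    ``n_errors`` and ``error_rate``; a condition with no trials gets a NaN
    rate (undefined, not zero).
    """
    labelled = _labelled(records)
    rows = []
    for cond in SEQUENCE_CONDITIONS:
        trials = [r for r in labelled if r.event.sequence_condition == cond]
        n = len(trials)
        errors = sum(not r.relevant for r in trials)
        rows.append(
            {
                "sequence_condition": cond,
                "n_trials": n,
                "n_errors": errors,
                "error_rate": errors / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rt_summary_by_condition(records: list[TrialRecord]) -> pd.DataFrame:
    """APA and foot-off latency mean +- SEM (and mean cost) per event condition."""
    labelled = _labelled(records)
    rows = []
    for cond in EVENT_CONDITIONS:
        sel = [r for r in labelled if r.event_condition == cond]
        n = len(sel)
        row: dict[str, object] = {"event_condition": cond, "n_trials": n}
        if n:
            apa = np.array([r.apa_ms for r in sel])
            foot = np.array([r.footoff_ms for r in sel])
            cost = np.array([r.cost_nats for r in sel])
            row.update(
                apa_mean_ms=apa.mean(),
                apa_sem_ms=apa.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan"),
                footoff_mean_ms=foot.mean(),
                footoff_sem_ms=foot.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan"),
                cost_mean_nats=cost.mean(),
            )
        else:
            row.update(
                apa_mean_ms=float("nan"),
                apa_sem_ms=float("nan"),
                footoff_mean_ms=float("nan"),
                footoff_sem_ms=float("nan"),
                cost_mean_nats=float("nan"),
            )
        rows.append(row)
    return pd.DataFrame(rows)
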