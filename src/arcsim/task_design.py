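"""Simon-task session designs and sequential-congruency labelling.

A Simon stimulus carries two binary attributes: the side it appears on
(*location*, ``p``) and the side it instructs (*symbol*, ``q``).  The trial is
congruent (``theta = 0``) when the two agree and incongruent (``theta = 1``)
when they conflict.  The four ``(p, q)`` combinations enumerate the four
stimulus images of the step-motion task.

Two session layouts are provided:

* Session I  — the Simon task proper: 200 trials, 160 congruent and 40
  incongruent, shuffled.
* Session II — the non-conflict control: 100 congruent trials only.

Stimuli are shown for 500 ms with inter-trial intervals drawn uniformly from
3000–5000 ms.  Trials after the first are labelled by the congruency of the
current and previous trial — ``C(C)``, ``C(I)``, ``I(C)``, ``I(I)`` — the
sequence conditions under which behavioural and physiological measures are
later aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

UNDEFINED = "UNDEFINED"
SEQUENCE_CONDITIONS = ("C(C)", "C(I)", "I(C)", "I(I)")

#: time the stimulus stays on screen, ms
STIMULUS_DURATION_MS = 500.0
#: inter-trial interval range (fixation cross), ms
ITI_RANGE_MS = (3000.0, 5000.0)
#: onset of the first trial, leaving room for a -500 ms baseline window
FIRST_ONSET_MS = 2000.0


class InvalidDesignError(ValueError):
    """Session design violates its invariants (e.g. negative trial counts)."""


@dataclass(frozen=True)
class Stimulus:
    """One Simon stimulus: location side, symbol side and their congruency."""

    location_p: int  # 0 = right, 1 = left
    symbol_q: int    # 0 = "R", 1 = "L"

    def __post_init__(self) -> None:
        if self.location_p not in (0, 1) or self.symbol_q not in (0, 1):
            raise ValueError("location and symbol must be binary")

    @property
    def congruency_theta(self) -> int:
        """0 when location and symbol agree, 1 when they conflict."""
        return int(self.location_p != self.symbol_q)


@dataclass(frozen=True)
class SessionDesign:
    """Trial counts and timing of one task session."""

    label: str = "I"
    n_congruent: int = 160
    n_incongruent: int = 40
    stimulus_duration_ms: float = STIMULUS_DURATION_MS
    iti_range_ms: tuple[float, float] = ITI_RANGE_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_congruent < 0 or self.n_incongruent < 0:
            raise InvalidDesignError("trial counts must be non-negative")
        if self.label == "II" and self.n_incongruent != 0:
            raise InvalidDesignError("Session II is congruent-only")
        lo, hi = self.iti_range_ms
        if lo > hi:
            raise InvalidDesignError("iti_range low must not exceed high")

    @property
    def n_trials(self) -> int:
        return self.n_congruent + self.n_incongruent


def session_i(seed: int = 0) -> SessionDesign:
    """The 200-trial Simon session (160 congruent / 40 incongruent)."""
    return SessionDesign(label="I", n_congruent=160, n_incongruent=40, seed=seed)


def session_ii(seed: int = 0) -> SessionDesign:
    """The 100-trial congruent-only control session."""
    return SessionDesign(label="II", n_congruent=100, n_incongruent=0, seed=seed)


@dataclass(frozen=True)
class TrialEvent:
    """A scheduled trial: onset, stimulus and sequence-condition label."""

    index: int
    onset_ms: float
    stimulus: Stimulus
    sequence_condition: str = UNDEFINED


def _stimulus_multiset(n_congruent: int, n_incongruent: int) -> list[Stimulus]:
    """Balanced multiset of the four stimulus types.

    The two congruent variants (and the two incongruent ones) are split as
    evenly as the class count allows; an odd remainder goes to the (p=0)
    variant.
    """
    out: list[Stimulus] = []
    for n, theta in ((n_congruent, 0), (n_incongruent, 1)):
        half, rem = divmod(n, 2)
        for p, count in ((0, half + rem), (1, half)):
            q = p ^ theta
            out.extend(Stimulus(location_p=p, symbol_q=q) for _ in range(count))
    return out


def generate_session(design: SessionDesign) -> list[TrialEvent]:
    """Generate a seeded, shuffled trial sequence for one session.

    Order is an unconstrained uniform permutation of the balanced stimulus
    multiset; inter-onset gaps are ``stimulus_duration + U(iti_range)``.
    Returned events already carry sequence-condition labels.
    """
    rng = np.random.default_rng(design.seed)
    stimuli = _stimulus_multiset(design.n_congruent, design.n_incongruent)
    order = rng.permutation(len(stimuli))
    itis = rng.uniform(*design.iti_range_ms, size=len(stimuli))

    events: list[TrialEvent] = []
    onset = FIRST_ONSET_MS
    for k, idx in enumerate(order):
        events.append(TrialEvent(index=k, onset_ms=float(onset), stimulus=stimuli[idx]))
        onset += design.stimulus_duration_ms + itis[k]
    return label_sequence(events)


def label_sequence(trials: list[TrialEvent]) -> list[TrialEvent]:
    """Label each trial by (current, previous) congruency.

    Trial ``k > 0`` gets ``X(Y)`` with X the current and Y the previous
    congruency letter; the first trial has no predecessor and stays
    ``UNDEFINED``.
    """
    out: list[TrialEvent] = []
    prev_theta: int | None = None
    for ev in trials:
        theta = ev.stimulus.congruency_theta
        if prev_theta is None:
            label = UNDEFINED
        else:
            label = f"{'CI'[theta]}({'CI'[prev_theta]})"
        out.append(replace(ev, sequence_condition=label))
        prev_theta = theta
    return out


def incongruence_ratio(design: SessionDesign) -> float:
    """Frequency ratio kappa = incongruent / congruent trial counts."""
    if design.n_congruent == 0:
        raise InvalidDesignError("incongruence ratio undefined without congruent trials")
    return design.n_incongruent / design.n_congruent


# ---------------------------------------------------------------------------
# delimited-table interface

def events_to_frame(trials: list[TrialEvent]) -> pd.DataFrame:
    """Event table with one row per trial (times in ms from recording start)."""
    return pd.DataFrame(
        {
            "index": [t.index for t in trials],
            "onset_ms": [t.onset_ms for t in trials],
            "location": [t.stimulus.location_p for t in trials],
            "symbol": [t.stimulus.symbol_q for t in trials],
            "congruency": [t.stimulus.congruency_theta for t in trials],
            "sequence_condition": [t.sequence_condition for t in trials],
        }
    )


def frame_to_events(frame: pd.DataFrame) -> list[TrialEvent]:
    """Inverse of :func:`events_to_frame` (congruency column is re-derived)."""
    cols = ("index", "onset_ms", "location", "symbol", "sequence_condition")
    events = []
    for idx, onset, p, q, seq in zip(*(frame[c] for c in cols)):
        events.append(
            TrialEvent(
                index=int(idx),
                onset_ms=float(onset),
                stimulus=Stimulus(int(p), int(q)),
                sequence_condition=str(seq),
            )
        )
    return events
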