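"""Information-theoretic core of the ARC (action-rule cognitive control) model.

The model treats the Simon task as a two-stage coding problem.  Categorising
the four stimulus types into congruent/incongruent halves the degrees of
freedom, so the processing cost of identifying the goal-relevant state drops
by exactly one bit.  Responses are one-hot 2-vectors (right = ``(1, 0)``,
left = ``(0, 1)``); the action rule is the anti-diagonal exchange operator
``Psi``, its own inverse, which maps either response code onto its mirror.

Per-trial cognitive cost is accounted as variational free energy

    F = D_KL( Q(phi) || P(phi | Phi) )  -  log P(Phi)

whose two terms are the Bayesian surprise (inference error between the goal
code and the code implied by the rapid, location-driven response) and the
Shannon surprise (improbability of the realised final response code).  On a
congruent trial the rapid response already matches the goal, so both terms
vanish.  On an incongruent trial the agent can either leave the rapid
response uncorrected — paying a large Bayesian surprise — or apply ``Psi``
(active inference), which cancels the inference error and leaves only the
Shannon surprise of the rarer, reversed code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PSI",
    "FreeEnergyTerms",
    "InternalModel",
    "InvalidDistributionError",
    "entropy_reduction",
    "free_energy",
    "infer_symbol",
    "kl_divergence",
    "response_vector",
    "reverse",
    "shannon_entropy",
]

#: reversal operator Psi: anti-diagonal exchange, self-inverse
PSI = np.array([[0.0, 1.0], [1.0, 0.0]])

_SUM_TOL = 1e-9


class InvalidDistributionError(ValueError):
    """Probabilities are negative or do not sum to one."""


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidDistributionError("expected a non-empty 1-d probability vector")
    if np.any(p < 0):
        raise InvalidDistributionError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise InvalidDistributionError(f"probabilities sum to {p.sum()!r}, not 1")
    return p


def shannon_entropy(probabilities, base: float = 2.0) -> float:
    """Shannon entropy ``H = -sum_i p_i log p_i``; zero entries contribute 0."""
    p = _check_distribution(probabilities)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def entropy_reduction(before, after) -> float:
    """Entropy drop ``H(before) - H(after)`` in bits.

    Categorising the four Simon stimulus types into two congruency classes
    takes a uniform 4-state distribution to a uniform 2-state one: 1 bit.
    """
    return shannon_entropy(before, base=2) - shannon_entropy(after, base=2)


def response_vector(side: int) -> np.ndarray:
    """One-hot response code: side 0 (right) -> (1, 0); side 1 (left) -> (0, 1)."""
    if side not in (0, 1):
        raise ValueError(f"side must be 0 or 1, got {side!r}")
    v = np.zeros(2)
    v[side] = 1.0
    return v


def reverse(v) -> np.ndarray:
    """Apply the reversal operator Psi (exchange the two entries)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (2,):
        raise ValueError("Psi acts on 2-vectors")
    return PSI @ v


def infer_symbol(location_p: int, theta: int) -> int:
    """Presumed symbol q* from location and congruency: ``q* = p XOR theta``.

    Congruent stimuli copy the location; incongruent ones mirror it.  This
    lets the symbol side be anticipated from the fast spatial channel plus
    the 1-bit congruency signal, before semantic processing completes.
    """
    if location_p not in (0, 1) or theta not in (0, 1):
        raise ValueError("inputs must be binary")
    return location_p ^ theta


def kl_divergence(q_dist, p_dist, epsilon: float = 1e-6) -> float:
    """Kullback–Leibler divergence ``D(q || p)`` in nats, with floor smoothing.

    Both distributions are floored at ``epsilon`` and renormalised before the
    sum, so divergences between (near-)degenerate one-hot response codes stay
    finite and ordered instead of infinite.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    q = _check_distribution(q_dist)
    p = _check_distribution(p_dist)
    if q.shape != p.shape:
        raise ValueError("distributions must have equal length")
    q = np.maximum(q, epsilon)
    q /= q.sum()
    p = np.maximum(p, epsilon)
    p /= p.sum()
    return float((q * np.log(q / p)).sum())


@dataclass(frozen=True)
class FreeEnergyTerms:
    """Free-energy decomposition for one trial (all in nats)."""

    bayesian_surprise: float
    shannon_surprise: float

    @property
    def total(self) -> float:
        return self.bayesian_surprise + self.shannon_surprise


@dataclass(frozen=True)
class InternalModel:
    """Prior over final response codes, indexed by whether Psi was applied.

    ``prior[0]`` is the probability of executing the unreversed rapid
    response, ``prior[1]`` that of the reversed one.  The default ties the
    prior to the session base rates: with incongruence/congruence frequency
    ratio ``kappa``, reversals occur with probability ``kappa / (1 + kappa)``.
    """

    prior: tuple[float, float] = (0.8, 0.2)
    smoothing_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        p = np.asarray(self.prior, dtype=float)
        if self.smoothing_epsilon <= 0:
            raise ValueError("smoothing_epsilon must be positive")
        if np.any(p <= 0) or np.any(p > 1) or abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError("prior entries must lie in (0, 1] and sum to 1")

    @classmethod
    def from_kappa(cls, kappa: float, smoothing_epsilon: float = 1e-6) -> "InternalModel":
        """Prior matched to a session's incongruence/congruence ratio."""
        if kappa < 0:
            raise ValueError("kappa must be non-negative")
        p_rev = kappa / (1.0 + kappa)
        eps = smoothing_epsilon
        p_rev = min(max(p_rev, eps), 1.0 - eps)
        return cls(prior=(1.0 - p_rev, p_rev), smoothing_epsilon=eps)


def free_energy(stimulus, adapted: bool, model: InternalModel) -> FreeEnergyTerms:
    """Free-energy terms for one trial.

    Congruent (``p == q``): the rapid response is the goal response, the
    final state has occurrence probability one, and both terms are zero.

    Incongruent, *adapted* (Psi applied): the inference error cancels, the
    lower limit of the free energy is the Shannon surprise of the reversed
    code, ``-log prior[1]``.

    Incongruent, *unadapted*: the goal code and the location-compatible code
    are opposite one-hot vectors, so the Bayesian surprise is their smoothed
    KL divergence (large, of order ``-log epsilon``) on top of the same
    Shannon term — strictly worse than adapting, for any prior.
    """
    theta = stimulus.congruency_theta
    if theta == 0:
        return FreeEnergyTerms(0.0, 0.0)
    shannon = float(-np.log(model.prior[1]))
    if adapted:
        return FreeEnergyTerms(0.0, shannon)
    goal = response_vector(stimulus.symbol_q)
    rapid = response_vector(stimulus.location_p)
    bayes = kl_divergence(goal, rapid, epsilon=model.smoothing_epsilon)
    return FreeEnergyTerms(bayes, shannon)
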