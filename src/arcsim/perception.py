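"""Congruency signal detection with a sequentially adaptive threshold.

Congruency is not read off the stimulus directly: the agent observes a scalar
sensory signal ``V`` drawn from one of two Gaussians — mean ``V0`` for
congruent trials, mean ``V1 > V0`` for incongruent ones — and classifies the
trial by comparing ``V`` with a discrimination threshold ``Vth``.

The threshold is mediated trial by trial:

    Vth  <-  retention * Vth + (-1)^theta * Gamma

so runs of congruent trials (theta = 0) push the threshold up, making a
subsequent incongruent signal easier to miss, while runs of incongruent
trials pull it down, making false incongruence alarms on a subsequent
congruent trial more likely.  This single mechanism produces the
congruency-sequence effects the simulator exhibits: misses concentrate on
I(C) trials and false alarms on C(I) trials.

Sensitivity/reliability of the detector is scored by prior-odds-weighted
ratios of Gaussian tail masses on either side of the threshold, with the
incongruence/congruence frequency ratio ``kappa`` supplying the odds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "PerceptionParams",
    "ThresholdState",
    "classify",
    "sample_signal",
    "sensitivity",
    "signal_density",
    "threshold_fixed_point",
    "update_threshold",
]


class NoFixedPointError(ValueError):
    """Threshold recursion does not converge (retention >= 1)."""


@dataclass(frozen=True)
class PerceptionParams:
    """Gaussian signal model and threshold-mediation parameters.

    V0, V1
        Peak (mean) values of the congruent and incongruent signal classes;
        the model requires ``V1 > V0``.
    sigma0, sigma1
        Spread of each class.  Defaults are asymmetric (0.22 congruent,
        0.35 incongruent): the frequent congruent class produces a tight
        signal while the rare, salient incongruent class is more variable.
        With the threshold orbiting near 0.5 this yields rare false alarms
        on congruent trials but an appreciable miss rate when congruent
        runs have pushed the threshold up — the asymmetry behind the
        sequence-dependent error structure.
    kappa
        Incongruence/congruence frequency ratio (0.25 in Session I).
    retention
        Coefficient on the previous threshold in the mediation rule.
    gamma
        Per-trial threshold step.
    vth_init
        Threshold at session start (midway between the class means).
    sensitivity_prefactor
        Optional override for the prior-odds weights in :func:`sensitivity`;
        ``None`` uses ``1/kappa`` for the incongruence score and ``kappa``
        for the congruence score.
    """

    V0: float = 0.0
    V1: float = 1.0
    sigma0: float = 0.22
    sigma1: float = 0.35
    kappa: float = 0.25
    retention: float = 0.95
    gamma: float = 0.04
    vth_init: float = 0.5
    sensitivity_prefactor: float | None = None

    def __post_init__(self) -> None:
        if not self.V1 > self.V0:
            raise ValueError("V1 must exceed V0")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 <= self.retention <= 1:
            raise ValueError("retention must lie in [0, 1]")

    def mean(self, theta: int) -> float:
        return (self.V0, self.V1)[_check_theta(theta)]

    def sigma(self, theta: int) -> float:
        return (self.sigma0, self.sigma1)[_check_theta(theta)]


def _check_theta(theta: int) -> int:
    if theta not in (0, 1):
        raise ValueError(f"theta must be 0 or 1, got {theta!r}")
    return theta


@dataclass(frozen=True)
class ThresholdState:
    """Current discrimination threshold plus the trajectory so far."""

    vth: float
    history: tuple[float, ...] = ()

    @classmethod
    def initial(cls, params: PerceptionParams) -> "ThresholdState":
        return cls(vth=params.vth_init)


def signal_density(v: float, theta: int, params: PerceptionParams):
    """Unit-area Gaussian density of the theta-class sensory signal at ``v``."""
    return norm.pdf(v, loc=params.mean(theta), scale=params.sigma(theta))


def sample_signal(theta: int, params: PerceptionParams, rng: np.random.Generator,
                  size=None):
    """Draw sensory signal(s) from the theta-class Gaussian."""
    return rng.normal(params.mean(theta), params.sigma(theta), size=size)


def classify(v: float, vth: float) -> int:
    """Threshold rule: incongruent (1) when ``v >= vth``, else congruent (0).

    Exact equality is assigned to the incongruent class (deterministic
    tie-break on a measure-zero event).
    """
    return int(v >= vth)


def sensitivity(theta: int, vth: float, params: PerceptionParams) -> float:
    """Detector sensitivity/reliability score for class ``theta`` in (0, 1].

    With A = congruent mass below the threshold, B = incongruent mass above,
    the incongruence score is ``1 / (1 + w * A / B)`` and the congruence
    score ``1 / (1 + w' * C / D)`` with C = incongruent mass above, D =
    congruent mass below; the weights default to the prior odds ``1/kappa``
    and ``kappa``.  Lowering the threshold drives the incongruence score to
    one (and vice versa); degenerate thresholds return the limiting value.
    """
    _check_theta(theta)
    below_c = norm.cdf(vth, loc=params.V0, scale=params.sigma0)   # A and D
    above_i = norm.sf(vth, loc=params.V1, scale=params.sigma1)    # B and C
    if theta == 1:
        w = params.sensitivity_prefactor
        w = (1.0 / params.kappa if params.kappa > 0 else np.inf) if w is None else w
        if above_i == 0.0:
            return 0.0 if below_c > 0 else 1.0
        return float(1.0 / (1.0 + w * below_c / above_i))
    w = params.kappa if params.sensitivity_prefactor is None else params.sensitivity_prefactor
    if below_c == 0.0:
        return 0.0 if above_i > 0 else 1.0
    return float(1.0 / (1.0 + w * above_i / below_c))


def update_threshold(state: ThresholdState, theta_observed: int,
                     params: PerceptionParams) -> ThresholdState:
    """One threshold-mediation step: ``vth <- retention*vth + (-1)^theta * gamma``."""
    _check_theta(theta_observed)
    step = params.gamma if theta_observed == 0 else -params.gamma
    new_vth = params.retention * state.vth + step
    return ThresholdState(vth=new_vth, history=state.history + (state.vth,))


def threshold_fixed_point(theta: int, params: PerceptionParams) -> float:
    """Limit of the threshold under endlessly repeated ``theta`` trials.

    Closed form ``+-gamma / (1 - retention)``; the recursion converges to it
    geometrically at rate ``retention``.
    """
    _check_theta(theta)
    if params.retention >= 1:
        raise NoFixedPointError("no fixed point when retention >= 1")
    sign = 1.0 if theta == 0 else -1.0
    return sign * params.gamma / (1.0 - params.retention)


def threshold_table(state: ThresholdState) -> "np.ndarray":
    """Threshold trajectory including the current value, oldest first."""
    return np.asarray(state.history + (state.vth,))
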