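"""Comparator nodes of the NTS and the chemoreceptor-gated learning rule.

Each of the N network nodes compares a fixed rostral set-point input
``R_k`` (weighted by a plastic synapse ``Wr_k``) against the chemoreceptor
afferent ``C`` (weight ``Wc_k = 1``) and drives its sympathetic efferent
through a sigmoid:

    S_k = Wr_k * R_k - Wc_k * C,      E_k = G(S_k) in (0.05, 1)

The plastic weight follows a Kohonen-style rule — Hebbian growth balanced
by an activity-gated decay whose rate is amplified by chemoreceptor
discharge:

    Wr_k(t+1) = max(0, Wr_k + alpha_t * R_k * E_k
                        - beta_t * (1 + C) * E_k * Wr_k)

so the weight holds its value when the blood gases are correct (C = 0,
at the fixed point Wr_k = (alpha/beta) * R_k) and is driven down whenever
the chemoreceptors fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LearningParams",
    "NetworkState",
    "sigmoid_G",
    "node_output",
    "update_weight",
    "init_network",
    "learning_schedule",
]


@dataclass(frozen=True)
class LearningParams:
    """Learning-rate schedule and sigmoid shape of the comparator layer.

    ``schedule_mode='constant'`` keeps (alpha0, beta0) for the whole run;
    ``'hyperbolic'`` decays both as 1/(1 + t/tau) to emulate a critical
    developmental period.  ``use_C_in_rule=False`` removes the (1 + C)
    amplification of the decay term, the simplification admissible under
    the hyperbolic schedule.
    """

    alpha0: float = 0.001
    beta0: float = 0.005
    schedule_mode: str = "constant"
    tau: float = 2000.0
    use_C_in_rule: bool = True
    sigmoid_gain: float = 10.0
    sigmoid_center: float = 0.08
    e_min: float = 0.05
    e_max: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("alpha0 and beta0 must be strictly positive")
        if self.schedule_mode not in ("constant", "hyperbolic"):
            raise ValueError(
                f"unknown schedule_mode {self.schedule_mode!r}; "
                "expected 'constant' or 'hyperbolic'")
        if self.tau <= 0:
            raise ValueError("tau must be strictly positive")
        if not self.e_min < self.e_max:
            raise ValueError("e_min must be below e_max")
        if self.sigmoid_gain <= 0:
            raise ValueError("sigmoid_gain must be strictly positive")


@dataclass
class NetworkState:
    """Per-node state: set points R, weights Wr/Wc, outputs S and E."""

    R: np.ndarray
    Wr: np.ndarray
    Wc: np.ndarray
    S: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.R)
        if n < 1:
            raise ValueError("network needs at least one node")
        for name in ("Wr", "Wc", "S", "E"):
            if len(getattr(self, name)) != n:
                raise ValueError("all node arrays must share length N")

    @property
    def n_nodes(self) -> int:
        return len(self.R)


def sigmoid_G(x, params: LearningParams):
    """Output nonlinearity mapping node drive onto the efferent range.

    A logistic curve scaled to (e_min, e_max) = (0.05, 1): the efferent
    rate saturates at a small non-zero floor for strongly negative drive
    and at 1 for strongly positive drive.
    """
    x = np.asarray(x, dtype=float)
    span = params.e_max - params.e_min
    with np.errstate(over="ignore"):  # exp overflow saturates to e_min
        return params.e_min + span / (
            1.0 + np.exp(-params.sigmoid_gain * (x - params.sigmoid_center)))


def node_output(R, C: float, Wr, Wc, params: LearningParams):
    """Comparator output (S_k, E_k) for set points R against feedback C.

    The node fires the difference of its two weighted inputs passed
    through the sigmoid; stronger chemoreceptor drive therefore lowers
    the sympathetic efferent rate (dilating the arteriole), a stronger
    weighted set point raises it.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("chemoreceptor input must lie in [0, 1]")
    R = np.asarray(R, dtype=float)
    Wr = np.asarray(Wr, dtype=float)
    if np.any(Wr < 0):
        raise ValueError("set-point weights must be non-negative")
    S = Wr * R - np.asarray(Wc, dtype=float) * C
    return S, sigmoid_G(S, params)


def update_weight(Wr, E, R, C: float, alpha_t: float, beta_t: float,
                  use_C: bool = True):
    """One plasticity step of the set-point synapse.

    Hebbian term ``alpha * R * E`` grows the weight with joint pre/post
    activity; the competitive decay ``beta * (1 + C) * E * Wr`` shrinks it
    in proportion to the weight and the node's own output, faster while
    the chemoreceptors signal abnormal gases.  The weight is floored at
    zero.  ``C`` is the delayed feedback the NTS actually receives.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("chemoreceptor input must lie in [0, 1]")
    Wr = np.asarray(Wr, dtype=float)
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    gate = 1.0 + C if use_C else 1.0
    return np.maximum(0.0, Wr + alpha_t * R * E - beta_t * gate * E * Wr)


def init_network(rng: np.random.Generator, n: int,
                 params: LearningParams | None = None) -> NetworkState:
    """Random developmental starting state for an N-node comparator layer.

    Set points R_k ~ U[0.1, 0.9] are drawn once and stay fixed; plastic
    weights Wr_k ~ U[0, 1]; chemoreceptor weights Wc_k = 1.  Outputs are
    initialized by one comparator evaluation at C = 0.
    """
    if n < 1:
        raise ValueError("network needs at least one node")
    params = params or LearningParams()
    R = rng.uniform(0.1, 0.9, n)
    Wr = rng.uniform(0.0, 1.0, n)
    Wc = np.ones(n)
    S, E = node_output(R, 0.0, Wr, Wc, params)
    return NetworkState(R=R, Wr=Wr, Wc=Wc, S=S, E=E)


def learning_schedule(t: int, params: LearningParams) -> tuple[float, float]:
    """Learning rates (alpha_t, beta_t) at iteration ``t``.

    Constant mode returns (alpha0, beta0) throughout; hyperbolic mode
    decays both by 1/(1 + t/tau), halving them at t = tau.
    """
    if t < 0:
        raise ValueError("iteration index must be non-negative")
    if params.schedule_mode == "constant":
        return params.alpha0, params.beta0
    decay = 1.0 + t / params.tau
    return params.alpha0 / decay, params.beta0 / decay
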