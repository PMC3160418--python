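"""Cardiovascular transfer functions of the closed regulation loop.

This module contains the deterministic and stochastic signal path from
sympathetic efferent discharge to chemoreceptor output:

efferent rate ``E`` → arteriolar blood flow ``F`` → tissue venous gas
tensions (pO2v, pCO2v) → randomly mixed central venous blood → pulmonary
exchange to arterial tensions (pO2a, pCO2a) → chemoreceptor discharge ``C``.

All gas tensions are in mmHg; discharge rates and flows are dimensionless,
with ``F = 1`` defined as nominal perfusion (the flow at which a tissue's
venous blood leaves at the normal 40/45 mmHg operating point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysiologyParams",
    "TissueVector",
    "BloodGasState",
    "flow_from_efferent",
    "tissue_gas_exchange",
    "sample_mixing_weights",
    "mix_venous",
    "pulmonary_exchange",
    "chemoreceptor_discharge",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological constants, anchors and gains of the vascular loop.

    The venous gas curves are pinned by three printed anchors: at nominal
    flow ``F = 1`` they return the normal venous tensions (40, 45) mmHg,
    at zero flow tissue pCO2v tends to 90 mmHg, and at large flow the
    curves saturate at ``po2v_max`` / ``pco2v_asymptote``.  The curve
    coefficients (``po2v_rate`` and the pCO2 hyperbola) are derived from
    those anchors in ``__post_init__`` so the calibration identity holds
    exactly rather than to rounded constants.

    Parameters
    ----------
    flow_scale
        Hyperbola numerator kappa in ``F = kappa / E``; with the default
        0.5 the mid-range discharge ``E = 0.5`` produces nominal flow.
    flow_offset
        Additive constant on the flow curve (models a shifted renal
        output curve); default 0 and untested beyond being plumbed.
    o2_slope, co2_slope
        Degradation slopes of the pulmonary linear laws outside the
        normal-diffusion thresholds (mmHg arterial per mmHg venous
        deficit).
    chemo_gain_o2, chemo_gain_co2
        Exponents (per mmHg) of the chemoreceptor exponential; defaults
        put mid-range discharge at deficits of roughly 15 mmHg.
    noise_mean, noise_sd
        Parameters of the Gaussian mixing-weight distribution before
        truncation to [0, 1].
    """

    flow_scale: float = 0.5
    flow_offset: float = 0.0
    po2v_max: float = 60.0
    pco2v_zero_flow: float = 90.0
    pco2v_asymptote: float = 40.0
    alveolar_po2: float = 104.0
    alveolar_pco2: float = 40.0
    arterial_po2_normal: float = 95.0
    arterial_pco2_normal: float = 40.0
    venous_po2_normal: float = 40.0
    venous_pco2_normal: float = 45.0
    o2_threshold: float = 39.55
    co2_threshold: float = 45.2
    o2_slope: float = 2.0
    co2_slope: float = 2.0
    chemo_gain_o2: float = 0.05
    chemo_gain_co2: float = 0.05
    chemo_weight_o2: float = 0.5
    chemo_weight_co2: float = 0.5
    noise_mean: float = 1.0
    noise_sd: float = 0.5
    # derived venous-curve coefficients, filled in __post_init__
    po2v_rate: float = field(init=False, repr=False)
    pco2v_a: float = field(init=False, repr=False)
    pco2v_b: float = field(init=False, repr=False)
    pco2v_c: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.flow_scale <= 0:
            raise ValueError("flow_scale must be strictly positive")
        for name in ("o2_slope", "co2_slope", "chemo_gain_o2",
                     "chemo_gain_co2", "chemo_weight_o2", "chemo_weight_co2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.o2_threshold < self.venous_po2_normal:
            raise ValueError("o2_threshold must lie below the normal venous pO2")
        if not self.co2_threshold > self.venous_pco2_normal:
            raise ValueError("co2_threshold must lie above the normal venous pCO2")
        if not 0 < self.venous_po2_normal < self.po2v_max:
            raise ValueError("venous_po2_normal must lie inside (0, po2v_max)")
        if not (self.pco2v_zero_flow > self.venous_pco2_normal
                > self.pco2v_asymptote):
            raise ValueError("pCO2v anchors must be ordered "
                             "zero-flow > normal > asymptote")
        # pO2v(F) = po2v_max * (1 - exp(-rate*F)); pO2v(1) = normal
        rate = -math.log(1.0 - self.venous_po2_normal / self.po2v_max)
        # pCO2v(F) = a/(F+b) + c; pCO2v(0) = zero_flow, pCO2v(1) = normal,
        # asymptote c.  Closed-form solution of the two anchor equations.
        c = self.pco2v_asymptote
        b = (self.venous_pco2_normal - c) / (
            (self.pco2v_zero_flow - c) - (self.venous_pco2_normal - c))
        a = (self.venous_pco2_normal - c) * (1.0 + b)
        object.__setattr__(self, "po2v_rate", rate)
        object.__setattr__(self, "pco2v_a", a)
        object.__setattr__(self, "pco2v_b", b)
        object.__setattr__(self, "pco2v_c", c)


@dataclass
class TissueVector:
    """Per-tissue state: efferent rate, flow and venous gas tensions."""

    E: np.ndarray
    F: np.ndarray
    po2v: np.ndarray
    pco2v: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.E), len(self.F), len(self.po2v), len(self.pco2v)}
        if lengths != {len(self.E)} or len(self.E) < 1:
            raise ValueError("all tissue sequences must share length N >= 1")

    @property
    def n_tissues(self) -> int:
        return len(self.E)


@dataclass(frozen=True)
class BloodGasState:
    """Central venous, arterial and chemoreceptor state for one iteration."""

    mixed_po2v: float
    mixed_pco2v: float
    arterial_po2: float
    arterial_pco2: float
    chemo_C: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.chemo_C <= 1.0:
            raise ValueError("chemoreceptor discharge must lie in [0, 1]")


def flow_from_efferent(E, params: PhysiologyParams):
    """Blood flow through a tissue's arteriole for efferent rate ``E``.

    The vasoconstrictor relation is a hyperbola ``F = kappa / E``: the
    higher the sympathetic discharge, the narrower the vessel and the
    lower the flow.  ``E`` is clipped into its physiological range
    [0.05, 1] before evaluation.
    """
    E = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("efferent discharge must be finite")
    E = np.clip(E, 0.05, 1.0)
    return params.flow_scale / E + params.flow_offset


def tissue_gas_exchange(F, params: PhysiologyParams):
    """Venous gas tensions (pO2v, pCO2v) leaving a tissue perfused at ``F``.

    Oxygen rises with flow along a saturating exponential toward
    ``po2v_max``; carbon dioxide falls along a hyperbola from the
    zero-flow extreme toward its asymptote.  The same curves apply to
    every bed.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)) or np.any(F <= 0):
        raise ValueError("flow must be finite and strictly positive")
    po2v = params.po2v_max * (1.0 - np.exp(-params.po2v_rate * F))
    pco2v = params.pco2v_a / (F + params.pco2v_b) + params.pco2v_c
    return po2v, pco2v


def sample_mixing_weights(rng: np.random.Generator, n: int,
                          params: PhysiologyParams | None = None) -> np.ndarray:
    """Draw the random venous mixing weights ``n_k`` for one iteration.

    Weights follow a Normal(mean, sd) truncated to [0, 1] by rejection —
    with the default mean 1 this keeps only the left half of the density.
    With ``sd = 0`` the distribution degenerates to all ones.
    """
    if n < 1:
        raise ValueError("need at least one tissue")
    params = params or PhysiologyParams()
    if params.noise_sd == 0.0:
        return np.full(n, np.clip(params.noise_mean, 0.0, 1.0))
    out = rng.normal(params.noise_mean, params.noise_sd, n)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(params.noise_mean, params.noise_sd, int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def mix_venous(po2v, pco2v, weights) -> tuple[float, float]:
    """Central venous tensions from the random mixture of all tissue beds.

    The mixture is the normalized weighted average
    ``sum_k n_k p_k / sum_k n_k`` per gas, a convex combination that is
    independent of the number of tissues.
    """
    w = np.asarray(weights, dtype=float)
    po2v = np.asarray(po2v, dtype=float)
    pco2v = np.asarray(pco2v, dtype=float)
    if w.shape != po2v.shape or w.shape != pco2v.shape:
        raise ValueError("weights and tissue tensions must have equal length")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("mixing weights must lie in [0, 1]")
    total = w.sum()
    if total == 0.0:
        raise ValueError("all-zero mixing weights: caller must resample")
    return float(w @ po2v / total), float(w @ pco2v / total)


def pulmonary_exchange(mixed_po2v: float, mixed_pco2v: float,
                       params: PhysiologyParams) -> tuple[float, float]:
    """Arterial tensions after alveolar exchange of the mixed venous blood.

    Inside the normal-diffusion region (pO2v >= 39.55 mmHg, pCO2v <= 45.2
    mmHg per gas) there is enough time to diffuse and the arterial output
    sits at the normal values (95, 40) mmHg.  Outside, exchange is
    impaired and the arterial value degrades linearly with the venous
    deficit; each gas is gated independently.  Arterial oxygen is floored
    at zero.
    """
    if not (np.isfinite(mixed_po2v) and np.isfinite(mixed_pco2v)):
        raise ValueError("mixed venous tensions must be finite")
    if mixed_po2v < 0 or mixed_pco2v < 0:
        raise ValueError("mixed venous tensions must be non-negative")
    if mixed_po2v >= params.o2_threshold:
        po2a = params.arterial_po2_normal
    else:
        po2a = max(0.0, params.arterial_po2_normal
                   - params.o2_slope * (params.o2_threshold - mixed_po2v))
    if mixed_pco2v <= params.co2_threshold:
        pco2a = params.arterial_pco2_normal
    else:
        pco2a = (params.arterial_pco2_normal
                 + params.co2_slope * (mixed_pco2v - params.co2_threshold))
    return float(po2a), float(pco2a)


def chemoreceptor_discharge(arterial_po2: float, arterial_pco2: float,
                            params: PhysiologyParams) -> float:
    """Chemoreceptor discharge rate ``C`` in [0, 1].

    Discharge rises exponentially with the arterial deficits — oxygen
    below, or carbon dioxide above, the normal (95, 40) mmHg — and is
    exactly zero when both tensions are at or inside normal.  The two
    gas contributions are weighted and the sum clipped to 1.
    """
    if not (np.isfinite(arterial_po2) and np.isfinite(arterial_pco2)):
        raise ValueError("arterial tensions must be finite")
    if arterial_po2 < 0 or arterial_pco2 < 0:
        raise ValueError("arterial tensions must be non-negative")
    d_o2 = max(0.0, params.arterial_po2_normal - arterial_po2)
    d_co2 = max(0.0, arterial_pco2 - params.arterial_pco2_normal)
    c = (params.chemo_weight_o2 * math.expm1(params.chemo_gain_o2 * d_o2)
         + params.chemo_weight_co2 * math.expm1(params.chemo_gain_co2 * d_co2))
    return min(1.0, c)
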