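"""Closed-loop iteration of the developing sympathetic regulation.

One iteration walks the full signal path: comparator nodes fire the
sympathetic efferents from the delayed chemoreceptor feedback, flows and
tissue venous gases follow, the venous effluents mix at random into the
central venous blood, the lungs produce the arterial tensions, the
chemoreceptors read them — and the set-point synapses update.  The
chemoreceptor signal the network sees is delayed: the mean of the last
three iterations' instantaneous discharge, zeros before the loop closes.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .physiology import (
    PhysiologyParams,
    chemoreceptor_discharge,
    flow_from_efferent,
    mix_venous,
    pulmonary_exchange,
    sample_mixing_weights,
    tissue_gas_exchange,
)
from .plasticity import (
    LearningParams,
    NetworkState,
    init_network,
    learning_schedule,
    node_output,
    update_weight,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ConvergenceReport",
    "check_calibration",
    "delayed_chemoreceptor",
    "step",
    "run",
    "convergence_diagnostics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a run: sizes, seed, loop and model constants."""

    n_tissues: int = 50
    iterations: int = 1000
    seed: int = 0
    delay_window: int = 3
    convergence_tol: float = 0.01
    convergence_run: int = 100
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    learning: LearningParams = field(default_factory=LearningParams)

    def __post_init__(self) -> None:
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.delay_window < 1:
            raise ValueError("delay_window must be >= 1")
        if self.convergence_tol <= 0 or self.convergence_run < 1:
            raise ValueError("convergence tolerances must be positive")


@dataclass
class Trajectory:
    """Per-iteration record of every state variable of a run.

    Scalar series have shape (T,); per-tissue series shape (T, N).
    Row t holds the values computed during iteration t (0-based), with
    ``C_delayed[t]`` the feedback the network acted on at that iteration.
    """

    E: np.ndarray
    F: np.ndarray
    po2v: np.ndarray
    pco2v: np.ndarray
    Wr: np.ndarray
    mixed_po2v: np.ndarray
    mixed_pco2v: np.ndarray
    arterial_po2: np.ndarray
    arterial_pco2: np.ndarray
    C_instant: np.ndarray
    C_delayed: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    @property
    def n_iterations(self) -> int:
        return len(self.C_instant)

    @property
    def n_tissues(self) -> int:
        return self.E.shape[1]


@dataclass(frozen=True)
class ConvergenceReport:
    """Summary diagnostics of a completed run.

    ``convergence_iteration`` is the first iteration (1-based) opening a
    ``convergence_run``-iteration window whose mean delayed chemoreceptor
    discharge is below tolerance, with every later window staying below
    it too; ``oscillation_count`` counts
    sign changes of the first differences of instantaneous C over the
    early transient.  ``E_spread`` is max - min of the final efferent
    rates (the model asserts convergence of each node, not identity
    across nodes).
    """

    converged: bool
    convergence_iteration: int | None
    final_arterial: tuple[float, float]
    final_venous: tuple[float, float]
    final_delayed_C: float
    oscillation_count: int
    E_spread: float


def check_calibration(physiology: PhysiologyParams,
                      learning: LearningParams, strict: bool = True) -> None:
    """Verify the zero-chemoreceptor region is reachable by learning.

    At the C = 0 fixed points of the weight rule, Wr_k = (alpha/beta) R_k,
    the efferent rates E_k = G(Wr_k R_k) determine per-tissue flows and
    venous gases; their unweighted mixture must fall inside the
    normal-diffusion thresholds, otherwise no weight configuration can
    silence the chemoreceptors and the loop cannot settle.  Raises
    ``ValueError`` for such a mis-calibrated parameter set; with
    ``strict=False`` a ``RuntimeWarning`` is emitted instead, so a user
    can still simulate (and watch) a loop that cannot converge.
    """
    R = np.linspace(0.1, 0.9, 81)
    Wr = learning.alpha0 / learning.beta0 * R
    _, E = node_output(R, 0.0, Wr, np.ones_like(R), learning)
    F = flow_from_efferent(E, physiology)
    po2v, pco2v = tissue_gas_exchange(F, physiology)
    mo, mc = float(po2v.mean()), float(pco2v.mean())
    if mo < physiology.o2_threshold or mc > physiology.co2_threshold:
        msg = (
            "mis-calibrated parameters: the C=0 fixed point yields mixed "
            f"venous ({mo:.2f}, {mc:.2f}) mmHg, outside the normal-diffusion "
            f"region (>= {physiology.o2_threshold}, <= {physiology.co2_threshold})")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)


def delayed_chemoreceptor(history: Sequence[float], window: int = 3) -> float:
    """Delayed feedback: mean of the last ``window`` instantaneous C values.

    Before the history fills the window, missing entries count as zero
    (no chemoreceptor drive before the loop first closes), so the mean
    is always taken over exactly ``window`` slots.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    recent = list(history[-window:])
    return float(sum(recent) / window)


def step(state: NetworkState, delayed_C: float, config: SimulationConfig,
         rng: np.random.Generator):
    """Advance the closed loop one iteration.

    Signal order: comparator outputs E from the delayed feedback, flows,
    tissue gases, fresh random venous mixing, pulmonary exchange,
    instantaneous chemoreceptor discharge, then the weight update (also
    on the delayed feedback — the NTS only ever sees the afferent
    signal).  Returns the new state, the instantaneous C, and the full
    record of the iteration.
    """
    phys, learn = config.physiology, config.learning
    S, E = node_output(state.R, delayed_C, state.Wr, state.Wc, learn)
    F = flow_from_efferent(E, phys)
    po2v, pco2v = tissue_gas_exchange(F, phys)
    while True:
        weights = sample_mixing_weights(rng, state.n_nodes, phys)
        if weights.sum() > 0.0:
            break
    mixed_po2v, mixed_pco2v = mix_venous(po2v, pco2v, weights)
    po2a, pco2a = pulmonary_exchange(mixed_po2v, mixed_pco2v, phys)
    C_instant = chemoreceptor_discharge(po2a, pco2a, phys)
    record = {
        "E": E, "F": F, "po2v": po2v, "pco2v": pco2v,
        "mixed_po2v": mixed_po2v, "mixed_pco2v": mixed_pco2v,
        "arterial_po2": po2a, "arterial_pco2": pco2a,
        "C_instant": C_instant, "C_delayed": delayed_C,
    }
    return state, C_instant, record


def run(config: SimulationConfig) -> tuple[Trajectory, ConvergenceReport]:
    """Simulate the full developmental period and summarize convergence.

    Runs ``iterations`` closed-loop steps from a random initial network,
    recording every state variable, and aborts with the iteration index
    if any state goes non-finite (the symptom of a mis-calibrated
    parameter set).
    """
    check_calibration(config.physiology, config.learning, strict=False)
    rng = np.random.default_rng(config.seed)
    state = init_network(rng, config.n_tissues, config.learning)
    T, N = config.iterations, config.n_tissues

    traj = Trajectory(
        E=np.empty((T, N)), F=np.empty((T, N)),
        po2v=np.empty((T, N)), pco2v=np.empty((T, N)), Wr=np.empty((T, N)),
        mixed_po2v=np.empty(T), mixed_pco2v=np.empty(T),
        arterial_po2=np.empty(T), arterial_pco2=np.empty(T),
        C_instant=np.empty(T), C_delayed=np.empty(T),
        alpha=np.empty(T), beta=np.empty(T),
    )
    history: list[float] = []
    for t in range(T):
        delayed_C = delayed_chemoreceptor(history, config.delay_window)
        alpha_t, beta_t = learning_schedule(t, config.learning)
        state, C_instant, rec = step(state, delayed_C, config, rng)
        state.Wr = update_weight(state.Wr, rec["E"], state.R, delayed_C,
                                 alpha_t, beta_t, config.learning.use_C_in_rule)
        history.append(C_instant)
        traj.E[t] = rec["E"]; traj.F[t] = rec["F"]
        traj.po2v[t] = rec["po2v"]; traj.pco2v[t] = rec["pco2v"]
        traj.Wr[t] = state.Wr
        traj.mixed_po2v[t] = rec["mixed_po2v"]
        traj.mixed_pco2v[t] = rec["mixed_pco2v"]
        traj.arterial_po2[t] = rec["arterial_po2"]
        traj.arterial_pco2[t] = rec["arterial_pco2"]
        traj.C_instant[t] = C_instant
        traj.C_delayed[t] = delayed_C
        traj.alpha[t] = alpha_t; traj.beta[t] = beta_t
        if not (np.isfinite(state.Wr).all() and np.isfinite(C_instant)):
            raise FloatingPointError(
                f"non-finite state at iteration {t}: check model calibration")
    report = convergence_diagnostics(traj, config.convergence_tol,
                                     config.convergence_run)
    return traj, report


def convergence_diagnostics(traj: Trajectory, tol: float = 0.01,
                            run_length: int = 100) -> ConvergenceReport:
    """Convergence summary of a recorded trajectory.

    Final pressures are means over the last ``run_length`` iterations;
    the oscillation count tallies sign changes (including changes to and
    from zero slope) of the instantaneous C differences over the first
    min(200, T) iterations.
    """
    T = traj.n_iterations
    conv_iter: int | None = None
    # chemoreceptor silence: windowed mean of delayed C below tolerance
    # from some iteration through the end of the run
    span = min(run_length, T)
    window_mean = np.convolve(traj.C_delayed, np.ones(span) / span, "valid")
    ok = window_mean < tol
    if ok[-1]:
        above = np.nonzero(~ok)[0]
        conv_iter = int(above[-1]) + 2 if above.size else 1  # 1-based

    early = traj.C_instant[:min(200, T)]
    signs = np.sign(np.diff(early))
    oscillations = int(np.count_nonzero(signs[1:] != signs[:-1]))

    tail = slice(max(0, T - run_length), T)
    return ConvergenceReport(
        converged=conv_iter is not None,
        convergence_iteration=conv_iter,
        final_arterial=(float(traj.arterial_po2[tail].mean()),
                        float(traj.arterial_pco2[tail].mean())),
        final_venous=(float(traj.mixed_po2v[tail].mean()),
                      float(traj.mixed_pco2v[tail].mean())),
        final_delayed_C=float(traj.C_delayed[tail].mean()),
        oscillation_count=oscillations,
        E_spread=float(traj.E[-1].max() - traj.E[-1].min()),
    )
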