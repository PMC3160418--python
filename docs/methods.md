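# Methods

## Model overview

`setpointnet` simulates the postnatal development of sympathetic
cardiovascular control as a discrete-time closed loop. Each of N tissue
beds is controlled by one comparator node of the NTS. Per iteration the
signal path is evaluated in physiological order:

1. comparator outputs `E_k = G(Wr_k R_k − Wc_k C_delayed)`;
2. arteriolar flows `F_k = κ / E_k` (plus an optional additive offset
   modelling a shifted renal output curve, default 0);
3. tissue venous tensions `pO2v_k = po2v_max (1 − e^{−λ F_k})`,
   `pCO2v_k = a/(F_k + b) + c`;
4. central venous mixing: a normalized average with fresh random weights
   `n_k ~ Normal(1, 0.5)` truncated to [0, 1] by rejection;
5. pulmonary exchange: arterial tensions are exactly (95, 40) mmHg while
   the mixed venous tensions are inside the normal-diffusion region
   (pO2v ≥ 39.55, pCO2v ≤ 45.2 mmHg, gated per gas), degrading linearly
   with the venous deficit outside it;
6. chemoreceptor discharge
   `C = min(1, Σ_g w_g (e^{k_g d_g} − 1))` over the two arterial
   deficits, zero at or inside normal;
7. weight update
   `Wr_k ← max(0, Wr_k + α_t R_k E_k − β_t (1 + C_delayed) E_k Wr_k)`.

The feedback the network sees is delayed: the mean of the last three
iterations' instantaneous `C`, with missing history counted as zero, so
the loop starts open. Both the comparator and the weight update use the
delayed signal — the NTS only ever receives the afferent pathway.

## Calibration and default parameters

The functional forms are canonical members of their families (hyperbola,
saturating exponential, flat-plus-linear, exponential, logistic), pinned
by printed physiological anchors rather than fitted constants:

| parameter | default | meaning |
|---|---|---|
| κ (`flow_scale`) | 0.5 | mid-range discharge E = 0.5 gives nominal flow F = 1 |
| `po2v_max` | 60 mmHg | venous O₂ asymptote at high flow |
| λ (`po2v_rate`) | ln 3 (derived) | solves pO2v(1) = 40 mmHg |
| pCO₂v curve a, b, c | 50/9, 1/9, 40 (derived) | solve pCO2v(0) = 90, pCO2v(1) = 45, asymptote 40 mmHg |
| diffusion thresholds | 39.55 / 45.2 mmHg | edge of the normal-diffusion region |
| s_O, s_C (`*_slope`) | 2.0 | arterial degradation per mmHg venous deficit |
| k_O, k_C (`chemo_gain_*`) | 0.05 /mmHg | deficits of ~15 mmHg give mid-range C |
| w_O, w_C | 0.5 | equal weighting of the two gas branches |
| sigmoid g, x₀ | 10, 0.08 | see below |
| α₀, β₀ | 0.001, 0.005 | learning and decay rates |
| delay window | 3 iterations | closed-loop afferent delay |
| N, T | 50, 1000 | tissues, developmental iterations |

Derived coefficients are recomputed from the anchors at construction, so
the calibration identity `tissue_gas_exchange(1) = (40, 45)` holds to
machine precision. The venous O₂ curve returns 0 (not the extreme
exercise value of ~3 mmHg) as flow tends to zero; that extreme is a
physiological observation, not a calibration anchor.

κ, g and x₀ are co-calibrated: at the C = 0 fixed points
`Wr_k* = (α/β) R_k` the drives `S_k = 0.2 R_k²` must map onto efferent
rates whose flows keep the mixed venous blood inside the
normal-diffusion region, otherwise no weight configuration can silence
the chemoreceptors. `check_calibration` verifies this reachability on an
R-grid; it raises when called directly and downgrades to a
`RuntimeWarning` during config loading and `run()`, so a deliberately
mis-calibrated loop can still be simulated and observed (it settles at a
nonzero chemoreceptor floor — e.g. α₀ = 0.002 with otherwise default
constants equilibrates near C ≈ 0.06 instead of converging).

The slopes s_O, s_C and gains k_O, k_C only set the loop gain: inside a
negative feedback loop their exact values move the convergence speed and
transient amplitude, not the fixed point, which is anchored by the
thresholds and normals.

## Learning-rate schedules

Constant mode keeps (α₀, β₀) throughout. Hyperbolic mode emulates a
critical period, decaying both rates by `1/(1 + t/τ)`. The decay
constant defaults to τ = 2000 iterations, of the order of the
developmental horizon: the integrated learning time `τ ln(1 + T/τ)` must
exceed the ~650 nominal-rate iterations convergence takes, otherwise
development ends before the weights settle (with τ = 200 the loop stalls
near arterial pO₂ ≈ 93 mmHg). With τ = 2000 the constant and hyperbolic
schedules reach final pressures within 0.35 mmHg of each other on every
tested seed; the residual chemoreceptor floor is slightly higher under
decay (slower late learning chases the mixing noise less), so
chemoreceptor silence is asserted on the seed-pooled mean for that
variant. `use_C_in_rule=False` removes the (1 + C) factor from the decay
term, the simplification admissible in the critical-period variant.

## Convergence diagnostics

"Learning complete" is operationalized as chemoreceptor silence: the
100-iteration moving mean of the delayed discharge staying below 0.01
from some iteration through the end of the run. A windowed mean rather
than a per-iteration bound is used deliberately: the fresh mixing noise
keeps rare single-iteration spikes of C ≈ 0.015 alive even in a fully
settled loop (more so at small N, where averaging over tissues is
weaker), and a converged developmental state means a silent mean floor,
not the absence of every noise spike. `convergence_iteration` is the
1-based start of the first such window; `oscillation_count` tallies sign
changes (including to and from zero slope) of the first differences of
instantaneous C over the first 200 iterations; `E_spread` reports
max − min of the final efferent rates — the model claims each node
converges, not that all nodes converge to a common value, so the spread
is reported rather than asserted.

## What the simulation does and does not emulate

The generator's defaults are the study conditions themselves (N = 50,
T = 1000, α = 0.001, β = 0.005, noise sd 0.5, delay 3); there is no
external data. Passing tests therefore demonstrate the internal
consistency and robustness of the mechanism — emergence of the set
point, N-invariance, schedule-invariance, noise robustness — not
agreement with physiological recordings. Deliberately absent:
baroreflex and cardiopulmonary pathways, heart rate / stroke volume /
peripheral resistance dynamics, hemoglobin dissociation, per-tissue
heterogeneous metabolism, and real-time units (an iteration is a
developmental epoch; maturation time is a plotting label).

## Numerical choices

- Efferent inputs to the flow curve are clipped to [0.05, 1]; the
  sigmoid makes this structural, clipping is a safety net.
- Weights are floored at 0 to forbid sign flips of the set-point
  pathway.
- Truncated-normal mixing weights are drawn by per-element rejection;
  acceptance mass ≈ 0.48, so termination is immediate in practice. An
  all-zero weight vector (probability zero) would trigger a resample.
- Arterial O₂ from the linear impairment law is floored at 0 mmHg.
- Trajectories serialize at 17 significant digits and are parsed with
  round-trip float precision, making save/load bit-faithful; run
  manifests snapshot every resolved parameter so a run can be
  reproduced exactly from its manifest.
- All randomness flows from one `numpy` Generator seeded by the config,
  making runs bit-reproducible per seed.

## Known limitations

- The reachability check uses the unweighted mixture over an R-grid; a
  pathological noise distribution concentrated on few tissues could in
  principle pass the check yet converge slowly.
- At small N (≲ 5) the mixing-noise floor can hold the windowed mean of
  C marginally above the 0.01 silence threshold even though the final
  pressures match larger networks within 1 mmHg.
- The length of the early oscillatory phase depends on the loop-gain
  constants (slopes and chemoreceptor gains) and is reported only as a
  diagnostic, never asserted.
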