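# Methods

## Model and assumptions

The model reduces Beclin-1-mediated autophagy–apoptosis crosstalk in an
ischemic neuron to five well-mixed, dimensionless abundances (B, Bc, A,
M, C) driven by a scalar stress input S(t).  Mass-action kinetics are
used throughout except for three saturable processes represented with
Michaelis–Menten forms: autophagic clearance of autophagosomes (limited
lysosome availability; flux J = β_A A/(1 + A/φ_A) with supremum
β_A φ_A), Caspase-3 autocatalytic activation (limited by the inactive
pool; the (1 − C) factor confines C to [0, 1]), and Caspase-3
inactivation by IAPs, whose own autophagic degradation (σ_J J term in
the denominator) weakens inactivation at high flux.  The opposed
saturable activation/inactivation give zero-order ultrasensitivity and a
bistable life/death switch.  All rates are per hour; abundances are
normalized so unstressed resting levels are ≈ 1 (C excepted), which is
why synthesis and decay constants default to comparable magnitudes.

Stress acts twice: it upregulates Beclin-1 expression
(α_B (1 + u_B S)) and damages mitochondria (α_M (1 + u_M S)).  Beclin-1
is protective through mitophagy (γ_M J M) and harmful through Bc-driven
mitochondrial permeabilization (σ_M Bc), autophagosome-platform Caspase
activation (σ_C A), and IAP depletion (σ_J J).

## Parameters

The 19 parameters carry representative values (`ParameterSet()`
defaults) and, for 16 of them, plausible sampling ranges
(`ensemble.TABLE1_RANGES`).  The three intrinsic Caspase parameters are
fixed at μ_C = 1, γ_C = 0.3, φ_C = 0.15 — varying them would break the
bistability that the fate decision requires (the package verifies the
bistability condition: g2(0) = 0.195 > 0, Δ = 0.27125 > 0, critical
points 0, ~0.207, ~0.943).

**Sampling design.**  The default virtual population samples 14
parameters by Latin hypercube (scipy's `qmc.LatinHypercube`, default
seed 1234, linear mapping of the unit cube onto the ranges): S, α_B,
β_B, γ_B, γ_BC, α_A, β_A, φ_A, α_M, σ_M, γ_M, α_C, σ_C, σ_J.  The two
stress-sensitivity coefficients u_B and u_M are held at 1: they rescale
the already-sampled stress axis (their sampled mean of 1.25 would
systematically inflate effective stress and with it every scenario's
apoptotic fraction by several points), and holding them fixed keeps the
stress level S the single, interpretable severity axis.  Their ranges
remain in `TABLE1_RANGES` and can be passed to `sample_lhs` explicitly.
Exact draws are sampler-stream specific, so ensemble results carry
sampling error of order n^(-1/2), not bit-reproducibility across
library versions.

## Initial conditions and degenerate variants

Every simulation starts from the variant's unstressed steady state,
computed by fixed-point iteration on the algebraic resting balances
(resting flux equals autophagosome production, J = α_A B) coupled with
the lowest stable root of the Caspase balance, then certified by a
residual check (< 1e-8 per component; near the resting saddle-node the
fixed point is polished by relaxation integration).  Note the resting
state is self-consistent in C: the small resting Caspase activity
(C ≈ 0.01 for the representative cell) produces a nonzero Bc and hence
a resting M above α_M/(γ_M J).  At the ensemble level this choice is
immaterial (naive all-ones starts move scenario fractions by < 0.7
points).

Two degeneracies exist and are handled differently:

* **Flux-saturated** (α_A B ≥ β_A φ_A at rest): autophagosomes have no
  resting balance.  Such variants (~2–3% of the default ensemble) are
  excluded from ensemble numerators and denominators, identically
  across paired scenarios (the union of per-scenario degeneracies), and
  their counts are reported.
* **Zero resting flux** (α_B = 0 after noise truncation): damaged
  mitochondria have no clearance balance, M grows without bound, and
  Caspase commitment is inevitable; these cells are counted apoptotic.
  They arise only in the knockdown noise populations, where excluding
  them would bias exactly the arm being studied.

## Numerics

* Single trajectories (`simulate`): scipy `solve_ivp` with LSODA,
  rtol 1e-8 / atol 1e-10, integration restarted at the stress on/off
  discontinuities.  Sub-tolerance negative excursions are clipped;
  larger ones raise.
* Ensemble sweeps: an in-package adaptive Dormand–Prince 5(4)
  integrator (numba-compiled, rtol 1e-6 / atol 1e-9, final-state only).
  The system's fastest decay rate (γ_M J, a few hundred per hour in
  extreme variants) is comfortably within an explicit embedded pair's
  stability-limited stepping.  The test suite checks agreement with the
  LSODA path, with a fixed-step RK4 oracle at dt = 1e-3 h (≤ 1e-3 in
  every component), and that halving tolerances moves C(48 h) by
  < 1e-4.
* Apoptosis call: C > 0.5 (strict) at the end of the 48-h horizon.
  Because the switch is bistable, end-point and ever-crossed
  classifications coincide except in a measure-zero band of borderline
  trajectories.
* Switch analytics: critical points by dense sign scan (400
  subintervals) plus Brent refinement to 1e-12; stability from the
  closed-form derivative of f_act − f_inact.  Continuation is naive
  per-grid root finding — branches in C never fold except at the
  saddle-node — with the fold refined by bisection on branch existence
  (6000-subinterval scan near the fold, since the merging roots are
  only ~√(drive offset) apart) and cross-checked against the tangency
  system f = 0, f' = 0.  With α1 = 0 the survival branch sits exactly
  at C = 0 and is lost at the boundary; the fold solver reports the
  collision at C = 0.  The printed discriminant convention includes the
  factor 1/2; only its sign matters.
* Viability windows: 100 log-spaced α_B points on [0.1, 10] (the
  thresholds span two decades), survival-set contiguity enforced (a
  non-contiguous set raises rather than silently hull-ing), edges
  refined by bisection to 1e-3.
* Golden hour: bisection on stress duration to 0.05 h, between a
  surviving and a committing bracket; non-monotone outcomes raise.

## Experiment conventions

* **Protocol**: stress on [0, 24] h of a 48-h horizon for all ensemble
  and window experiments, applied uniformly.
* **Interventions are acute**: golden-hour overrides start from the
  *unperturbed* cell's resting state with the modified dynamics from
  t = 0, as for a drug given at stroke onset.  (A chronically adapted
  knockdown cell rests with more damaged mitochondria and shows a
  smaller benefit.)  The intervention panel is: α_B = 0.5, β_B = 0,
  β_A = 5 (5-fold flux enhancement, countering autophagosome
  accumulation), σ_J = 0.001, plus σ_C = 0 as the literal Mechanism-2
  knockout arm; each also combined with 10-fold saturation relief
  (φ_A × 10).  When no duration up to the horizon commits the cell the
  threshold is reported as unbounded, with a horizon-censored value
  (T* ≥ 48 h) available for summaries; the σ_J = 0.001 + φ_A × 10
  intervention is such a complete rescue at S = 8.
* **Stress bands** for stratified summaries: mild (0, 1], moderate
  (1, 2.5], severe (2.5, 5], and an explicit extreme band (5, 10] so
  that sampled variants beyond the severe band are reported, not
  dropped.  Expression bins for shape summaries are log-spaced.
* **Statistics**: pairwise Pearson chi-square on 2×2 tables without
  continuity correction (immaterial at ensemble sizes of thousands),
  Bonferroni multiplied by the stated family size and capped at 1;
  Wald 95% intervals for proportions, clipped to [0, 1] (degenerate at
  the k = 0 and k = n boundaries — a documented property of the
  method; a Wilson alternative exists behind a flag but is never the
  default).

## What the generators emulate — and what they do not

The LHS ensemble emulates cell-to-cell variability in expression
levels, half-lives and stress exposure across a plausible biological
range; the noise populations emulate expression heterogeneity around a
knockdown/overexpression mean (Gaussian, SD 0.5, truncated at zero).
Neither captures spatial stress gradients in the penumbra, cell-type
heterogeneity, reperfusion injury, or pathway players outside the five
modeled species — so passing ensemble tests demonstrates internal
consistency of the model's predictions, not fidelity to any particular
tissue.  No parameters are fitted to data.

## Problem sizes

Default analyses use 10,000-variant ensembles (a full 8-scenario paired
run takes well under a minute on one CPU with the compiled integrator).
The test suite uses reduced sizes chosen for statistical resolvability:
500-variant paired runs for structural properties, a 2000-variant run
(binomial 3σ ≈ ±3 points at the observed fractions) for the published
fraction comparisons, and 400-cell noise populations for ordering
claims.

## Known limitations

* The Wald interval degenerates at proportion boundaries (by design,
  matching the stated method).
* The viability-window scan assumes a contiguous survival set in α_B;
  the package fails loudly if a variant violates this rather than
  reporting an outer hull.
* Ensemble values depend on the sampler stream; only
  sampling-error-level reproducibility across environments is claimed.
* The severe-stress golden hour of the strongest combined intervention
  exceeds the simulation horizon; its fold-extension is a lower bound.
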