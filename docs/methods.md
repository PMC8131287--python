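# Methods

## The toy system as a stand-in for solvated host–guest MD

Production REUS binding calculations run a guest molecule through a rigid
macrocyclic host (cucurbit[8]uril) in explicit water. None of the estimation
machinery cares about those details: it consumes reaction-coordinate samples
under known biases. `reusbind` therefore replaces the molecular system with
the simplest model that preserves every estimator-facing feature and adds an
exact answer:

    U(x, y, z) = U_ax(z) + U_rad(x, y)
    U_ax(z)    = −D exp(−z²/2w²) + soft walls outside the axial range
    U_rad      = c (x² + y²)

* separability makes the marginal PMF along ζ = z exactly
  `U_ax(z) + const` (anchored to 0 at the bound pose z = 0), so WHAM output
  can be scored against a closed form;
* the single Gaussian well of depth D mimics the symmetric bound-pose
  minimum between the two host portals; the flat region |z| ≫ w plays the
  laterally confined unbound state;
* the harmonic radial term plays the role the cylindrical flat-bottom
  restraint plays in production: it confines the guest's lateral excursions
  in the unbound state, which is exactly what the effective-volume
  correction prices. The flat-bottom cylinder (r₀ = 7.5 Å, 5 kcal/mol/Å²)
  is still applied, but with the default radial stiffness it never engages —
  faithful to production, where it is a safety rail rather than a force.

Defaults (chosen once, as a mid-range guest): D = 5 kcal/mol (between the
weakest ≈ 3.5 and strongest ≈ 17 kcal/mol pulling free energies of the
benchmark systems), w = 1 Å, axial range (−13, 14) Å matching the production
reaction-coordinate span, c = 1 kcal/mol/Å², wall stiffness 10 kcal/mol/Å²,
mass 100 amu (guest-sized point particle), T = 298.15 K,
k_B = 0.0019872041 kcal/mol/K (k_B T = 0.59248 kcal/mol).

### What the generator does not emulate

No solvent friction memory, no conformational degrees of freedom, no
orientation-dependent binding, no asymmetric or multi-minimum PMFs, no
slow host breathing. A green toy test therefore establishes the
*estimators* (exchange bookkeeping, WHAM, corrections, error bars) are
correct and internally consistent — not that any particular force field or
sampling length suffices for a real complex. Asymmetric-profile diagnostics
(`wham.check_symmetry`) are implemented and tested on synthetic profiles,
but the toy generator itself only produces symmetric wells.

## Sampling

Two independent routes, used to cross-check each other:

* **Langevin dynamics** — BAOAB splitting with the exact Ornstein–Uhlenbeck
  friction substep; friction 1 ps⁻¹ and dt = 0.002 ps (well under the
  fastest period: ω ≈ 4.6 ps⁻¹ at the default stiffnesses). Configurational
  bias is O(dt²) and negligible at these settings. Velocities are drawn from
  Maxwell–Boltzmann at start and left untouched by exchanges (umbrellas are
  momentum-independent).
* **Exact inverse-CDF sampling** — i.i.d. draws of ζ from the 1-D biased
  marginal on a 4096-point grid with linear interpolation. This is the
  oracle: the dynamics must match it in distribution (KS/χ² checks), and
  WHAM tests consume it so that statistical error is the only error.

## Replica exchange

Neighbor pairs (m, m+1) attempt exchanges every `steps_per_cycle` dynamics
steps (default 20 steps = 0.04 ps, the toy-clock analogue of the production
2 ps interval), alternating even/odd parity so each pair is attempted every
other sweep — a standard balanced scheme; the source protocol does not
specify its pair-selection rule. Exchanges swap window labels, not
coordinates (equivalent, cheaper to log). Library default run length is
20,000 cycles; the test-suite and acceptance-script runs use 2,500–3,000
cycles, which already give a few hundred effective samples per window
(samples 0.04 ps apart are serially correlated on the ≈1 ps velocity
relaxation time; the block bootstrap absorbs this).

**Umbrella stiffness.** The ladder is 32 windows on (−13, 14) Å, tiled at
0.5 Å in the dense bound region (−3, 3) and uniformly on each flank
(spacing ≈ 1.0–1.1 Å). The published protocol reports its per-window
stiffnesses only in inaccessible supplementary material, but reports a
20–30% observed exchange rate. For exact sampling on a locally flat
landscape the neighbor acceptance has the closed form 2Φ(−s√(βk)) (s =
spacing), and the package ships an exact-density predictor
(`reus.predict_exchange_acceptance`, 2-D quadrature over the two biased
marginals) that also handles curvature from the well. The default uniform
stiffness k = 1.385 kcal/mol/Å² was calibrated once, a priori, with
`reus.calibrate_ladder_stiffness` to a predicted mean acceptance of 0.25 on
the default ladder; realized dynamics runs land at ≈ 0.25.

## WHAM

Standard discrete self-consistent iteration on shared 0.2 Å bins, bias
tabulated at bin centers (midpoint rule), gauge f₀ = 0, stopping when
max|Δf_m| < 10⁻⁷ kcal/mol (cap 10⁵ iterations); probabilities are
normalized and empty bins masked. A second, independent numerical route —
BFGS minimization of the (convex) WHAM negative log-likelihood with
analytic gradient, per-sample normalized — is exposed as `fit(method="ml")`
and agrees with the iteration to < 10⁻⁶ kcal/mol on small problems. The
overlap graph is checked for connectivity before solving; disjoint windows
raise.

**ΔG_REUS definition.** The source protocol never states whether its
pulling free energy is the PMF well depth or a Boltzmann-integrated binding
ratio, so both are implemented: `depth` (bound-region minimum minus the
mean over the unbound plateau; the default, consistent with reading depths
off published profiles) and `integrated`
(−kT ln[⟨e^{−βF}⟩_bound / ⟨e^{−βF}⟩_unbound], used for the end-to-end
quadrature cross-check because it has an exact counterpart). The bound
region defaults to the densified (−3, 3) Å; the unbound reference is the
outermost 3 Å of each flank (left flank only for unidirectional runs).
The mode is recorded in every result.

**Uncertainty.** Block bootstrap over each window's series (block = 50
exchange cycles ≈ several correlation times; 20 resamples by default),
re-running the full WHAM → ΔG pipeline per resample with warm-started
window offsets. The uncertainty method is unstated in the source; block
bootstrap is the standard choice that respects serial correlation without
an explicit autocorrelation model.

## Corrections

* **Volume (rest-off).** `V_eff = π (r_max² − r_min²) h_max` from the plain
  radial/axial excursion extrema of the first (unbound) replica, exactly as
  the estimator is defined — deliberately including its noise sensitivity
  (extrema of an unbounded-support density grow with sample size; a
  percentile variant is provided but off by default). V₀ is fixed at the
  published 1649.76 Å³ rather than the 1 M textbook 1660.5 Å³, overridable.
  Because V_eff is a statistic of the finite run by construction, the
  end-to-end quadrature oracle prices the volume term at the measured
  V_eff; the arithmetic itself is validated on uniform-cylinder fixtures
  where the limit is exact.
* **Restraint-on (TI).** Linear coupling V(λ) = λ·V_restraint (the coupling
  form is unstated in the source), so ⟨∂V/∂λ⟩ = ⟨V_restraint⟩_λ; one
  Langevin walker per (pose, λ); trapezoid over the non-uniform λ grid;
  mean and stderr over 5 bound poses drawn at evenly spaced times from the
  bound window. The published λ ladder (dense near λ = 1) is the default
  and is appropriate for bound poses, where the integrand is smooth
  (trapezoid bias ≈ 0.003 kcal/mol, well under the stderr). For switching a
  restraint onto an *unconfined* coordinate the integrand is steep near
  λ = 0 (⟨V⟩ ~ kT/2λ above a crossover) and the published grid carries
  ≈ 0.4 kcal/mol trapezoid bias; such cases need the grid refined near 0,
  which is how the closed-form validation (k = 2.5 over a 10 Å uniform
  coordinate → 1.452 kcal/mol) is run. Toy-scale lengths default to 2,000
  equilibration + 10,000 production steps per λ, standing in for the
  100/200 ps production protocol. A known toy-scale limitation: with the
  deep default well the λ = 0 ensemble technically includes rare plateau
  excursions a short walker never makes; their weight in the TI integral is
  ≈ 0.003 kcal/mol (0.25% of Z₀), far below the reported uncertainty.
* **Assembly and sign convention.** ΔG_bind = ΔG_REUS + ΔG_rest−off +
  ΔG_rest−on. The source's assembly equation is printed with all three
  terms negated, which contradicts its own component table; the table's
  plain-sum convention (under which every row is internally consistent) is
  implemented, and the negated form is treated as alternate sign
  bookkeeping. Stereoisomer averages are arithmetic means with errors
  propagated as ½√(σ_R² + σ_S²).

## Protonation cycle

`pKa^bound = pKa^free + (ΔA_L − ΔA_HL⁺)/(k_B T ln 10)`; the ΔΔA direction
(ambiguous in the source text) is fixed as neutral-minus-protonated, which
reproduces the published pH-corrected entries to 0.01 kcal/mol for two of
the three parameter sets (the third disagrees by 0.05 kcal/mol even from
its own printed inputs, suggesting unrounded inputs were used). The "log"
in the population factor is the natural log under the 1/β prefactor
(validated numerically); the implementation uses log-add-exp guards and is
exactly closed under exchanging the roles of the two protonation legs.
Note the corrected ΔG is monotone *non-decreasing* in pKa^bound — a rising
bound pKa drives the bound state fully protonated and the correction to
zero.

## Benchmark statistics

RMSE with population denominator n, Pearson r (R² = r²), Kendall τ-a
(no tie correction; ties raise), MAE, and ME = mean(experimental −
computed) — the conventions validated against the published statistics
table. Of that table, the reproducible entries from the rounded inputs are:
all four FM-MP2 statistics and its ME; C36-S6 r/R²/τ; FM-PM6 τ; FM-PM6's
Pearson r only reproduces when the uncorrected neutral G5 entry is used
instead of the pH-corrected one, so the verification layer reports that
variant with a provenance flag. The published FM-MP2 MAE violates
|ME| ≤ MAE and is not reproducible under any convention; it and the
FM-PM6/C36-S6 RMSE entries are reported but not asserted.

## Known limitations

* Single-particle guest: the center-of-mass reaction-coordinate projection
  is exercised on static multi-site configurations only; no rigid-body
  dynamics.
* 1-D PMFs only; no MBAR, no 2-D umbrella grids, no explicit
  autocorrelation-time estimation beyond the block bootstrap.
* The unidirectional mode truncates the ladder at the bound center, so its
  integrated-mode bound integral covers half the well; the depth-mode
  definition (the default) is the appropriate one for one-sided runs.
* Exchange acceptance calibration assumes the exact-sampling limit between
  attempts; short dynamics segments leave realized rates within a few
  percent of prediction on this system, but strongly correlated segments on
  rougher landscapes could deviate more.
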