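# Methods

## Model

The package models the energy balance of a single "average" eukaryotic
cell as twelve coupled ODEs in molecules-per-cell (m.p.c.) units. ATP
enters at a constant influx `A0` and is consumed by first-order
turnover, basal DNA replication (`Nnt·Ng/tau`), transcription and
translation of a housekeeping background (`Q` genes) and of the two
retrotransposon families, and reverse transcription of new genomic
element copies (charged once inside the replication term and once in
the insertion bracket of the ATP equation — the balance equation is
implemented exactly as the decomposition in `budget` mirrors it, and
the two charges are reported as separate categories).

Every ATP-dependent step carries a Michaelis–Menten factor
`a/(K + a)`; mRNA–ribosome binding and the L1↔Alu mRNA exchange on the
ORF2p complex follow mass action, with the bimolecular rate constants
(`k_bq`, `k_bL`, `k_subS`, `k_subL`) treated as second-order,
1/(m.p.c.·min), because they multiply products of two concentrations.
Translation rates scale the elongation rate `gamma_max` (aa/min) by
the protein length — the median housekeeping length `Nq` and `NL/3`
for the L1 polyprotein (one amino acid per codon); insertion rates
scale the single-nucleotide incorporation rate `chi_max` by the
element length. L1 insertion additionally requires ORF1p through a
limited-binding-occupancy factor `K_L·O1/(1 + K_L·O1)`.

Key assumptions: deterministic, well-mixed kinetics (no stochastic or
spatial structure); a fixed cell volume so counts stand in for
concentrations; housekeeping genes as a single lumped competitor;
ORF2p never free (instantaneously bound to an mRNA); element
"deactivation" (`lambda_L`, `lambda_S`) lumps silencing into a
first-order exit from the transcribed pool.

The Alu-free reduced variant is a flag on the same right-hand side,
not a separate system: Alu transcription, the substitution reaction
and Alu insertion are zeroed and the `mS`, `bS`, `S` derivatives
frozen, so both variants share one tested code path.

## Parameters

All ~45 constants default to the published calibration and are
documented field-by-field on `ParameterSet` (units: 1/min for
first-order rates, m.p.c. for counts and Michaelis constants, bp/aa
for lengths, ATP per nucleotide/amino acid for stoichiometries).
Eleven of them — the complex formation/turnover constants, ATP
degradation and the two deactivation rates — have no direct literature
estimate and are the *free* parameters re-estimated by `calibrate`.
`V_cell` is metadata and enters no rate; the sensitivity module keeps
it only to demonstrate a vanishing response. Strict positivity is
enforced for every field; degenerate limits used in tests (no
housekeeping transcription, no replication) are expressed through
extreme positive values (`w_q = 1e-30`, `tau = 1e30`) rather than
zeros.

## Numerics

**Integration.** The system is stiff (timescales from sub-minute ATP
turnover to multi-day protein turnover), so trajectories use the
implicit Radau method with the analytic Jacobian, relative tolerance
1e-8 and per-variable absolute tolerance 1e-6 of the reference
magnitude. The right-hand side is evaluated on `max(state, 0)` and
the free-ribosome pool is clamped at zero, so integration noise near
the axes cannot produce negative fluxes; trajectories are validated
post hoc (excursions below −1e-6 of a variable's scale abort the run).
Internal steady-state-search integrations use a 1e-9 absolute-tolerance
fraction so their noise stays far inside that floor.

**Jacobian.** Derived symbolically (sympy) from the clamp-free
right-hand side and lambdified once per model variant; exact at
admissible interior states. The test suite cross-validates it against
central finite differences (1e-5 relative element-wise, 1e-4 on
eigenvalues).

**Steady states.** Two-phase: integrate from the guess over doubling
time horizons until the relative state change per doubling falls below
1e-10, then polish with a damped Newton iteration (backtracking line
search on the residual, nonnegativity-guarded). Residuals are
expressed relative to the gross flux of each balance equation (the sum
of the absolute values of its terms), which makes a single convergence
threshold (1e-9; typically 1e-13 is reached) meaningful across
variables spanning seven orders of magnitude. Parameter scans and
response coefficients use a warm fast path — Newton directly from the
neighbouring solution — falling back to the full two-phase search on
failure.

**Stability and uniqueness.** Stability is the sign of the largest
real part of the Jacobian spectrum at the converged state; for the
reduced variant the spectrum is taken on the 9 active degrees of
freedom (the frozen rows are identically zero and would only add
spurious zero eigenvalues). The uniqueness probe draws starts
log-uniformly within ±2 decades of the reference state (fixed seed)
and clusters converged results at 0.1% relative tolerance (absolute
below 1 m.p.c.).

A caveat the analysis surfaced: the retrotransposon-free subspace
(all element species zero) is invariant, so an RTE-extinct fixed point
coexists with the active state at every parameter setting, and because
the ORF1p occupancy factor makes re-invasion quadratic in the
perturbation, that point is even linearly stable. Positive randomized
starts converge to the active state in practice, which is the sense in
which the active reference state is "the" stable steady state. Below
a critical `w_L/lambda_L` ratio the active branch disappears
altogether and warm-started scans legitimately continue onto the
extinct branch.

**Drop metrics.** `T_drop` is the total Lebesgue measure of
`{t : a(t) < threshold}`, with crossing times located by root
bracketing on the Radau dense output to 1e-3 min (the measured
durations are O(5 min)); the single-dip dynamics of the scenarios make
the total-time and first-interval definitions coincide, and the total
is the more robust choice. `a_min` refines the sampled minimum with a
bounded scalar minimization. Scenario runs integrate to 1e4 min and
extend tenfold (to at most 1e7 min) while ATP has not yet returned
above threshold.

**Scans and inverse queries.** 1D/2D fold scans solve outward from
fold 1 with warm starts (row-wise for 2D). The fold reaching a target
ATP fraction expands a geometric bracket from 1 and bisects on the
log-fold to 1e-3 in the fraction. The copy-number threshold fold
bisects on the log of the initial fold to 5% relative. Because the
stationary equations contain `w_L` and `lambda_L` only through
`L* = v_intL/lambda_L` and `omega_L = (w_L/lambda_L)·v_intL·MM(a)`,
stationary quantities depend on these two parameters solely through
their ratio; the 1D scans of the two parameters are exact mirror
images and the equal joint fold reaching a given ATP level is exactly
the square root of the single-parameter fold.

**Sensitivity.** Response coefficients are central finite differences
with relative step 1e-3, re-solving the steady state on each side; the
step sits well above the 1e-9 solver residual and well inside the
smooth response range. Both raw derivatives and elasticities
(`∂a*/∂p · p/a*`) are reported; ranking claims use elasticities
because the parameters span ~12 orders of magnitude and raw
derivatives would rank by units alone.

**Calibration.** Least squares on relative residuals of the
stationary (ATP, L1, Alu) counts against their targets, optimized in
log-parameter space (positivity without constraints;
Levenberg–Marquardt for ≤3 free parameters, trust-region reflective
otherwise). With the full 11-parameter free set the problem is
underdetermined, so a mild quadratic log-space penalty (weight 1e-4 by
default) anchors the fit to its initial guess, keeping the shipped
defaults a reproducible fixed point; recovery tests run unregularized.

## Problem sizes

Default grids: 25 log-spaced folds per decade over [0.1, 10] for 1D
scans, 9 points per decade over [1, 1e4] for copy-number sweeps; the
uniqueness probe uses 20 starts. The shipped experiments each run in
seconds on one CPU; the full test suite and the reproduction script
complete in about a minute each.

## Known limitations

- The printed reference value of the L1 mRNA–ribosome complex
  (`cL = 1.8e5`) is inconsistent with its own flux balance; the model
  converges to `cL ≈ 1.08e5` while matching every other reference
  value within ~1%. `cL` is therefore excluded from reference
  comparisons.
- The `w_L`/`lambda_L` ratio symmetry above means the two headline
  perturbation targets cannot be distinguished at stationarity; only
  transient dynamics separate them.
- The model tracks full-length, active elements only; truncated L1
  copies, p53/BRCA1/KRAS feedbacks, immune signalling and any explicit
  cell-death mechanism beyond the 30%-of-reference ATP marker are out
  of scope.
- No stochastic (Gillespie-type) simulation and no bifurcation
  tracking beyond the documented scans.
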