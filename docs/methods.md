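# Methods

## Pathway reconstruction

The packaged default network (`carokin/data/network.json`) is a canonical
mevalonate→carotenoid reconstruction for a β-carotene-producing yeast:
ERG10, ERG13, the HMG1/HMG2 isozyme pair, ERG12, ERG8, MVD1, IDI1, two
ERG20 condensations, the BTS1/CrtE isozyme pair, two ERG9 half-reactions
(presqualene diphosphate formation and its NADPH-dependent conversion to
squalene), CrtYB phytoene synthase, four CrtI desaturation steps
(phytoene → phytofluene → ζ-carotene → neurosporene → lycopene), CrtYB
lycopene cyclase, and two accumulation sinks. That yields 29 metabolites,
14 enzymes and 22 reactions. Species fall into two classes: 17 *balanced*
intermediates fully contained in the pathway (mass-balanced at steady
state) and 12 *unbalanced* externals (acetyl-CoA, CoA, NADP(H), adenine
nucleotides, phosphates, CO₂, squalene and the desaturase redox carrier),
which are only concentration-bounded. Water and protons are omitted, as
usual for kinetic models in concentration space.

A rank argument fixes the balanced split: with the two isozyme pairs lumped
the network has 20 independent columns, and a three-dimensional steady-state
flux space requires 17 independent balance rows. The free coordinates are
`SK_lyc`, `SK_b_car` and `ERG9b`; `propagate_fluxes` solves the remaining
17×17 system exactly. CrtI is modelled as four sequential desaturations
because the enzyme performs four chemically analogous FAD-dependent steps;
the intermediates are genuine pathway species, and the sub-steps share the
CrtI enzyme level. The reconstruction is data, not code — users can
substitute their own JSON with different padding or bounds.

Units: concentrations mol/L, fluxes mmol per litre of cell volume per hour.
All reference fluxes are positive because reaction direction is defined as
the producing direction.

## Reference condition and unit conversion

The anchor condition is the best-producing strain at the low dilution rate
(0.101 1/h) from the packaged chemostat rate table. Specific rates
(nmol/gDCW/h) convert to volumetric rates with the factor
density×1000/(1+moisture) = 1102.9/2.525 ≈ 436.8 gDCW per litre of cell
volume, using a cell density of 1.1029 g/mL and a moisture content of
1.525 g water/gDCW. The ERG9b flux is proportional to growth rate; the
proportionality constant defaults to 0.025 mmol/gDCW per unit growth rate,
chosen so that the squalene-branch flux is the same order of magnitude as
the carotenoid sink fluxes (an ergosterol demand of roughly 10 mg/gDCW of
biomass gives the same order). It is a config input (`erg9b_coeff`), since
deriving it properly requires genome-scale analysis outside this package's
scope.

Transcript data are reduced with the Common Base method: per replicate the
efficiency-weighted log quantity L = −Cq·log₁₀(E); relative expression is
10^(L̄_cond − L̄_ref) with a pooled-variance t interval on the difference of
means, exponentiated. The interval is exact under Gaussian Cq noise with
equal variances, which is also what the synthetic qPCR generator produces —
a Monte-Carlo test confirms ≈95% coverage.

## Thermodynamic reference states

Standard reaction energies (kJ/mol, 298.15 K — the temperature the energy
table refers to, kept for internal consistency even though cultivation runs
warmer; configurable) are packaged as an estimates table with provenance
uncertainty. Feasible ΔG ranges come from TMFA-style linear programs over
the log-concentration box, clipped by the flux-direction half-line.
Balanced species range over 10⁻⁹–10⁻¹ M except lycopene, whose lower bound
is extended to 10⁻¹¹ M so that the carotenoid fluxes remain
thermodynamically feasible; unbalanced bounds are literature-informed
estimates stored with the network.

Reference states are sampled sequentially along the pathway: each distinct
chemistry (isozymes share one ΔG_r) is assigned a pivot metabolite that
first appears there, non-pivot concentrations are drawn log-uniformly, and
ΔG_r is drawn uniformly on its conditional feasible range with the pivot
concentration following exactly. Draws hitting an empty conditional range
are rejected wholesale. Accepted states therefore satisfy
ΔG_r = ΔG° + RT·Σ s_i ln c_i to machine precision rather than to an
optimiser tolerance, and the marginal of each ΔG_r is uniform conditional
on the upstream draws (exactly uniform whenever the pivot box does not
bind, e.g. in single-reaction networks). A direction margin (default
0.25 kJ/mol) keeps every sampled energy strictly away from equilibrium,
which also bounds the exchange fluxes of the kinetic particles and hence
the condition numbers of the state solves.

## Particle sampling and rate evaluation

Per catalytic cycle: reversibilities from a flat Dirichlet (floor 0.02,
resampled), state abundances from a flat Dirichlet over the pattern's
states (floor 10⁻³); one-way fluxes v⁺_i = v·R_i/(R_i−1), v⁻_i = v/(R_i−1)
with R_i = exp(−r_i ΔG_r/RT); elementary constants
k⁺_i = v⁺_i/(u_from·c_ref), k⁻_i = v⁻_i/(u_to·c_ref). The floors exclude
pathologically stiff particles (a vanishing reversibility or abundance
implies an unbounded rate constant) and distort the flat priors only in
their extreme tails. Anchoring and the Haldane relationship then hold by
construction, which the tests assert at 10⁻⁹ (observed ~10⁻¹⁴). Dead-end
inhibitor branches bind the free enzyme with zero net flux at reference;
their exchange flux is sampled log-uniformly within a decade of the cycle
flux. The HMG2 allosteric modifier is a two-conformation factor
f = 1/(1+L(1+[eff]/K)) normalised to 1 at reference, with L log-uniform on
[10⁻⁴,10⁴], K within a decade of the reference effector concentration and
GGPP as the default effector (the physiological signal for HMG2 turnover;
flagged as an assumption in the network file). Sinks are first-order mass
action anchored at the reference flux.

Rates solve the enzyme-state balance M(c)u = 0, Σu = 1 by LU factorisation
with one iterative-refinement pass (the catalytic net rate is a small
difference of large one-way fluxes). Derivatives dv/d ln c come from
implicit differentiation of the same system and back the elasticity module
and the steady-state optimiser; a central-difference fallback is kept as a
cross-check. Patterns are grouped by state count and evaluated through
batched LAPACK solves; a full network rate+Jacobian evaluation costs well
under a millisecond.

## Condition simulation and rejection

For each particle and condition, a steady state is sought with enzymes
inside their 95% CI boxes and relative concentrations inside 0.01–100
(balanced) / 0.1–10 (unbalanced). The solve is staged: first the square
system over balanced log-concentrations with enzymes clamped at the CI
means (the documented initial guess, metabolites starting at 1), then — if
that stalls — a joint bounded trust-region least-squares over
concentrations and enzymes. Feasibility requires a maximum imbalance below
10⁻⁶ × the median reference flux; non-convergence marks the particle
infeasible for that condition rather than raising. The solver is a
trust-region reflective nonlinear least-squares (analytic Jacobian, box
bounds, 150 iterations per stage): the steady-state objective is an exact
residual system, for which this method proved markedly more robust than a
general SQP on the same bounds.

Discrepancy is a weighted Euclidean norm over conditions and free fluxes
with weights 1/σ², σ = CI half-width / 1.96. Rejection keeps the
⌊cutoff·n⌋ lowest scores among feasible particles (ties broken by index);
infeasible particles are excluded from the posterior and counted.
Cross-validation reuses the per-condition squared errors, so swapping
train/test roles costs no re-simulation. Prior/posterior separation is
tested with a two-sided Wilcoxon rank-sum.

## Metabolic control analysis

Scaled elasticities at the anchor state (optionally at fitted states) feed
the standard matrix formulae: C_S = −L(N_r (∂v/∂c) L)⁻¹N_r and
C_J = I + (∂v/∂c)C_S, scaled by reference fluxes/concentrations. The link
matrix is computed generally (QR row selection), though the default network
has no conserved moieties among balanced species. Responses to enzymes and
to unbalanced metabolites compose control with the corresponding
elasticities; the response of any flux to CrtYB equals the sum of the
control columns of its two reactions, as the chain rule requires. Summation
(rows of C_J sum to 1, of C_S to 0) and connectivity theorems are verified
at 10⁻⁶ in the tests (observed ~10⁻¹⁴).

Ensemble summaries bootstrap the mean of each coefficient over the
posterior particles. The default resample count is 10⁶ (computed in
chunks); the recovery experiments use 10⁵, which resolves p-values to
10⁻⁵ — far below the Bonferroni-corrected 0.05 threshold over the
14-enzyme family tested. Two-sided percentile p-values equal twice the
smaller tail mass of the bootstrap mean around zero; a reported 0.0 means
"below 1/B".

## Perturbation scenarios and robustness

Enzyme perturbations clamp the target to its factor ±1%, other enzymes to
1±1%, metabolites free; metabolite perturbations clamp one unbalanced
species ±1% with enzymes free within ±10%. Default factor grids are
log₂-spaced {¼,½,1,2,4}; Crt-gene grids can be supplied as copy-number
ratios via the spec. The 67% CrtYB upregulation (~two extra gene copies) is
available as a composable base state so secondary perturbations stack. The
HMG1 sweep extends the factor grid to 10–100× to emulate strong
constitutive overexpression of a deregulated variant. The robustness
criterion classifies a component by the ensemble fraction f with
β-carotene sink flux below the reference CI lower bound: none (f ≤ 5%),
medium (5% < f ≤ 20%), high (f > 20%), strict inequalities.

## Synthetic data generator

The generator defines the study conditions the pipeline is validated on:
a ground-truth particle anchored at the packaged reference fluxes; strains
as enzyme-level multipliers, by default a two-strain design expressing the
heterologous CrtE/CrtI/CrtYB at 61/89/68% and 27/51/33% of the reference;
flux observations with multiplicative lognormal noise (sd 0.10, giving 95%
CI half-widths of ~20%, comparable to the packaged chemostat rate table);
relative enzyme levels with lognormal sd 0.05; and qPCR threshold cycles
Cq = Cq_ref − log(ratio)/log(E) with Gaussian replicate noise (sd 0.2
cycles). Strain steady states are solved exactly with unbalanced species
held at reference (the strains differ only in enzyme dosage), and the
generating fluxes are stored for recovery scoring. A candidate truth under
which a study strain has no steady state inside the assumed physiological
windows is redrawn: such a truth could not have produced the emulated
experiment. Scenario tilting (`crtyb_limited`, `erg13_limited`) forces the
target enzyme's free-enzyme abundance share low (saturation → high flux
control) and everyone else's high (first-order operation → control passed
downstream).

What the generator does *not* emulate: correlated measurement errors,
growth-rate-dependent expression changes, extracellular dynamics,
regulation beyond the packaged entries, and model misspecification (the
fitted structure family always contains the truth's). Passing recovery
tests therefore demonstrate the soundness of the inference machinery, not
the adequacy of any particular reconstruction for real data.

## Problem sizes and numerical defaults

The documented desk-scale experiments use a 1,000-particle prior (simple
structure, two synthetic strains, 1% cutoff) for flux recovery and a
400-particle prior (detailed structure, 5% cutoff → 20 posterior particles)
for control-structure recovery; both finish in minutes on one CPU. The
full-scale design the machinery supports — 10,000 particles with a 1%
cutoff retaining 100 — is exercised at the arithmetic level on synthetic
score vectors. Other defaults: steady-state imbalance tolerance 10⁻⁶ ×
median reference flux; optimiser iteration cap 150 per stage; thermodynamic
direction margin 0.25 kJ/mol; Dirichlet floors 0.02 (reversibilities) and
10⁻³ (abundances); per-particle random streams derived from one root seed
by counter offset, so results are independent of evaluation order and
reproducible bit-for-bit under a fixed configuration.

## Known limitations

* The reconstruction's padding (four CrtI steps) and the unbalanced-species
  concentration bounds are literature-informed defaults, not measured
  values; both live in data files and should be replaced when a curated
  reconstruction is available.
* ΔG° uncertainty is recorded but not propagated into the feasible ranges —
  concentration freedom dominates them by an order of magnitude.
* Transfer of the posterior across dilution rates is not modelled; each
  growth rate is an independent anchor.
* The steady-state solve returns one point of a possibly multi-valued
  manifold; the staged initial guess (enzyme means, concentrations at 1)
  makes the selection deterministic but not globally optimal for the
  discrepancy.
* HMG1's translational feedback cannot be represented by activity-level
  regulation; the HMG1 sweep emulates a deregulated variant only in the
  activity sense.
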