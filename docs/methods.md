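# Methods

`personaflux` computes genetically personalised, organ-specific metabolic
flux maps from a constraint-based metabolic network, organ-average gene
expression and per-individual gene scores, and screens the resulting
fluxome against quantitative features and survival outcomes.  This note
describes the models, their assumptions, the tunable parameters, and the
choices made where the design was genuinely open.

## Constraint-based networks

A network is the polytope of steady-state flux vectors

    { v : S v = 0,  lb <= v <= ub }

with one mass-balance row per *non-boundary* metabolite.  Metabolites in
blood or bile compartments are flagged boundary (constant concentration) so
an organ subnetwork can run self-contained.  Fluxes are in mol/day.

Organ assembly restricts a base reconstruction to a reaction set, sets each
exchange bound to the arithmetic mean of the two parent whole-body (male and
female) models — a reaction listed by only one parent keeps that parent's
bounds, since there is nothing to average — and drops orphan metabolites.
Reaction-id liftover between reconstructions is a reported partition into
mapped/unmapped; unmapped ids are left to manual curation and one-to-many
entries are kept in full.  Model validation uses (i) the fraction of
reactions able to carry |flux| above 1e-6 mol/day anywhere in the feasible
set, and (ii) feasibility of metabolic tasks, checked as an LP in which all
exchanges are closed, task inputs get sources and required outputs get
sinks with the required rate as lower bound.

Linear programmes are solved with HiGHS (scipy) at a feasibility tolerance
of 1e-9; flux vectors are *reported* feasible when mass balance, bounds and
any extra rows hold to 1e-6.  Both tolerances are arguments.

Reversible reactions (lb < 0) are split into irreversible forward/reverse
copies before any expression-weighted or log-scale step, so that every flux
is non-negative; net flux = forward − reverse is recoverable from the split
map.  The split preserves the feasible set of net fluxes (tested by mapping
sampled points both ways).

## Expression mapping

Reaction expression for the reference state sums the organ-average TPM of
all genes annotated to a reaction and log2-transforms:
`x = log2(1 + sum TPM)`.  The +1 pseudocount (configurable) guards gene
sets with zero total abundance; sums are used for AND as well as OR gene
relationships, i.e. the boolean rule structure is deliberately flattened.
Complex (AND) semantics conventionally use a min rule instead; that is a
known approximation of this package.

Per-individual reaction activity fold changes are the abundance-weighted
mean of per-gene fold changes:

    FC_{R,n} = sum_{g in g_R} GTEx_g 2^{S_{g,n}} / sum_{g in g_R} GTEx_g

where S_{g,n} is the individual's log2 gene score (e.g. imputed from
genotype with elastic-net weights, `score_genotypes`).  Genes without a
score contribute S = 0 (no change), so sparsely imputable reactions default
towards FC = 1; reactions whose gene set has zero total abundance are set to
the neutral FC = 1.  FC is therefore bounded by the per-gene extremes
min 2^S <= FC <= max 2^S, invariant to rescaling the abundances, and
strictly increasing in every score — all property-tested.

## Reference flux distribution

1. **Objectives.** Each organ objective forces `lb = fraction x FVA-max`
   for its reaction.  The fraction is configuration (default 0.5 when
   unspecified); jointly infeasible objectives raise an error naming them.
2. **Expression-weighted minimisation.** Minimise
   `sum_i v_i (max(0, P95 − x_i) + 1)` over the split network, where P95 is
   the 95th percentile of x over mapped reactions (log2 scale); unmapped
   reactions get weight 1.  Reactions backed by low transcript abundance are
   penalised, yielding enzymatically parsimonious solutions.
3. **Near-optimality restriction.** The polytope is restricted to weighted
   totals within 99% of the optimum.  For a minimisation this is read as
   `total <= optimum / 0.99` (the conservative reading; a multiplicative
   mode `optimum x 1.01` is available for comparison).
4. **Sampling.** The restricted polytope is sampled with artificially
   centred hit-and-run: warm-up points are the optimal vertices visited by
   per-reaction FVA, directions are differences between a stored point and
   the running centre projected exactly onto the null space of S (so mass
   balance cannot drift over long chains), the centre updates after every
   accepted point, and every `thinning`-th point is recorded.  Defaults are
   1000 samples at thinning 1000; the sampler is fully deterministic given
   its seed.  Degenerate dimensions (lb = ub, or an empty interior after
   restriction) are handled by zero-length steps.

The reference distribution v_ref is the per-reaction mean of the samples;
as the mean of points of a convex set it is itself feasible, which is
asserted in tests.

## Personalisation (quadratic metabolic transformation)

Per individual, the flux map is the unique minimiser of the strictly convex
QP

    min  w sum_{i in Ru} (v_ref_i − v_i)^2 / max(|v_ref_i|, m)
       +   sum_{i in Re} (v_ref_i FC_i − v_i)^2 / max((v_ref_i (FC_i − 1))^2, m)
    s.t. S v = 0, lb <= v <= ub

Re are fold-change-mapped reactions (target v_ref x FC), Ru the unmapped
rest (anchored at v_ref); both terms are scaled by the reference so
high-flux reactions do not dominate.  `w` (default 1) weighs the unmapped
anchor, `m` (default 1e-6) floors the scaling denominators.  The QP is
solved in the split (non-negative) flux space, so the two directions of a
formerly reversible reaction carry their own targets and no sign
cancellation arises.

No dedicated QP library is assumed: the solver is a sequential
quadratic-programming solve (SLSQP, analytic gradient, started from the
reference point) with a trust-region fallback with exact diagonal Hessian;
solutions are accepted only if constraint violation is below 1e-6 and are
verified in tests against closed-form reductions, an independent-start
uniqueness check and consistent-target recovery at relative error < 1e-6.

Downstream layers: `log2(v + 1e-9)` (the pseudo-flux guards exact zeros;
configurable) and per-reaction z-scores using the sample (n−1) standard
deviation; zero-variance reactions are set to 0 and flagged.

The hyperparameters (w, m) are tuned by grid search — defaults
w in {100, 10, 1, 0.1, 0.01}, m in {1e-6 … 1e-12} — scoring each cell by
the sum of R² over all flux-feature pairs of the linear association screen,
with the same pruning settings as the production screen.  Ties break to the
earlier grid entry, making the search deterministic.

## Association screens

**Features** are preprocessed by dropping columns with > 75% missing values
and (when a second cohort's standard deviations are supplied) columns with
|log2 sd ratio| > log2 2.5, residualising on covariates by per-feature OLS,
and z-scoring.

**Collinearity pruning** is greedy: while any pair of columns exceeds the
|Pearson rho| threshold (0.9 for fluxes, 0.75 for features), the member of
the most-correlated pair with the larger mean absolute correlation to all
remaining columns is removed; remaining ties break lexicographically.  The
procedure is idempotent and deterministic.

**Linear screen.**  Each feature is regressed on each standardised flux
(`Met = a v + e`); an intercept is fitted even though both sides are
centred, so the slope is robust to preprocessing drift.  Significance is a
two-tailed t-test on the slope; Benjamini-Hochberg adjustment runs across
all flux x feature pairs jointly, with a default adjusted-p threshold of
1e-6.  Zero-variance flux columns are skipped with a note.

**Survival screen.**  One Cox proportional-hazards model per flux with age
as the time scale (left truncation at entry age), stratified by sex and
adjusted for caller-specified covariates, fitted by lifelines.  The flux
coefficient is the log hazard ratio per standard deviation of
log-transformed flux; significance is a two-tailed Wald test and BH
adjustment runs across all converged fluxes (non-converged fluxes are
flagged and excluded from the family, with a warning).

**Enrichment** of hit sets within labelled groups uses the one-sided
(greater) Fisher exact test, computed as the upper hypergeometric tail;
unlabelled items are excluded.  Adjustment is BH across the labels of a
call; callers pool labels across organs before adjusting when the family
should span organs.

**Reaction systems.**  Metabolites take the modal system of the
non-transport reactions they participate in (ties: lexicographically
smallest, flagged; orphans: "Miscellaneous").  Transport and exchange
reactions then take a weighted vote over their metabolites' systems, with
common transport cofactors (Na+, K+, H+, ATP/ADP, ...; configurable)
down-weighted to 0.1 — the exact down-weight is this package's choice, any
value < 1 implements "less weight".  Weighted ties resolve to
Miscellaneous with a flag.  Systems are annotations only and never affect
stoichiometry or fluxes.

## Synthetic study conditions

Cohort inputs are restricted-access in the real studies, so the simulators
generate statistical stand-ins with planted ground truth:

* gene scores are i.i.d. Normal(0, sd²) on the log2 scale, default
  sd = 0.25 so fold changes span roughly [0.5, 2];
* features are linear combinations of (standardised) fluxes plus
  Gaussian noise with configurable planted slopes;
* survival times are exponential with hazard
  `h0 x stratum factor x exp(sum logHR_i flux_i)`, uniform entry ages,
  distinct baselines per sex stratum and administrative censoring
  calibrated to a target fraction.

All randomness derives from one master seed through per-component spawn
keys.  These generators emulate the *statistical* structure the association
models assume — linearity, proportional hazards, independent noise — and
none of the biological structure of real cohorts (linkage disequilibrium,
population stratification, assay batch effects, non-proportional hazards),
so passing tests demonstrate correctness of the algorithms under their own
assumptions, not robustness to real-data pathologies.

The end-to-end verification plants one flux-feature effect (slope 0.3,
n = 2000 individuals) on a three-reaction toy network and requires the
screen to flag exactly the planted pair at adjusted p < 1e-6.  Gene-score
standard deviations in that experiment (0.7 source, 0.25 planted branch,
1.0 alternative branch) are chosen so that stoichiometric coupling
(v1 = v2 + v3) leaves flux columns correlated below ~0.3; with strongly
coupled columns an indirect association of a proxy flux is statistically
real and exact discovery would be the wrong expectation.  Verification
problem sizes (200 hit-and-run samples at thinning 20, tuning on a
300-individual subset with the full 5 x 7 grid, 100 Cox replicates at
n = 800) are chosen so the whole verification battery completes in about a
minute on a laptop while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

* GPR rules are flattened to gene sets (sums), ignoring AND semantics.
* The hit-and-run chain mixes slowly in very anisotropic polytopes; the
  defaults (thinning 1000) follow common practice, not a convergence
  diagnostic.
* The near-optimality restriction's "within 99%" has two readings for a
  minimisation; both are implemented, division is the default.
* No loopless or thermodynamic constraints; no gap-filling.
* The QP solver targets small and medium networks; genome-scale cohorts
  would want a compiled QP backend behind the same interface.
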