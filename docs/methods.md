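# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the places where the design was genuinely open.

## Light-response modelling

Fq'/Fm' declines with instantaneous light. We model it with fixed effects
only, as measurement campaigns in breeding nurseries do: the line effect and
the line × PPFR interaction are what breeders select on, and the fit must be
cheap at 10⁴–10⁵ records. Model variants:

* `basic` (single trial): `fqfm ~ line + ppfr + sqrt(ppfr) + ppfr:line`.
* `interaction` (multi-trial): adds trial main effects, trial:line,
  trial:ppfr and trial:ppfr:line interactions, the absorbance covariate
  (MTCI for canopy scans, relative chlorophyll for leaf meters), broadband
  reflectance, and optionally a device effect.
* `extended`: adds PRI, NDVI, temperature and measurement date; these
  auxiliary covariates typically explain little variance and exist mainly
  for the variance-partition report.
* `biomass`: `value ~ env + line + env:line + row + col` for spatial
  adjustment of pot/plot traits.

**Square-root versus linear light terms.** The light response flattens at
high irradiance, so the shared (population-level) trend carries both a
linear and a `sqrt(PPFR)` term. The *line-specific* response is kept on
linear PPFR, so slopes have interpretable units (Fq'/Fm' per µmol photons
m⁻² s⁻¹); a `sqrt_interaction` switch moves the interaction onto the
square-root scale for sensitivity analysis.

**Estimation.** OLS with treatment contrasts and a pseudoinverse. Partially
replicated multi-trial designs alias parts of the trial:line interactions;
the pseudoinverse returns the minimum-norm solution and the sequential-SS
machinery reports the *rank gained* by each term as its degrees of freedom,
which is the honest df for an aliased term. Slopes and adjusted means are
computed as prediction contrasts (difference over a 1 µmol step at the mean
light level, square-root term and covariates held at their grand means,
averaged with equal weight over the trial/device/date reference grid), which
makes them invariant to contrast coding and line ordering; standard errors
come from the coefficient covariance of the same contrast.

**Variance partition.** Sequential (Type-I) sums of squares, computed by
adding term blocks in an explicit order and measuring the drop in residual
SS. The order defaults to the model's term order but can be any permutation,
because published tables in this field list terms in bespoke orders. The
budget closes exactly by construction: term SS plus residual equal the total
centered SS.

**Cook's-distance screen.** A deliberately permissive single-pass rule for
gross measurement errors: discard observations with D > median(D) + 50 ×
IQR(D), then refit once. It is not iterated; with a factor of 50 it removes
only points that are orders of magnitude more influential than the bulk.

## Spatial adjustment and heritability

Adjusted line means evaluate the fitted trait model on a reference grid with
equal weight per environment and the row/column factors averaged over their
levels, emulating estimated-marginal-means semantics; additive row/column
terms mean the averaging can cycle max(R, C) paired levels instead of the
full product grid.

Heritability uses H² = σ_L / (σ_L + σ_ε / n̄) on a line-mean basis, with n̄
the total number of observations divided by the number of lines. The trait
models are fixed-effects models, but the formula needs variance components,
so the model is refit with the line term as a Gaussian random effect by REML
(statsmodels MixedLM), keeping environment/row/column fixed. Nested spatial
labels make that fixed design rank deficient; an independent column basis is
selected by pivoted QR before fitting. For the response trait, per-trial
slopes from the basic model are the "replicates" entering the same formula.

## Prediction models

All three yield models share environment fixed effects (flat prior) and a
genomic line effect g ~ N(0, K σ_g²), with K the VanRaden relationship
K = WW′ / (2 Σ p_k(1−p_k)) from column-centered dosages (missing dosages
imputed to the marker mean, monomorphic markers excluded, 10⁻⁸ × mean-diag
jitter before factorization). The G×E model adds independent per-environment
genomic deviations with a common variance, gE ~ N(0, I ⊗ K σ_gE²).

The reaction-norm (G×Ec) model replaces the categorical interaction with a
measured covariate v per line × environment cell (here the light-response
slope, centered): a fixed cell-level regression on v plus a random
regression gV = diag(v) Z a with a ~ N(0, K σ_a²), so cov(gV) =
(vv′) ∘ (ZKZ′) σ_a² — the elementwise product of the covariate and genomic
covariances on the observation grid. The published notation for this model
is ambiguous about whether v indexes environments or lines; the
cell-level reading implemented here reduces to the Kronecker form when v is
constant within an environment and is the one that makes CV2 coherent
(the covariate is cheap to measure on new lines in the new environment).

**Sampler.** A Gibbs sampler with Gaussian full conditionals for each effect
block (one Cholesky solve of an n_lines-sized system per block and
iteration) and scaled-inverse-chi-square full conditionals for the
variances. Hyperpriors use 5 degrees of freedom with scales set so each
random term's prior mode takes an equal share of half the phenotypic
variance — the convention of standard whole-genome-regression software —
and are configurable. Default chain settings are 16 000 iterations, 4 000
burn-in, thinning by 5; cross-validation studies in the tests and the
acceptance script use shorter chains (300–1 500 kept draws) after checking
that posterior means are stable at those lengths on the problem sizes used.
Predictions are accumulated for *every* line × environment cell each kept
iteration, so unobserved cells get kinship-shrunken posterior means — that
is what the CV scenarios score. With variances frozen, the posterior mean
coincides with closed-form MME-BLUP; the test suite verifies agreement to
< 0.02 phenotypic sd on a 20-line instance against an independently coded
oracle.

**Cross-validation.** Lines are split into three parts, repeatedly; CV1
masks a fold's records only in the rotating target environment (their
records elsewhere remain in training), CV2 masks the fold's records
everywhere and scores the target environment. Accuracy is the mean over
folds of the per-fold Pearson correlation on masked cells; folds with fewer
than three masked observations are skipped with a warning.

**Association scan.** Marker-by-marker linear regression of the trait on
dosage plus the first three SNP principal components, vectorized by
residualizing trait and dosages on the covariate basis; Bonferroni line at
α / n_markers; MAF < 5% markers excluded beforehand (boundary kept). This is
a plain scan for planted-signal recovery and screening, not a substitute for
modern iterative mixed-model methods.

## Synthetic-data generator

The generator emulates a two-to-five-trial screening of ~100–300 inbred
lines. Defaults, and why:

* **Marker panel**: 1 000 independent markers (no LD), allele frequencies
  uniform on [0.05, 0.5], Binomial(2, p) dosages. Enough for a well-behaved
  kinship at the simulated scale; real panels are larger but LD-redundant.
* **Slopes**: mean −1 × 10⁻⁴ Fq'/Fm' per µmol m⁻² s⁻¹ (a drop of ~0.12
  across the diurnal light range), genetic sd 3 × 10⁻⁵, G×E sd 1 × 10⁻⁵.
  The polygenic part is built from marker effects, so kinship models are
  well specified; an optional QTL adds a dosage-linear effect.
* **Measurement model**: intercept 0.78, square-root coefficient −2 × 10⁻³,
  additive noise sd 0.03 (chosen as a realistic scatter for single
  fluorescence readings; config-exposed, not a claimed instrument constant),
  truncated at ±3σ. Short-tailed routine noise is a deliberate design
  choice: "gross outlier" is a separate, explicitly planted record class,
  which is what makes filter bookkeeping exact (below).
* **Light**: a half-sine diurnal course truncated at the 100 µmol m⁻² s⁻¹
  low-light threshold, peak 1 200 ± 100 µmol m⁻² s⁻¹ day-to-day, 57
  measurement days — glasshouse-like conditions; only the marginal PPFR
  distribution matters for slope estimation.
* **Reflectance**: three red-edge bands (754/710/680 nm) back-computed from
  a short-tailed target chlorophyll index; sufficient for the index
  plumbing without simulating full spectra.
* **Planted rule violations**: configurable fractions of records violate
  each stream-level filter rule on disjoint subsets. After planting, any
  *legitimate* record that would fall outside the default 2.5 × IQR fence
  (the steepest line at the brightest moment can get there) is clipped onto
  the fence. Clipping never crosses a quartile, so the filter recomputes
  identical bounds and its removal counts equal the planted counts exactly —
  the property the filter-audit tests assert. The guarantee is tied to the
  default rule factor; custom factors revert to approximate bookkeeping.
* **Yield trial**: partially replicated (first four lines as checks at six
  replicates, others one or two), random placement on an auto-sized grid,
  row/column effect sd 0.2, environment effect sd 1, genetic sd 1. The
  residual sd is derived from the target heritability through the same
  replicate-adjusted formula the estimator uses, so H² recovery is a
  round-trip test. Yield's genetic value correlates with the line-mean slope
  (default r = 0.5, sign: shallower slope → higher yield), its
  slope-independent part is polygenic from a second set of marker effects,
  and a configurable share (default 0.8) of the yield G×E is driven by the
  slope G×E — the signal the reaction-norm model is supposed to exploit.

What the generator does *not* emulate: linkage disequilibrium and population
structure beyond random kinship, canopy architecture and radiative transfer,
temporal autocorrelation of weather, instrument drift, and non-linear light
responses. Passing tests therefore demonstrate that the estimators recover
the quantities they target under their own model class with realistic noise
— not that the linear slope is the right physiological model for any
particular crop.

## Problem sizes and tolerances

The test suite and the acceptance script run desk-scale versions of each
experiment: slope recovery at 100 lines × 200 observations, sampler-vs-BLUP
at 20 lines with 12 000 kept draws (tolerance 0.02 sd ≈ 3 Monte-Carlo
standard errors), variance-component recovery at 300 lines × 3 environments
(25% tolerance covers realized-variance and posterior-shrinkage error at
that size), CV2 model ordering over 20 simulation replicates, family-wise
error over 200 null scans (asserted at 5% plus two binomial standard
errors), and QTL power over 30–50 replicates. Numerical guards: kinship
jitter 10⁻⁸ × mean diagonal, degenerate (zero) IQRs disable the outlier rule
for that variable and trial, a zero index denominator raises rather than
returning infinity, and Cook's screening with an infinite factor is a no-op.

## Known limitations

* Slope standard errors from pseudoinverse fits understate uncertainty for
  terms involved in aliasing; rankings and correlations are unaffected.
* Adjusted means for lines absent from a trial rely on minimum-norm
  interaction estimates (effectively shrinking the missing interaction to
  zero).
* The REML bridge for heritability treats spatial effects as fixed; with
  very sparse layouts the line variance can absorb residual spatial trend.
* The Gibbs sampler factors an n_lines × n_lines system per block and
  iteration; beyond ~2 000 lines an eigendecomposition-based sampler would
  be the right replacement.
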