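# Methods

This note documents the statistical models implemented in `brainmr`, the
generative model behind the synthetic cohorts, the defaults and why they
were chosen, numerical conventions, and known limitations.

## Association scans

All scans are ordinary least squares with an intercept and user-declared
covariates; categorical covariates expand to indicator contrasts with the
first observed level dropped, and a rank-deficient design raises an error
naming the collinear columns. The per-variant GWAS and the per-region
volume scan both use the Frisch–Waugh–Lovell decomposition: covariates are
reduced to an orthonormal basis once, predictors and responses are
residualized against it, and the scanned term's coefficient, standard
error and t statistic follow from the residual cross-products with the
correct residual degrees of freedom (n − k − 1). This reproduces the full
multiple regression exactly (verified against `statsmodels.OLS` to 1e-10
relative in the tests) while scaling to thousands of variants.

Conventions: missing dosages are mean-imputed per variant before OLS (the
standard PRS/GWAS practice); phenotype and covariate missingness is
handled by complete-case removal per analysis; p-values are two-sided
throughout the scan; monomorphic variants are flagged and their statistics
set missing, never fabricated. Genomic coordinates are 1-based (VCF
convention). The genomic inflation factor is λ_GC = median(t²)/0.4549364
(the χ²₁ median), invariant to variant order and equivariant to scaling of
the test statistics.

The scan accepts a `dtype` argument; the replicated simulation studies run
in single precision, which roughly halves memory traffic with no effect on
the measured rates (final statistics are accumulated in double precision).
The default path is double precision.

**GMV-association patterns** are the vector of signed t statistics of the
trait term, one entry per atlas region. t is used rather than the raw
slope because regions differ widely in volume scale and t is scale-free; a
standardized-beta variant is available via `statistic="std_beta"`.

## Polygenic score instruments

`build_prs` selects variants with discovery p ≤ threshold (default 0.05)
and uses the discovery slope on the stated effect allele as the weight.
`clump` implements greedy lead-variant selection: repeatedly take the
smallest-p unclaimed variant with p ≤ p_index (default 5e-8) and claim all
variants within window_kb (default 250) at squared dosage correlation ≥
r2_max (default 0.1). Ties on p break toward the smaller genomic
coordinate for determinism. The clumping defaults are conventional
PRSice-adjacent values and are recorded in the model provenance as
assumptions, since studies rarely print the exact values they used. On an
LD-free panel clumping returns exactly the p ≤ p_index set regardless of
r2_max, which the tests assert.

Scoring harmonizes alleles by variant id: an entry stored on the panel's
other allele contributes weight × (2 − dosage); an entry matching neither
orientation raises an error listing the offenders. Representing a variant
on either allele changes every score by the same constant (2 × weight) and
therefore never changes any correlation or regression computed from the
score; the tests pin down exactly this contrast-invariance.

## Modified bidirectional Mendelian randomization

The identifying idea: a variant's indirect association with a downstream
trait is always weaker than its direct association with the trait it acts
on, so removing from an exposure PRS every variant whose association p
with the *outcome* falls below a threshold t — for t stepping from 0.05 to
0.50 by 0.05 — progressively strips pleiotropic and reverse-path variants
while keeping genuine exposure instruments. Because the same construction
runs in both directions simultaneously, reverse causation becomes a
testable outcome rather than an assumption.

Implementation (`BidirectionalMR.fit`):

* PRS_x and PRS_y are built at p ≤ 0.05 from two discovery GWAS that the
  caller asserts are sample-disjoint from the target cohort (the report
  stamps sample hashes; the module cannot verify disjointness from IDs it
  never sees). Pruning uses the discovery GWAS of the opposite trait —
  the only cross-association source available at scale.
* Pruning is strict (`p < t` removes), so retained sets are nested
  nonincreasing in t; the report validates this invariant.
* Each ladder row records partial correlations of the (valid-)PRS with
  both traits, computed by residualizing score and trait on the
  covariates and correlating — algebraically the t test of the OLS
  coefficient, chosen because the field reports R values.
* One-tailed p-values: the instrument-exposure test always uses the
  positive tail (a discovery-weighted score predicts its own trait
  positively by construction). The instrument-outcome tail is fixed by
  the sign of the *observational* covariate-adjusted exposure–outcome
  correlation in the target sample — an a-priori direction in the spirit
  of testing whether the genetic instrument reproduces the phenotypic
  association, and independent of the instrument noise (so the reverse-
  direction test stays calibrated). The sign is recorded in the report.

**Verdict rule.** A direction is supported when the instrument predicts
its own exposure at p < α (default 0.05) in every ladder row and the
instrument-outcome association is significant in at least `min_frac` of
rows with a consistent sign across all rows. The strict tier
(min_frac = 1.0) is the default; a lenient tier (min_frac = 0.3) is also
reported, mirroring the weaker "consistent sign but intermittent
significance" situation that arises for smaller effects. Fewer than three
usable rows in either direction forces `inconclusive`. The 2×2 of
directions maps to X_causes_Y / Y_causes_X / bidirectional / inconclusive.

**IVW cross-check.** Fixed-effect inverse-variance weighting of per-variant
Wald ratios: β̂ = Σ(β_x β_y /se_y²)/Σ(β_x²/se_y²), SE = (Σβ_x²/se_y²)^{-1/2},
two-sided normal p. First-order IVW ignores exposure-side noise, which is
why the acceptance study uses strong instruments (per-variant NCP ≫ 1);
with weak instruments the estimate attenuates and the interval
undercovers, a known property, not a defect of the implementation.

## Pattern similarity and the ID-shuffle null

The statistic is the Pearson correlation over pairwise-complete regions
(≥ 3 required) between two spatial signatures. The null distribution
shuffles which individual each row of the volume matrix belongs to — one
shared permutation per iteration — and recomputes every pattern involved
from scratch. This severs all volume–phenotype links while preserving (a)
the covariance of volumes across regions, so spatially oversampled or
correlated regions cannot inflate false positives, and (b) the
trait–covariate structure. For a pair of traits both patterns are
regenerated from the same shuffled volumes, preserving the cross-trait
null dependence induced by sharing one imaging matrix; for
expression-vs-pattern tests the expression profile stays fixed.

p_perm = (k+1)/(n_perm+1), guaranteeing validity; at k = 0 the result is
displayed as the bound "< 1/n_perm" (e.g. `<1E-04` at 10,000
permutations). Two-tailed (absolute-value) comparison is the default;
one-tailed mode serves replication-style tests. Permutation counts below
100 are refused as unstable. Internally the permuted-data patterns come
from the same closed-form residual scan as the association module (the
tests assert exact agreement with `RegionalAssociation`), and the
transcriptome-wide screen computes the null pattern once per iteration
and correlates it against all genes — provably identical p-values to the
naive per-gene loop (asserted by test), at a fraction of the cost. BH
q-values are computed across genes, and a discovery/replication helper
keeps genes with q < α in discovery, p < 0.05 in replication, and
consistent sign.

## Mediation

Baron–Kenny causal steps: τ from y ~ x (+covariates), τ′ and b from
y ~ x + m (+covariates), a from m ~ x (+covariates); four criteria flags
at a configurable per-path α (default 0.05, two-sided). PM = (τ−τ′)/τ; in
the linear no-covariate case τ − τ′ = a·b holds to numerical precision
(asserted at 1e-8). The bootstrap resamples *individuals* with
replacement, refits all paths in every draw (no hat-matrix reuse —
correctness over speed at desk scale), and reports the doubled chance of
PM < 0, capped at 1, with exact zeros counting half (so a degenerate
comparison of identical models yields p ≈ 1) and a zero count reported as
the bound "< 2/n_boot". Draws with a degenerate τ are excluded and
counted; more than 10% of them flags the result unstable (the threshold
is an assumption). If more than 25% of PM draws are negative the result
carries a sign-convention warning, since PM is only interpretable as a
proportion when the effect directions are concordant.

**Excess PM.** Two models sharing the exposure and the sample are compared
by PM_A − PM_B per draw, with the *same* resample applied to both. When
the two candidate mediators proxy the same pathway their PM draws co-move
and pairing strictly reduces the excess variance (a regression test pins
this); for reversed-outcome comparisons the draws can anticorrelate, in
which case pairing is still the right choice — the comparison is then
evaluated on identical data — but not a variance reduction. A mediator is
preferred only when the doubled-tail p falls below the declared level and
the point excess has the matching sign; degenerate draws above 10% in
either model force "undecided".

## Synthetic cohort generator

Generative model (all effects additive-linear, variants independent by
default):

* **Genotypes**: dosage = two independent Bernoulli(maf) allele draws
  (exact HWE), maf ~ U(0.05, 0.5). An optional AR(1) latent-allele block
  mode exists solely to exercise clumping; independence keeps every
  oracle closed-form.
* **Diets**: diet = Z·β + covariate effects + N(0, 1−h²), with Z the
  HWE-standardized dosages, Σβ² = h² (default 0.2 each). The n_shared
  pleiotropic variants receive *exactly* proportional opposite-sign
  effects on the two diets (sample correlation −1 by construction),
  emulating a negative genetic correlation between a cereal-like and a
  coffee-like trait.
* **Volumes**: region r gets baseline + pattern_r·(β_raw·diet_y) + direct
  genetic loading + covariate effects + N(0, σ_r²). The loading pattern
  defaults to a lobe-structured random vector (8 contiguous blocks with
  shared means, mean ≈ 1) so regional effects are spatially organized.
  β_raw is solved in closed form so that the *standardized* causal effect
  of diet_y on total volume (the row sum) equals `causal_beta_xy`
  (default −0.1 SD per SD, the coffee-reduces-volume direction). A direct
  polygenic volume score (disjoint variants, h2_vol of the
  covariate-adjusted TGMV variance) makes the reverse-direction
  instrument non-trivial, and `n_pleiotropic_vol` diet-y variants carry
  additional direct volume effects — the exclusion-restriction violations
  the MR pruning ladder exists to remove (default 10% of the diet-y
  causal set).
* **Mediation chains**: one designated diet-y-specific variant carries a
  forced standardized a-path (within the h² budget; a diet-y-specific
  rather than a shared variant so the exact −1 shared-effect correlation
  and the forced path cannot conflict), and BMI = b·diet_y + c′·g + noise
  scaled to unit variance; true PM = ab/(ab+c′) (defaults 0.1, 0.3, 0.03
  → PM = 0.5). A lifestyle trait follows a second, fixed chain.
* **Expression**: n_signal_genes rows are r·z(pattern) + √(1−r²)·noise
  (default r = 0.6), the rest standard normal.
* **Covariates**: age ~ N(55.1, 7.46), sex ≈ 52% female, two assessment
  sites at 84.5/15.5% — matching the demographic profile typical of a
  middle-aged population cohort — with small fixed effects on diets and
  volumes (brain volume shrinks ~2 units/region/year of age).
* **Determinism**: one master seed spawns per-component child seeds
  (logged in the truth record); an identical config reproduces the cohort
  byte-for-byte through serialization.

What the generator does **not** emulate: realistic LD maps, imputation
dosages, population stratification, gene–environment interaction, ordinal
measurement of intake (a rounding mode exists but is off by default —
the study treats intake as continuous), spatial autocorrelation of the
expression noise, and donor-level expression aggregation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data complications.

## Study conditions used by the replicated studies

`brainmr.studies` fixes the following desk-scale conditions (also used by
`scripts/acceptance.py` and the acceptance tests):

* **MR direction recovery**: 50 replicates; each simulates one cohort of
  40,000 (so that the discovery GWAS half and the target half are
  disjoint samples of n = 20,000 each from the same population), m =
  2,000 variants, h² = 0.2, standardized causal effect −0.1, 10%
  pleiotropic variants. The half-split mirrors the design of running
  discovery GWAS and instrument tests in separate release batches.
* **IVW**: 200 two-sample simulations, 20 equal-share causal instruments,
  h² = 0.4, discovery n = 50,000, target n = 10,000, true β = 0.3 —
  chosen from a power analysis so instruments are strong (per-variant
  z ≈ 7) and first-order IVW's known weak-instrument attenuation is
  negligible relative to the Monte-Carlo resolution.
* **Permutation calibration**: 500 null replicates at n = 200, 40
  regions, n_perm = 199. **Power**: 60 replicates at n = 2,000 with two
  planted patterns of exact sample correlation 0.6 and per-region |t| ≈ 8,
  n_perm = 999. The larger n in the power arm keeps the effect-induced
  regional covariance (which widens the permutation null, as it should)
  small relative to the planted signal.
* **PM recovery**: 20 chains at n = 100,000 with (a, b, c′) =
  (0.3, 0.4, 0.12), true PM = 0.5. **Excess PM**: 50 chains at
  n = 20,000, 500 bootstrap draws, wrong model = mediator/outcome
  reversed.

## Numerical choices and degenerate inputs

* Residualized predictors with sum of squares below 1e-12 of scale are
  treated as constant (flagged missing).
* p-values are clipped into (0, 1] — never exactly 0.
* QR decomposition for covariate bases; Cholesky with pseudoinverse
  fallback for the small mediation fits.
* Bootstrap and permutation p-values are deterministic given the seed;
  all seeds derive from one `SeedSequence` and stay below 2³¹.
* Volumes are clipped at 0 only as a container invariant; under the
  default noise scales clipping is a ~10⁻⁸-probability event per cell.

## Limitations

Single-variant OLS ignores relatedness and stratification (no mixed
models); clumping uses in-sample dosage correlations, not an external
reference panel; the MR verdict rule treats ladder rows as exchangeable
evidence and does not model their dependence; IVW is fixed-effect only
(no Egger/median estimators, by scope); the mediation model assumes
linearity and no exposure–mediator interaction; and the permutation null,
while robust to regional covariance, does not preserve spatial
autocorrelation of *expression* maps (no spin-test analogue).
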