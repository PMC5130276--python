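# Methods

This note documents the statistical procedures, the generative model behind
the synthetic cohorts, the numerical choices, and the limits of what the
simulations can show.

## Association model

Each gene is fit independently by OLS on `[1, x, covariates]`, where `x`
is sex (F = 0, M = 1) or age at surgery in years. The scan is vectorized:
one pseudoinverse of the design serves all genes, with per-gene residual
variance on `n − p` degrees of freedom, two-sided p-values from the t
distribution, and Benjamini–Hochberg step-up FDR across the genes of the
analysis at hand (genome-wide in discovery; within the tested candidate
subset in validation). Sex and age are analyzed in separate
single-variable models; no moderation (shrinkage of σ_g) is applied —
the point is the plain linear-regression scan, and a moderated variant
would change the calibration being studied. Smoking enters as indicator
columns with never-smoker as reference; samples whose smoking status is
"unknown" are dropped (with a logged count) whenever smoking is a
covariate, since imputing a reference status would dilute the adjustment.

Sign conventions: positive β means male-higher (sex) or rising with age.
Signed fold change is `2^β` for β ≥ 0 and `−2^(−β)` otherwise; the map is
exactly invertible and its image is (−∞, −1] ∪ [1, ∞).

## Preprocessing

1. **Probe filter.** Keep probes that map to a gene symbol and are
   detected (detection p < 0.01) in at least 10% of samples. The boundary
   is inclusive: "fewer than 10%" are removed, exactly 10% is kept.
2. **Collapse.** One probe per gene — the one with the highest detection
   rate; ties break to the lexicographically smallest probe id so the
   result is deterministic.
3. **Quantile normalization.** Every sample's distribution is replaced by
   the mean order-statistic distribution; ties receive the mean of the
   tied reference values, so the operation is idempotent. This is a
   deliberately simple, fully specified surrogate for spline-based
   intensity normalization; a `normalization: none` switch exists.
4. **Batch adjustment.** Parametric empirical-Bayes location/scale
   adjustment: genes are standardized by a least-squares fit of batch
   means (plus any protected covariates), per-batch/per-gene location
   (γ) and scale (δ²) estimates are shrunk toward normal and
   inverse-gamma priors fit across genes by method of moments, and the
   shrunken effects are removed. The EB iteration stops when the relative
   change in (γ*, δ*) falls below 1e-4 (at most 100 iterations), matching
   the reference implementation's convention; a test compares the output
   with Bioconductor `sva::ComBat` to 1e-3. By default no biological
   covariates are protected (batches are two halves of one cohort,
   adjusted before any association testing); a covariates hook is
   exposed. Batch labels always come from the sample sheet — they are
   never inferred.

A caveat worth knowing: on a gene whose variance is dominated by a huge
group contrast (the Y-linked ~49-fold gene), EB rescaling without
protected covariates attenuates the contrast slightly (~2–3% in fold
units in our simulations). This is inherent to running the adjustment
blind to the biology, not an implementation artifact.

## Permutation null

Only the variable of interest is shuffled; covariates stay attached to
their samples, because shuffling them too would test a different null.
Each cycle re-runs the exact discovery scan (OLS + genome-wide BH) and
records the number of significant genes and, per candidate gene, whether
it passed. Shuffling is unstratified (age permutation does not preserve
sex composition); the summary is an exact function of the persisted
per-cycle counts, so it is auditable after the fact. Under a global null
with ~11,000 independent genes, BH yields zero rejections in ≈95% of
cycles and the expected count stays well below 1 — the observed discovery
counts must be judged against that scale.

## Validation and intersection

Validation BH runs within the candidate subset actually present on the
cohort's platform (missing candidates are recorded, not imputed). A gene
validates in a cohort iff FDR < 0.05 there *and* its coefficient has the
discovery sign; a zero coefficient counts as non-concordant and is
logged. Genes significant anywhere with the opposite sign are
contra-regulated and globally excluded — one discordant cohort disqualifies
a gene everywhere. The common set intersects the per-cohort validated
lists; Venn region counts use plain significance per dataset so the region
sums reconstruct each dataset's significant-gene count. Chromosomal
bookkeeping distinguishes autosomes (with the number of distinct autosomes
involved), non-pseudoautosomal X and Y, and pseudoautosomal genes
(annotated "X;Y").

## Enrichment

Genes are ranked by descending t statistic (ties broken alphabetically for
determinism). The enrichment score is the signed extremum of a running sum
that increments by `|score|^w / Σ|score|^w` at set members and decrements
by `1/(N − N_set)` elsewhere; the default weight w = 0 gives the classic
Kolmogorov–Smirnov form (the running sum then ends exactly at zero and
|ES| ≤ 1), with w = 1 available for parity with common GSEA software.
Sets are intersected with the analysis universe *before* the 15–500 size
filter, matching standard GSEA behavior. Significance uses phenotype
permutation — the variable is shuffled, t statistics recomputed, genes
re-ranked, ES recomputed — with the add-one estimator
`p = (1 + #{|ES_null| ≥ |ES|}) / (B + 1)`; NES divides ES by the mean
|null ES| of matching sign; BH runs across the tested sets. The
enrichment map connects sets with FDR below the cutoff when their overlap
coefficient |A∩B| / min(|A|, |B|) is ≥ 0.5 (inclusive), with shared-gene
counts as edge weights.

## The synthetic cohorts

The generator emulates the study design, not the platform: a 284-sample
discovery cohort (202 M / 82 F, two processing batches of 206 and 78,
essentially all smokers, ages 36–85 M / 40–83 F) and three validation
cohorts of 409 (229 M), 339 (182 M) and 363 (193 M) samples with mixed
smoking including "unknown" strata. Per gene and sample the model is
baseline + sex effect + age slope + smoking shift + batch location shift,
plus Gaussian noise scaled by the batch scale factor. Parameter choices:

- **Ages** are uniform over the per-sex observed ranges. The real age
  distributions are bell-ish around the mid-60s; uniform matches the
  printed ranges, is simple, and only mildly overstates age variance
  (which makes age-slope recovery slightly easier than reality — a known
  optimism).
- **Y-linked genes**: female values come from a background-intensity
  Gaussian (default mean 5.0, SD 0.5 on the log2 scale), independent of
  age and smoking; the male linear model sits `sex_log2fc` above that
  background. Fold changes like 49× are background contrasts, not true
  expression ratios.
- **Detection p-values** are U(0, 0.01) for detectable sample–probe pairs
  and U(0.01, 1) otherwise, so the detection rate equals the gene's
  `expressed_fraction` exactly in expectation.
- **Extra probes** of a gene share its effects but carry independent noise
  and their own (degraded) expressed fraction, so the collapse rule has
  real work to do.
- **Residual SDs.** Planted catalogue genes default to σ = 0.15: the
  published catalogue pairs small effects (down to 1.08-fold, 0.003
  log2/year) with FDRs that survive genome-wide correction at n = 284,
  which is only consistent with well-detected, low-noise genes.
  Background genes draw σ uniformly from [0.1, 0.4]. Single-gene recovery
  demonstrations use σ = 0.5 (sex) and σ = 0.3 (age) — deliberately
  noisier than the default so the recovery claim is not trivially easy.
- **Background baselines** reach down to the background intensity itself
  (uniform from one log2 unit below background mean up to 11). Filtered
  arrays retain transcripts barely above background in most samples;
  without that low tail the Y-gene female draws would be rank outliers
  that quantile normalization visibly distorts.
- One global seed drives everything; multi-cohort generation spawns one
  child stream per cohort deterministically.

What the generator does **not** model: gene–gene correlation, platform
chemistry or bead-level structure, non-Gaussian heavy tails, batch effects
correlated with biology, and age-by-sex interactions. Passing tests
therefore show that the pipeline's logic and calibration are correct under
independence and additivity — not that real cohorts would yield these exact
counts. In particular, genome-wide counts on real data reflect correlated
genes (BH remains valid but the null count distribution is wider), and the
sex/age leakage visible in the simulated discovery scan (sex-effect genes
occasionally reaching significance in the age arm) arises from in-sample
sex–age correlation, exactly as it would in a real unbalanced cohort.

## Problem sizes used by the test suite and acceptance script

The shipped analyses run at reduced but non-trivial scale, chosen as the
smallest sizes at which the studied phenomena are cleanly visible:
permutation-null calibration at the full 11,089-gene, 284-sample design
with 1,000 cycles; four-cohort common-set recovery over 20 replicates at
~1,500 genes; effect-size recovery averaged over five replicate
discovery-scale cohorts of ~800 genes (the average reports the estimator's
recovery at ~2% Monte-Carlo precision rather than a single draw at ~4.5%).

## Known limitations

- Quantile normalization is a stand-in; results on real bead-array data
  normalized with spline methods will differ in detail.
- The non-parametric ComBat variant and RMA summarization of validation
  platforms are out of scope — validation cohorts are expected to arrive
  as already-summarized gene matrices.
- The permutation machinery calibrates counts only; it does not produce
  per-gene permutation-adjusted p-values.
- Meta-analytic pooling across cohorts is intentionally absent: the
  validation criterion is intersection, which is stricter and favors
  reproducibility over power.
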