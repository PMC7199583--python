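# Methods

## Model and procedure

The pipeline tests literature-derived regulatory pathways against
multi-cohort case/control expression data in five stages.

**1. Relation classification.** Input relations are directed edges
regulator → target with a polarity (positive/negative) and the target's
direction in disease (up/down, or promoter/inhibitor for disease-driver
annotations, which share the same algebra: promoter ≙ up, inhibitor ≙
down). Only polarity-bearing relations are admitted. Classification is a
pure function of (polarity, direction): negative×up → suppressed disease
promoter, positive×down → activated disease inhibitor, matched signs →
concordant (excluded from the contradirectional sets), unknown direction →
excluded with a log message. When one (regulator, target) pair carries
conflicting polarities, the polarity with more supporting references wins;
a tie excludes the target — reference weight is the only available
arbiter.

**2. Per-study effects.** The effect size is the log2 fold-change of
group means; its standard error is the unpooled Welch form with unbiased
per-group variances. The Welch form was chosen over a pooled variance
because the emulated design contains cohorts with extreme group imbalance
(4 controls vs 443 cases), where pooling would let the large arm dominate
the variance estimate. Groups of size one contribute zero variance and
the estimate is flagged. Zero standard errors (flat genes) are floored at
one tenth of the gene's smallest positive standard error before weighting
so inverse-variance weights stay finite; if every study is flat, unit
standard errors are substituted and pooling degrades to a plain mean.

**3. Pooling and model selection.** Fixed effects: weights 1/se²;
pooled estimate, SE = 1/√Σw, two-sided z test. The z (normal) rather
than t reference is the standard choice for inverse-variance pooling with
moderate k. Heterogeneity: Cochran's Q against the fixed pooled value,
df = k − 1, ISq = 100·(Q − df)/Q clamped to 0 when Q ≤ df, and Q-p the
chi-square(df) upper tail. Model selection follows the ISq clamp alone —
fixed when ISq = 0, otherwise DerSimonian–Laird random effects (moment
estimator, truncated at 0; no iteration, no Hartung–Knapp adjustment).
Q-p is reported but never gates. The output field name `ISq` follows the
upstream worksheet convention although the formula is the conventional
between-study I²; a single-study gene is pooled "fixed" with
heterogeneity left undefined. Raw p-values are the primary output across
genes; a BH column is emitted as extra information, clearly labelled.

**4. Covariate meta-regression.** Per gene, OLS of study LFCs on total
sample size (cases + controls; a cases-only mode exists), study age in
years, and country one-hot-encoded against the most frequent level.
Numeric factors report coefficient t-test p-values; country reports one
partial-F p-value. The regression is unweighted by default (an
inverse-variance WLS variant is behind a flag) because the per-study LFC
is the quantity of scientific interest, not its precision-weighted
version; aliased columns are dropped with a warning, and a single-country
design drops the country factor rather than failing.

**5. Enrichment and network.** One-sided Fisher's exact (hypergeometric
upper tail) per gene set, BH-FDR q-values with a pass/fail flag at
q = 0.05, and Jaccard similarity. The enrichment background defaults to
the collection's declared universe, else the union of its sets — the only
self-consistent choice when no curated background ships with the
collection. Set and query sizes are counted inside the background for
p-values and pipeline Jaccards; published tables that print raw set sizes
are reproduced by calling `jaccard` on the printed counts directly.
Pathway membership of the query genes over the surviving sets
(default p < 1e-6) defines the network: an edge wherever two genes share
at least one pathway, weighted by the shared count. Node summaries give
the pathway count, degree, and mean ± SD of incident edge weights; the SD
uses the n − 1 denominator ("±" read as a sample SD; a population-SD
variant is behind a flag), with fewer than two incident edges reported as
SD 0 and flagged.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of 13 public lung-adenocarcinoma
microarray cohorts: per-arm sample sizes 4–443, country and study-age
covariates, log2-scale intensities. Values are Gaussian on the log2 scale
(baseline 8, per-sample noise SD 1 — typical microarray magnitudes), with
the true study effect δ_gs ~ Normal(true LFC + linear covariate terms,
τ²). It does **not** model probe-level structure, batch effects,
normalisation artefacts, gene–gene correlation, or heavy-tailed noise;
passing recovery tests therefore demonstrates correctness of the
estimators under the declared sampling model, not robustness to real
microarray pathologies. Covariate effects enter the true study effect
linearly, so the meta-regression is correctly specified under the
generator; mis-specified variants are left to users.

The default pipeline bundle plants: the regulator at LFC −0.48 (down in
disease); the five disease-up and four disease-down common targets that
the source literature reports as expression-confirmed at ±0.6/−0.5; two
confirmed disease promoters at +0.6; all other literature targets null.
The gene-set bundle contains 115 sets against an 8000-gene universe: the
published top-10 geometry (sizes 215–803, overlaps 12–17 with the 26-gene
query, overlap members drawn round-robin from a 24-gene coverage pool so
exactly 24 of 26 query genes appear in the top 10), plus 105 synthetic
sets cycling (size, overlap) pairs (300,10)…(700,13) chosen so that every
set clears p < 1e-6 against that universe while never outranking the
planted top 10. Relation fixtures carry 13 + 6 contradirectional common
targets and 7 + 3 promoter/inhibitor relations overlapping in 4 genes,
for 25 driven molecules plus the regulator.

## Numerical choices and degenerate inputs

- p-values are clamped into (0, 1] at the smallest positive float.
- Enrichment ties are broken by set name for deterministic ranking.
- Matrix round-trips use `%.17g` so write→read is bit-for-bit.
- Empty relation tables propagate to empty downstream artifacts with exit
  code 0; any stage failure writes a `FAILED` marker naming the stage.
- All simulations are driven by `numpy.random.default_rng(seed)`; a fixed
  seed makes every artifact byte-identical across runs.

## Problem sizes used in the test and acceptance suites

Recovery experiments use the 13-cohort design with a single planted gene
and 500 replicates (pooled-estimate bias, power, model-selection rate);
meta-regression calibration uses 1000 pure-noise replicates; heterogeneity
calibration uses 300 replicates of 13 equal 80-per-arm cohorts; the
exhaustive Fisher check enumerates every configuration up to a 12-gene
universe. These sizes give Monte-Carlo standard errors well inside the
asserted bands.

## Known limitations

- Under homogeneity (τ² = 0), Q computed with *estimated* variances
  exceeds its nominal chi-square(k−1) behaviour when some arms are very
  small; with the emulated design the ISq = 0 rule selects the fixed
  model in only ≈ 43–46% of replicates (the chi-square ideal is 55%).
  The selection rule is implemented exactly as specified; users should
  not read the fixed/random label as a calibrated homogeneity test.
- No moderated (limma-style) variance shrinkage; genes with tiny arms get
  noisy weights.
- Gene identifiers are matched case-sensitively after whitespace
  trimming; alias resolution is out of scope.
- Published enrichment p-values depend on the (unknown) curated
  background of the source database and are not reproducible from printed
  counts alone; only the Jaccard arithmetic is.
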