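# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Corpus statistics

A prescription is a set of (herb, dose) pairs with a stage label
(compensated / decompensated). For a stage corpus of `n` prescriptions with
`T` total herb occurrences, a herb used in `f` prescriptions has

* rate = 100·f/n (percent of prescriptions containing the herb),
* proportion = 100·f/T (percent of all herb occurrences).

Dose statistics (min/max/mean/sd, grams) are computed over prescriptions
where the herb carries a recorded dose; missing doses are excluded rather
than imputed, since published dose summaries describe observed dosages only.
`exceeds_recommended` compares the mean dose with the upper bound of the
pharmacopoeia-recommended range.

Property/flavor/meridian frequencies are **occurrence-weighted**: a herb
contributes its prescription frequency once per attribute level it carries.
This is the only counting rule consistent with published axis totals that
exceed the number of herbs (e.g. 1,987 meridian occurrences from 34 herbs).
Percents are reported both exact and rounded half-up to two decimals, the
print convention of the source tables; note that published flavor percents
for the compensated stage are internally inconsistent with their own axis
total (451/1251 = 36.05%, printed as 37.87%), so only exact ratios are ever
computed here.

## Ordination

Profiles default to binary presence/absence — the corpora record herb
composition, not abundance — with a dose-weighted mode behind a flag.
Bray-Curtis dissimilarity (scipy) reduces on binary data to one minus the
Sørensen similarity. PCoA is classical scaling: Gower double-centering of
−½d², symmetric eigendecomposition, coordinates scaled by √eigenvalue.
Negative eigenvalues (expected for non-Euclidean dissimilarities) are
reported in the spectrum but excluded from both the coordinates and the
variance-explained denominator; no Cailliez/Lingoes correction is applied
by default because such corrections change the variance-explained
percentages. On Euclidean input the embedding reproduces the distances
exactly (tested to 1e-9).

PERMANOVA partitions squared dissimilarities (SS_total = Σd²/n, SS_within
summed per group) and reports pseudo-F = (SS_b/(g−1))/(SS_w/(n−g)); on
univariate Euclidean data this equals the classical ANOVA F exactly. The
p-value uses seeded label permutations with the +1 correction,
p = (1+#{F* ≥ F})/(1+N), default N = 999, so p ≥ 1/(N+1).

PLS-DA regresses column-centered profiles on a ±1 class vector via NIPALS
(scikit-learn). Per-component "percent variation" is the share of total
predictor (X) variance removed by each deflation step, ‖t_a p_aᵀ‖²/‖X_c‖²;
over a full-rank decomposition these sum to 100%. Whether published PLS-DA
percentages refer to X- or Y-variance is generally ambiguous, so only the
X-variance definition is computed and it is not asserted against any
external figure.

## Association rules

Level-wise Apriori with the downward-closure prune; the implementation is
tested for exact equivalence with brute-force enumeration (all itemsets up
to size 4) across 100 random corpora. Consequents are restricted to single
herbs, matching the convention of standard rule-mining tools and of every
published rule in this setting. Support is defined on the full antecedent ∪
consequent itemset; lift = confidence / support(consequent). Items below
the frequency floor (default: herbs used in ≤10 prescriptions) are removed
from transactions **before** mining; this matters because supports are
fractions of all transactions, and applying the floor only to display would
change nothing — the choice is switchable. Ties in "highest
support/confidence/lift" are reported as the full tied set.

## Target overlap and enrichment

Gene symbols are uppercased and whitespace-stripped on ingestion; alias
resolution is out of scope (an alias map may be pre-applied). ADME
screening keeps ingredients with OB ≥ 30% and DL ≥ 0.18, boundaries
inclusive. The three-way intersection report returns all seven exclusive
regions (UpSet semantics); inclusion-exclusion over the regions is tested
to hold exactly. Hub ranking counts incident edges at or above the score
cutoff (default 0.4, the usual interaction-database confidence threshold)
with lexicographic tie-break. Pathway over-representation is the upper-tail
hypergeometric probability, verified against exhaustive enumeration on a
20-gene universe; the universe defaults to the union of pathway members
because no external universe is canonical here. Benjamini-Hochberg
adjustment is applied across tested pathways; raw and adjusted values are
both emitted. Being discrete, the p-values are super-uniform (conservative)
under the null rather than exactly uniform.

## Mendelian randomization

Instrument selection: p < 1e-5 (the customary microbiome-GWAS threshold, as
genome-wide significant taxa loci are scarce), then greedy clumping by
ascending p — a SNP is dropped if within 500 kb of an already-retained SNP
on the same chromosome with r² > 0.1; pairs absent from the LD lookup are
treated as independent (LD is an input; no reference-panel computation).
Instrument strength uses the squared-z approximation F = (β/se)², since
per-SNP R² and exact per-SNP sample sizes are not always published; SNPs
with F ≤ 10 are removed. Confounder screening is a join against a supplied
SNP→trait table with an exclusion list.

Harmonization branches: exact allele match kept; exact swap flips the
outcome beta and frequency; palindromic SNPs (A/T, C/G) are resolved by
effect-allele frequency when both frequencies lie outside (0.42, 0.58) —
the conventional ambiguity band — and dropped otherwise; all other allele
configurations (including strand-complement pairs) are dropped with the
action recorded. Dropping rather than strand-flipping complement pairs is
deliberately conservative.

Estimators (per-SNP Wald ratio θ_j = β_out/β_exp with first-order standard
error se_out/|β_exp|; second-order terms omitted by default):

* **IVW**: weighted regression of β_out on β_exp through the origin,
  weights 1/se_out². Random-effects (default) inflates the fixed-effect
  standard error by √max(1, Q/(n−1)) — multiplicative model, never
  deflating. One SNP reduces exactly to the Wald ratio.
* **MR-Egger**: same regression with an intercept after orienting every SNP
  to β_exp ≥ 0; the intercept estimates directional pleiotropy. Inference
  uses t with n−2 df and the same floored multiplicative overdispersion.
* **Weighted median**: ordered Wald ratios interpolated at standardized
  cumulative weight 0.5; parametric-bootstrap standard error (default
  1,000 seeded draws). Consistent while valid instruments carry >50% of
  the weight.
* **Simple / weighted mode**: argmax of a Gaussian kernel density over the
  ratios (unweighted / inverse-variance weights), bandwidth 0.9·min(sd,
  MAD·1.4826)·n^(−1/5) times a user factor; zero spread returns the common
  ratio with zero se; bootstrap se otherwise.

IVW p-values use normal quantiles by default (t optional). Cochran's Q uses
first-order ratio weights (β_exp/se_out)² around the fixed-effect estimate,
referred to χ²(n−1). MR-PRESSO simulates the no-pleiotropy null from
leave-one-out fitted values (seeded, default 1,000 draws): the global test
compares the observed weighted leave-one-out residual sum of squares to its
simulated null; the per-SNP outlier test is Bonferroni-corrected; the
distortion test refers the estimate shift after outlier removal to shifts
from removing random subsets of the same size. Steiger converts per-SNP
F to r² = F/(F+n−2), sums over instruments per side, and z-tests the
Fisher-transformed aggregate correlations.

### Calibration behavior worth knowing

First-order weighting ignores exposure-side sampling error. Consequences,
all reproduced by the test suite: (1) IVW 95% CI coverage sits at the low
edge (~93%) rather than 95% when the causal effect is nonzero — the
recovery criterion's [93%, 97%] band reflects this; (2) Cochran's Q follows
its χ² reference only at the causal null (at θ ≠ 0 the ratio variance
gains a θ²·se_exp² term the weights ignore, inflating Q — which the
random-effects model then absorbs); (3) the Egger intercept test is
calibrated at the complete null but mildly anticonservative (~0.07 at
nominal 0.05) when a nonzero causal effect meets noisy exposure betas, the
known regression-dilution (NOME) leakage — its type-I criterion is
therefore evaluated at the causal null with balanced pleiotropy, pleiotropy
sd 0.005 (the order of the outcome-side sampling error at the simulated
cirrhosis-GWAS sample size, the regime the weighted-regression null
assumes).

## Synthetic-data generator

One root seed; each generator derives an independent child stream by stable
hashing of its name (CRC-32 into a seed sequence), so adding a generator
never perturbs the others. Everything is reproducible byte-for-byte.

* **Corpora**: two stages sized like the mined corpora (98 compensated /
  241 decompensated by default in the pipeline config); planted herb
  blocks included jointly with per-stage probabilities (their expected
  itemset supports); background herbs drawn only from outside all blocks so
  planted supports are uncontaminated; doses from normals truncated at a
  per-herb lower bound (published dose summaries are mean ± sd of positive
  doses).
* **GWAS tables**: maf ~ U(0.05, 0.5); per-allele standard errors
  1/√(2·maf·(1−maf)·n) at n = 18,340 (exposure) and 377,277 (outcome),
  the sample sizes of the microbiome and cirrhosis source GWAS; true
  exposure effects N(0.15, 0.05²), which puts per-SNP instrument F in the
  strong-instrument range; outcome effects θ·β_exp + α with α = 0 for valid
  instruments and α ~ N(pleiotropy_mean, pleiotropy_sd²) for the invalid
  fraction; observed betas add sampling noise scaled by `noise_scale`
  (0 gives the exact noise-free limit used by construction tests). A
  configurable fraction of outcome rows has alleles swapped (default 0.2)
  and a fraction of SNPs is palindromic (default 0.1) so every
  harmonization branch is exercised. LD blocks place members 10 kb apart
  with the block r² between every pair; other SNPs sit ≥1 Mb apart.
* **Target sets**: exact exclusive-region cardinalities over three labeled
  sets (default pipeline run plants an 85-gene three-way core, the size of
  the published cross-target set); the planted hub is wired to every other
  core gene at score 0.9 with a 0.5-score chain and sub-cutoff 0.2 edges
  elsewhere, making its degree strictly maximal at the 0.4 cutoff.

What the generator does **not** emulate: real LD structure (block-constant
r² only), minor-allele-frequency/effect-size coupling, sample overlap
between the two GWAS, winner's curse in instrument selection, herb-name
synonymy/misspelling, and dose-composition correlation. Passing tests
therefore demonstrate correctness of the estimators and pipelines under
their stated models, not robustness to those real-data pathologies.

## Problem sizes

Defaults are desk-scale by design: 999 permutations (PERMANOVA), 1,000
bootstrap/simulation draws (median/mode/PRESSO), 1,000 replicates for
estimator-recovery and type-I studies, 200 replicates for power/direction
studies, rule-mining oracle checks on ≤12-herb corpora. These sizes give
Monte-Carlo error well inside the asserted bands.

## Known limitations

* No multivariable MR, CAUSE or contamination-mixture estimators; no
  individual-level data; LD is an input, never computed.
* Apriori only (no FP-Growth); consequents of size one.
* Attribute vocabulary is the fixed five-property / seven-flavor /
  twelve-meridian scheme; herbs outside it need pre-mapping.
* The published corpus-analysis extremes that depend on the full mined
  prescription supplement (rule-support/lift extrema, the corpus PERMANOVA
  F) are not bundled; the engines are instead validated by oracle
  equivalence and planted-truth simulation.
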