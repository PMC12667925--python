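# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic cohort does and does not emulate,
and the design decisions taken where the methodology left room.

## TMT normalization chain

The chain runs in a fixed order: missingness filter → KNN imputation →
sample-loading (SL) → internal reference scaling (IRS) → TMM. SL, IRS and
TMM are scale transforms applied to raw reporter intensities; the filter,
imputation and all downstream statistics operate on log2 values, with
conversions made explicit through the matrix's `scale_tag`.

* **Missingness filter** — a feature is kept when observed in ≥ 30% of
  samples (`min_valid_frac = 0.30`); the boundary case (exactly 30%) is
  kept, mirroring a "less than 30% → drop" rule.
* **KNN imputation** — `k = 10` by default. The distance between two
  features is the root-mean-square difference over their jointly observed
  samples; RMS (rather than a raw sum of squares) keeps feature pairs with
  different overlap counts comparable. A missing cell becomes the
  unweighted mean of the k nearest features observed at that sample; a
  feature-mean fallback covers the no-candidate corner. Observed cells are
  never altered. k, the metric and the impute-after-log placement are
  package conventions — reasonable defaults, not field constants.
* **SL** — every channel is rescaled to the grand-mean column total,
  removing loading differences.
* **IRS** — per feature, each plex's values are multiplied by `g / r_p`
  (`r_p` = plex reference mean, `g` = geometric mean of all `r_p`). After
  correction the reference means agree exactly across plexes. When a
  feature has no observed reference in some plex, that plex's values
  become missing rather than guessed (conservative; they are re-imputed
  before TMM). Note the factor inherits the reference channel's
  measurement noise: with a single pooled-reference channel per plex the
  residual between-plex dispersion after IRS equals the technical noise of
  one channel, which is why IRS works well only when technical noise is
  small relative to biological signal.
* **TMM** — reference column = the one with total closest to the mean
  (overridable); trim fractions 0.30 (M) and 0.05 (A) per tail; the factor
  is `2^mean(M)` over survivors, unweighted, since the count-based
  precision weights of the RNA-seq formulation have no analogue for
  intensities. Factors are rescaled to geometric mean 1. TMM is idempotent
  when the reference column is held fixed; re-selecting the reference
  after scaling can move factors by a few percent.
* **Differential abundance** — Welch's t per feature with BH correction.
  A count-model test (edgeR-style negative binomial) is not applicable to
  TMT log-intensities, so the package uses Welch + BH throughout; the
  downstream consumers only need a ranking and a threshold. Degenerate
  zero-variance features get p = 1 (no shift) or p = 0 (exact shift).

## Consensus-NMF subtyping

Input: protein and phosphosite matrices (normalized, log2, complete) are
row-concatenated; the top 500 rows by **mean absolute deviation**
(mean |x − mean|, per the stated metric) are median-centred per row and
split into positive/negative parts, giving a non-negative matrix with
doubled row count whose difference reconstructs the centred data exactly.

Factorization is multiplicative-update NMF on the Frobenius objective,
with the per-iteration error trace recorded (the updates are monotone).
`nmf_factorize` defaults to `max_iter = 2000, tol = 1e-6`. Consensus
restarts use capped inner updates (`max_iter = 100, tol = 1e-4`): the
argmax-of-H partition stabilises long before the objective converges, and
the cap keeps a 200-restart × 4-rank survey over five seeds inside tens of
seconds. Consensus[i,j] = fraction of restarts co-clustering i and j;
final labels cut an average-linkage tree of (1 − consensus); cophenetic =
Pearson correlation between (1 − consensus) distances and the tree's
cophenetic distances; silhouette uses (1 − consensus) as dissimilarity.

Rank choice: the default rule takes the largest k whose cophenetic is
within 0.05 of the survey maximum and whose smallest class has ≥ 5
samples; `k_override` reproduces a fixed choice (the cohort analyses here
fix k = 3). Labels are renamed P1, P2, … by decreasing class size and are
nominal.

A structural note on the rank survey: when the planted subtypes are
strongly separated (the regime in which recovery ARI ≈ 1), between-subtype
consensus entries are essentially exactly 0 at every surveyed rank, and
the cophenetic correlation of a 3-block consensus with any amount of
within-block fuzz stays above ≈ 0.98. Over-specified ranks therefore show
only a small cophenetic decline (~0.01–0.03) on such data, however
unstable the extra component is; large drops at k > k_true are a signature
of marginally separated real cohorts, not of cleanly separable ones. The
recovery benchmark reports the drop it actually measures.

## Allele-specific instability scoring

Segments are integer (total, major, minor) copy-number intervals, 0-based
half-open internally (SEG files on disk are 1-based inclusive). Adjacent
equal-state segments are merged before scoring, so all scores are
invariant to subdivision and input order; a coverage gap breaks runs. Sex
chromosomes are excluded from every score; the WGD fraction denominator is
the full autosomal genome length, ploidy weights are covered lengths, and
coverage below 50% triggers a warning.

* CIN counts a segment in every category it satisfies (a total = 1,
  minor = 0 segment is both a loss and an LOH segment); an exclusive mode
  (gain > loss > LOH precedence) is available.
* HRD-LOH: maximal LOH runs (minor = 0, total ≥ 1) strictly longer than
  15 Mb, excluding runs spanning an entire chromosome (exactly [0, length)).
* LST: per chromosome arm; segments shorter than 3 Mb are removed and
  same-state flanks re-merged; a junction counts when both flanks are
  ≥ 10 Mb and ≤ 3 Mb apart. "State" is the (major, minor) pair, so
  copy-neutral LOH boundaries are transitions.
* TAI: allelic-imbalance runs (major ≠ minor) touching either telomere,
  not crossing the centromere (a run ending exactly at a centromere edge
  counts), not spanning the whole chromosome; no minimum length by default
  (configurable).
* HRD = HRD-LOH + LST + TAI, asserted as an invariant.

Segments are taken as already purity/ploidy-resolved; estimating those
from raw coverage is out of scope. A GRCh37-like genome table (rounded
centromeres) ships with the package and is configurable.

## Enrichment and kinase activity

ssGSEA ranks each sample's features by (log2) abundance and accumulates a
running statistic with in-set increments ∝ |value|^0.75 and uniform
out-of-set decrements; the score is the signed sum of the running values
over all ranks (the area under the running-enrichment curve). Sets
overlapping the matrix by < 3 features are omitted. Per-set scores are
z-scored across samples ("NES"); permutation p-values are deliberately
not computed for ssGSEA (the scores are consumed directly), while
preranked GSEA reports feature-permutation p-values and sign-matched NES.
ORA is the upper-tail hypergeometric against an explicit universe with BH
correction.

Kinase activity is the substrate-set z-score
`z = (mean substrate FC − mean all FC)·√m / SD(all FC)` over kinases with
≥ 3 annotated sites present, with a two-sided normal p and BH q. This is a
transparent substitute for network-propagated kinase-activity inference
tools whose internals are not reproducible from their descriptions; the
substrate aggregation function is exposed for extension. Multi-site
phosphopeptides are expanded to one row per site beforehand; redundant
site measurements are averaged.

## Cross-omic association and transfer

Cis/trans mapping uses Spearman correlation; BH families are declared
explicitly: one family for all cis tests per level (mRNA, protein), one
per CNA gene for trans tests. The classifier stage selects features by
one-vs-rest Welch contrasts at FDR < 0.01 and linear |fold change| > 2,
then trains a random forest (pluggable) on a stratified 70% split with
stratified k-fold cross-validation, reporting held-out per-class and
macro F1. Survival uses Kaplan–Meier estimates and the multivariate
log-rank test.

## The synthetic cohort

The generator's defaults describe a 72-sample, 3-subtype cohort measured
in 16-channel TMT plexes with one pooled-reference channel each.

Signal structure, per sample: log2 abundance = feature baseline
(N(18, 1.5²) proteins, N(16, 1.5²) phosphosites) + subtype signature
(50 features per subtype per matrix, +1.0 log2) + latent shared programs
(8 programs, sparse loadings on 25% of features at 0.30 log2 amplitude,
continuous activities partially aligned with subtype, mean offsets of
SD 0.5) + binary crosscutting states (3 states, 40 features each,
+0.4 log2 in a random 30% of samples) + kinase-driven shifts (20 kinases,
8 substrate sites each, +1.0 log2 in the kinase's active subtype) +
biological between-sample variation (SD 0.35). 15% of samples are
"intermediate": their signature is a convex mix (weight 0.6–0.85) of two
subtypes, with the dominant side as true label. Pooled references are the
arithmetic plex mean of the raw intensities *including* biological
variation (the pool is made from the samples) but *before* batch factors
(per plex per feature, SD 0.4 log2, multiplicative) and technical noise
(per channel, SD 0.15 log2) — exactly the structure IRS assumes.
Missingness (30% by default) is either uniform or a logistic dropout on
log2 abundance calibrated to the target rate, emulating detection limits.
mRNA is complete and log2; cis genes (100) move mRNA by 0.5 log2 per copy
and protein by 70% of that. Survival is exponential with per-subtype
hazards (0.10, 0.50, 0.25 per time unit; the second subtype is the
aggressive one) and administrative censoring at t = 10.

Segment profiles are built deterministically to hit requested scar
targets: each element sits inside one arm with ≥ 4 Mb uncovered guard gaps
so elements never interact through the LST gap rule — HRD-LOH elements are
20 Mb copy-neutral (2,2,0) interiors, LST elements are contiguous
(2,1,1)+(3,2,1) 12 Mb pairs, TAI elements are 20 Mb telomeric (3,2,1)
segments, extra gains (5,3,2) and losses (0,0,0) are 8 Mb interiors; the
rest of the genome is diploid filler, or (4,2,2) filler in
whole-genome-doubled samples (each maximal tetraploid run counts as one
gain, tracked by the truth accounting). Consequences: `n_gain ≥ n_lst +
n_tai` is required, and `n_loh_segments = n_hrd_loh`. A stochastic mode
Poisson-jitters the element counts.

What the generator does **not** emulate: peptide-level structure and
rollup, ratio compression, realistic mutational processes or signature
spectra, segment-caller noise (breakpoint jitter, subclonality), and
correlated missingness between protein and phosphosite layers. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct for its stated data model, not that the model captures every
property of real LC-MS cohorts.

## Benchmark problem sizes

The recovery and calibration benchmarks run on scaled-down feature spaces
(700 proteins, 600 phosphosites, 700 transcripts; the clustering input is
the top-500 MAD rows either way), n = 60 samples, 200 consensus restarts
over k = 2–5, and medians over 5 seeds; the instability oracle check uses
1,000 random genomes. These sizes make the full benchmark suite a
ten-minute-scale, single-CPU computation while leaving every statistical
conclusion unchanged.

## Known limitations

* IRS with a single reference channel per plex cannot distinguish batch
  effect from the reference's own technical noise; cohorts with noisy
  references should pool replicate reference channels.
* The consensus cophenetic coefficient saturates on strongly separated
  cohorts (see above), so rank selection on clean data leans on the
  minimum-class-size rule or an explicit `k_override`.
* The kinase z-score ignores site direction annotations and shared
  substrates between kinases; it ranks kinases, it does not deconvolve
  them.
* Fold-change-based transfer features assume the external cohort is on a
  comparable log scale; no cross-platform calibration is performed.
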