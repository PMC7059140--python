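# Methods

This note records the model assumptions, the numerical choices made where
the design was genuinely open, what the synthetic generators do and do not
emulate, and the problem sizes the test suite runs at.

## Profile statistics

Perturbed and control cell populations are compared per feature with two
distribution-distance statistics. The rank-sum statistic pools both samples,
midranks ties, and computes `U = R − n1(n1+1)/2` from the perturbed sample's
rank sum `R`; the KS distance is the maximum ECDF gap `D`. Both are
multiplied by the scaling factor `sf = n1·n2/(n1+n2)` so that wells with
more cells carry proportionally stronger distance readouts. Note that the
classical variance-stabilised KS scaling uses `sqrt(n1·n2/(n1+n2))`; this
package applies the linear factor by default and exposes
`sf_mode="sqrt"` on both functions rather than guessing an intent — the two
modes differ only by a monotone per-well rescaling.

Shape statistics use the sample skewness `g1` and excess kurtosis `g2`;
bimodality is Sarle's sample coefficient
`b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))`, ≈ 1/3 for a normal sample,
5/9 for a uniform, larger for separated mixtures. Degenerate statistics
(zero variance, n < 4) are encoded as missing, never silently zeroed, so the
cleaning/imputation stage handles them explicitly. The default quantile set
is {1, 5, 25, 50, 75, 95, 99}% with linear interpolation.

## Preprocessing

Cleaning drops rows, then columns, exceeding 30% missingness (one pass
each; dropping rows first means a feature is judged on the retained
samples). Imputation replaces each missing cell by the inverse-distance
weighted mean of the 10 nearest *feature columns*, with distances computed
as root-mean-square differences over rows where both features are observed
(per-pair normalisation keeps distances comparable when overlaps differ; a
1e-12 guard avoids division by zero; columns with no overlap fall back to
the column mean). Plate z-scoring maps every feature to mean 0 / SD 1 within
its plate; zero-variance features become 0.

The total cell number (TCN) confound is removed by sorting rows by TCN,
splitting them into 32 equal-frequency bins, merging any bin under 100 rows
into its right neighbour (the last bin merges left), and z-scoring each
feature within each bin. Within-bin means/SDs are exact to floating
precision, so any feature that is a monotone function of TCN is flattened;
the acceptance test constructs a feature equal to `2·TCN + noise` and checks
|r| > 0.9 before and < 0.1 after correction.

PCA reduction fixes component signs by forcing each component's
largest-magnitude loading positive, and z-scores the scores, making the
reduced matrix reproducible bit-for-bit.

## Annotation catalog

Annotations are propagated along explicit child→parent links (`is_a`, and
`part_of` unless disabled); the operation is idempotent and terms missing
from the graph pass through with a log message. Filtering keeps terms with
100–500 annotated genes, both bounds inclusive. Redundancy merging is greedy
agglomeration: the currently highest-Jaccard pair above 0.70 is merged
(union of gene sets, id of the larger set kept, ties to the
lexicographically smaller id) and overlaps recomputed until no pair exceeds
the threshold. Merged sets may exceed the size ceiling and are kept, with
`merged_from` recording provenance. Evidence-code filtering is off by
default.

## Training protocol

Per term: positives are shuffled and split 70/30 (ceil on the training
side); negatives are drawn uniformly without replacement from the universe
minus all the term's annotated genes, one per positive in each split, so
every fit is balanced. The per-term random stream is derived from the global
seed plus a CRC of the term id, making the whole pipeline a pure function of
(matrix, annotations, config, seed).

Features are ranked by two-sample KS p-value between training positives and
negatives (ties: larger statistic, then column order) and scanned once in
that order; a feature is kept when it improves the mean 30-fold
cross-validated F-score by more than 1e-4 (fold count clipped to the smaller
class size). The top-ranked feature is always retained and at most 100
features are kept, so the accepted-trace is non-decreasing by construction.

The kernel scale grid defaults to `2^k · d_med, k = −4..4` with `d_med` the
median pairwise training distance (the RBF is parameterised as
`gamma = 1/(2σ²)`). Because a joint search over σ and feature subsets is
quadratic, the pipeline does a coarse σ search on the top-20 KS-ranked
features, forward-selects at that σ, then re-searches σ on the selected set;
ties go to the smallest σ. The SVM regularisation constant C defaults to 1.0
and is exposed in the config.

Metrics are measured on the held-out 30%: FPR on the test negatives, test
recall on the test positives, training recall on the training positives,
AUROC over pooled test scores. A term is classifiable iff FPR < 0.20,
test recall > 0.30 and train recall > 0.40, all strict. Genome-wide
prediction uses the signed decision-function value; ranks order predicted
genes by decreasing score, and `zscored_rank` z-scores each gene's decision
scores across terms (per-gene axis) for cross-term comparison. Consensus
retraining refits on 10 CV partitions of the annotated genes with features
and σ frozen and keeps genes predicted in ≥ 7 refits.

## Baselines

The clustering baseline reduces profiles to the first 100 principal
components, clusters (k-means, or a hand-rolled deterministic 1-D batch SOM
chain so unit counts are comparable with k), and scores each gene for a term
by the annotated fraction of its cluster *excluding the gene itself*;
recall counts annotated genes co-clustered with another annotated gene and
AUROC ranks genes by the overlap score. Leave-self-out makes the score
honest (no self-fulfilling membership — including the gene itself inflates
null AUROC to ~70%) at the price of a small systematic −0.5/k offset under
the null, visible at k = 10 and negligible by k ≥ 50; the degenerate k = 1
map collapses to AUROC 0 under this convention. The correlation baseline
predicts a gene for a term when its Pearson correlation with any *other*
annotated gene of the term exceeds 0.9.

## Post-processing

Seeds are siRNA guide positions 2–7, normalised to the RNA alphabet. The
off-target filter tests, for each term and each seed carried by ≥ 4 genes,
the 2×2 table {predicted, not} × {carries seed, not} over the scored
universe with a right-tail Fisher test; at p < 0.01 (raw, uncorrected — by
design the filter is deliberately aggressive) all predictions of the seed's
carriers for that term are flagged, and flagged rows are retained unless
removal is requested. The term network joins prediction sets with Jaccard
overlap > 0.70 (overlap-coefficient switch available) and then attaches
every still-isolated term to its best partner, so no node is isolated.
First-neighbour enrichment excludes the annotated genes themselves from the
neighbour set and uses the upper-tail hypergeometric. The subphenotypic
embedding fits a logistic regression to reproduce the classifier's predicted
labels from its selected features and runs t-SNE on those columns scaled by
the absolute logistic weights (perplexity 30, clipped for small inputs;
fixed seed).

## Synthetic screens

`generate_screen` plants term signatures additively: background values are
Normal(0, noise_sd²) — optionally t₃ rescaled to the same variance, since
real screens are heavy-tailed — and each term's positives are shifted by
`effect_size` SD on its informative features. Missingness is completely at
random; TCN is lognormal (median 6,000 cells, log-SD 0.35, matching the
scale of arrayed image-based screens); confounded features are linear in
standardised TCN plus noise. The default fixture is 2,000 genes × 200
features with a 150-gene term, 10 informative features and a 1.0 SD shift.

What this does *not* emulate: correlated feature blocks, plate/batch
structure beyond an offset, annotation noise (false positives inside terms),
partial penetrance at the single-cell level and dose-dependent knockdown
efficiency. Passing tests therefore demonstrate correctness of the
machinery and recoverability of additive signatures, not performance on real
screens.

## Problem sizes and tolerances in the test suite

Oracle checks (rank-sum/KS vs enumeration, Fisher/hypergeometric vs
exhaustive tables with total ≤ 30) are exact to 1e-9 or better. The
parameter-recovery run uses the default fixture. The null-control run
trains the full pipeline on 100 random 200-gene sets over a 2,000 × 50
standard-normal matrix with a 3-point σ grid centred on the median
heuristic — sizes chosen so the whole suite completes on a single CPU in
well under half an hour while keeping 100 independent full trainings. The
clustering-null run uses 2,000 genes × 100 features, 20 random terms and
k ∈ {10, 50, 100, 150, 200}; its mean AUROC is asserted within ±2
percentage points of 50%. Per-bin z-score exactness is asserted at 1e-9.

## Known limitations

- The σ/feature-selection interleaving is a tractable approximation to a
  joint search; a full joint search would be quadratic in grid × features.
- Merging by greedy agglomeration is one defensible reading of
  threshold-based term merging; single-linkage components would merge more.
- The seed filter applies no multiple-testing correction (by design), so a
  few coincidentally enriched background seeds are flagged at α = 0.01.
- Forward selection is a single ordered pass; features rejected early are
  never revisited even if they would help in combination.
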