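# Methods

## Scope and model

`assocnet` computes one evidence channel of a functional-association
network — co-expression — end to end, plus the machinery to move scored
edges between organisms (hierarchical orthology with interolog transfer) and
to interpret gene sets (term enrichment). The underlying model of the
co-expression channel is that transcriptional co-regulation induces
correlated expression across diverse conditions, and that the degree of
correlation can be turned into a probability of functional association by
benchmarking against curated pathway co-membership.

## Inclusion filters

Samples need ≥ 100 distinct mappable genes with a non-missing value,
experiments ≥ 3 retained samples, organisms ≥ 50 retained experiments.
"Mappable genes" are counted as distinct gene IDs (not probes) per sample.
Filters apply in the order sample → experiment → organism, so a sample
removal can cascade into experiment and organism removal; this is the
conservative reading of thresholds that are defined independently. Every
exclusion is logged as `level<TAB>id<TAB>reason`.

## Normalization

Dual-channel arrays carry log-ratios already and are only z-normalized per
sample column (population SD; zero-variance columns become all-zero, fully
missing columns stay missing). Single-channel intensities are
log2-transformed (values ≤ 0 treated as missing), then each probe's mean
over the experiment's samples is subtracted, then columns are z-normalized.
The order matters: z-scores can be negative, so the log2 step must come
first, and the per-probe centering is what makes absolute intensities
comparable to two-channel fold-changes. The z-step is idempotent, which the
tests exploit.

Missing values are carried through with pairwise-complete handling
everywhere (no imputation). Correlations are only reported when at least
`min_overlap` (default 20) pairwise-complete observations exist; sparser
pairs are treated as undefined, and undefined array similarities count as
below any pruning threshold.

## Redundancy pruning

Public repositories contain many near-duplicate arrays (reprocessed
submissions, technical replicates), which would otherwise dominate gene-gene
correlations. Array redundancy is measured by Spearman rank correlation over
shared genes and pruned with Hobohm-2: repeatedly delete the array with the
highest number of neighbours above the threshold until no pair exceeds it.
Thresholds are 0.7 (single-channel) and 0.95 (dual-channel); the dual
threshold is stricter because log-ratio arrays are already less correlated
with each other. Similarity is signed — anti-correlated arrays are not
redundant. Degree ties are broken by deleting the lexicographically larger
array ID, making the output deterministic; the original formulation of the
algorithm leaves the tie-break open. Pruning operates on the pooled
per-organism, per-channel collection across all experiments.

## Calibration and combination

Gene pairs are labeled positive when both genes share an annotated pathway,
negative when both are annotated but share none, and excluded otherwise.
Pairs ranked by signed Pearson r (negative co-expression is not rewarded)
are scanned with a sliding window (default 500) whose positive fraction
estimates local precision; isotonic regression (pool-adjacent-violators, via
scikit-learn) enforces monotonicity, and scoring interpolates linearly
between knots with clamping outside the observed range. The window width
trades resolution against binomial noise: at 500, the per-window standard
error is ≤ ~0.022.

Channel scores combine by noisy-OR in prior-corrected space (see README for
the formula). The correction removes the baseline chance that a random
benchmarkable pair is positive, so that independent weak evidence does not
inflate; the prior defaults to the measured positive fraction (weighted
across channels) and can be overridden. Scores below the prior are floored
at the prior, so the combination is monotone and never returns less than any
input. The combination formula itself is a design choice of this package —
the composite-evidence literature uses several variants — and is exposed as
a standalone function.

ROC benchmarking groups tied scores into single steps and integrates by
trapezoid; the AUC equals the normalized Mann–Whitney U statistic, which the
tests verify against scipy independently.

## Orthology consistency and transfer

A hierarchy of per-clade groups is self-consistent when every group's
members, where assigned at an ancestor clade, fall inside a single ancestor
group; proteins unassigned at an ancestor constrain nothing. Two repair
strategies run to a fixpoint:

* `merge_up` (default): walk leaves-to-root, union-merging the ancestor
  groups bridged by any descendant group. Ancestor groups only grow; no
  grouping information is discarded, which is why it is the default.
* `split_down`: walk root-to-leaves, splitting each group by its members'
  ancestor groups. Descendant groups only shrink. Members unassigned at the
  ancestor stay with the sub-group of the lexicographically smallest
  ancestor group, so they never force a split on their own.

Both strategies terminate (group counts are monotone and bounded) and are
idempotent at the fixpoint; which consistent state is "best" is not defined
here, so the choice is exposed as a flag and the two extremes bracket the
group-count spectrum.

Transfer maps an edge (a, b, S) at the lowest clade covering source and
target species: every pair of target-species members of a's and b's groups
receives S·(n_a·n_b)^−γ, where n_a, n_b are the member counts. γ (default
0.5) is this package's paralogy penalty — a documented, configurable
surrogate for transfer weightings that are typically unpublished; γ = 0
conserves scores and any γ ≥ 0 never amplifies them. Multiple transfers onto
one target pair merge by plain noisy-OR; self-pairs are dropped; transferred
scores below 0.15 are discarded as uninformative.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) computed via
the log survival function (scipy) for numerical stability in deep tails, with
Benjamini–Hochberg FDR across all tested terms of a catalog. The background
defaults to the catalog's annotated universe rather than a whole proteome —
conservative and self-contained. The test statistic is a design choice; the
suite validates it against exact combinatorial enumeration and a permutation
oracle.

## Synthetic data

The expression generator is a latent-factor model: per sample, each module
draws an activity ~ N(0, 1); member genes load with weight 1 plus N(0,
noise_sd) gene noise; probes add independent N(0, noise_sd). Single-channel
experiments are emitted as 2^(signal + probe baseline), so the pipeline's
log2/centering path is exercised nontrivially; dual-channel experiments emit
the log-ratios directly. Near-duplicate arrays (copy + N(0,
duplicate_noise_sd)) exercise pruning, multi-probe genes exercise merging.
Default study conditions: 200 genes in 20 modules of 10 (all genes
annotated, so all pairs are benchmarkable), noise_sd 0.5, 60 experiments of
4 samples (~240 arrays before duplication), duplicate rate 0.1, up to 2
probes per gene, 50/50 channel mix. These sizes keep a full run in seconds
while leaving ≥ 100 retained arrays per channel — enough for stable
correlations at min_overlap 20.

What the generator does **not** emulate: dye bias, spatial artifacts,
platform batch effects, heavy-tailed intensity distributions, missingness
patterns of real GEO matrices, or overlapping/nested pathway annotation.
Passing the planted-truth benchmark therefore shows the pipeline recovers
co-regulation under idealized noise, not that it reaches any particular
accuracy on real compendia.

The orthology generator builds a balanced species tree (depth ≥ 2), families
with 1–3 paralogs per species, and nested groups constructed top-down (each
parent group's restriction to a child clade is randomly kept or split), so
the truth is consistent by construction; corruption reassigns a fraction of
non-root proteins to random wrong groups of the same clade.

## Numerical and degenerate-input choices

* Population (ddof = 0) standard deviation in z-scoring; zero-variance
  columns map to zeros rather than NaN.
* Similarity/correlation entries are undefined (NaN) below `min_overlap` or
  at zero variance, and undefined never counts as redundant.
* Calibration knots collapse duplicate raw scores by averaging and a final
  cumulative-max guards monotonicity against floating-point jitter.
* `combine_scores` accepts scores equal to 1 (returns 1) even though
  calibrated scores normally stay below 1.
* Hobohm-2 and the consistency repair break all ties lexicographically, so
  every pipeline output is deterministic; the only randomness in the package
  lives in the generators' seeds.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
the default study conditions above (19,900 scored pairs end to end; 200
random similarity matrices of ≤ 10 arrays for the pruning oracle; 10,000
pairs for calibration recovery; 100 corrupted hierarchies of 8 species / 3
families; 20 null enrichment replicates over 200 terms). A full run of both
completes in well under a minute on one CPU.

## Known limitations

* Calibration and ROC evaluation in the end-to-end pipeline use the same
  gold standard, as the original procedure does; the unit tests additionally
  check calibration recovery on held-out two-regime data, but the pipeline
  itself does not split.
* The transfer weighting and the score-combination constant are this
  package's own (documented) choices, not reverse-engineered values.
* RNA-seq counts, quantile/loess normalization and batch correction are out
  of scope; inputs are assumed to be plain TSV matrices, not SOFT/MINiML.
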