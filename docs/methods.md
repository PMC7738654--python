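# Methods

## Scope and data model

The package analyses probe-by-sample count matrices from digital
hybridization counting. Probes carry one of four classes: *Endogenous*
(the biological panel), *Housekeeping* (reference genes), *Negative*
(probes with no target, measuring nonspecific background) and *Positive*
(spike-ins; carried through but not used by any stage). Counts are raw
nonnegative integers; all QC decisions (background, screening, detection)
are made on the raw scale, and only differential expression and clustering
work on log2 normalized values. Probe identity is the (class, name) pair;
mismatched or permuted probe sets across lanes are hard errors rather than
silently reconciled.

## Background threshold

θ_s = mean + 2·SD of the sample's negative-control counts, with the
sample (n−1) standard deviation: the negative panel is small (8 probes by
default) and the unbiased estimator is the common choice at that size.
θ is permutation-invariant in the probes and scale-equivariant. An all-zero
negative panel yields θ = 0 with a warning; detection then treats any
nonzero count as infinite SNR rather than failing.

## Housekeeping screening, stability and panel choice

A reference gene close to background carries degradation noise, not
biology. "Close to background" is quantified as failing `count > k·θ_s` in
any sample, with k = 3 by default — the same cutoff the detection filter
uses, so a gene kept for normalization would also count as detected.
Failing genes are flagged, never dropped from the matrix.

Stability uses the geNorm measure: for gene j within a reference set,
M_j is the mean over partners k of the standard deviation across samples of
log2(x_j) − log2(x_k). Two conventions are fixed here: the SD uses ddof = 1,
and log2 is taken on raw counts with a pseudocount of 1 applied only when
zeros are present. An iterative-elimination ranking (drop the highest-M
gene, recompute, repeat down to two) is provided; the final two genes share
the top rank and are listed alphabetically.

The normalization panel itself is chosen by correlation, mirroring the
manual practice of picking a few high-signal, mutually consistent reference
genes: an exhaustive search over subsets of the passing genes maximizes the
minimum pairwise Pearson r of log2(count+1), subject to that minimum
reaching `min_r` (default 0.8); ties break by lower mean M, then
lexicographically. Both selection routes (geNorm ranking and correlation
panel) are exposed, and the pipeline config picks one per run.

## Normalization

g_s is the geometric mean of the panel genes' raw counts in sample s;
f_s = mean(g)/g_s; column s is multiplied by f_s. After scaling, all
samples share the panel geometric mean exactly (the fixed point asserted in
tests to 1e-9 relative). The arithmetic-mean reference only sets the overall
scale — any fixed reference yields identical test statistics downstream.
Downstream log2 values use log2(x + 1); the offset is a config knob.

## Detection

SNR_gs = raw count / θ_s, computed pre-normalization on both sides — the
threshold is defined on raw negative-control counts, so mixing scales would
be incoherent. A gene is detected when SNR > cutoff (strictly; default 3)
in at least `min_fraction` (default 0.5) of the samples of at least one
group; the `all_samples` scope is available instead. The group-wise default
keeps genes expressed in only one condition. Only endogenous probes are
filtered. The detected set is monotone nonincreasing in both the cutoff and
the fraction.

## Differential expression

Unpaired two-sample t-tests per detected gene on log2(normalized+1):
pooled-variance Student by default (df = n1+n2−2), Welch optional. Both
groups constant and equal gives (t, p) = (0, 1); constant and unequal gives
p = 0 with a zero-variance warning. Fold change derives from the log2 mean
difference Δ: linear ratio R = 2^Δ, reported in the signed convention
(R if R ≥ 1, else −1/R), so the DEG rule |signed FC| ≥ 1.5 corresponds to
|Δ| ≥ log2 1.5 ≈ 0.585. The FC boundary is inclusive and the p boundary
strict (p < 0.05). A ratio-of-linear-means mode is provided since both
conventions are in use for counting data; the two agree in sign and differ
only through Jensen's inequality. No multiple-testing correction is applied
by default — with 11 vs 4 samples the analysis deliberately favours
sensitivity — but `correction="bh"` appends Benjamini–Hochberg adjusted
p-values without changing the default calls.

## Enrichment

One-sided upper-tail hypergeometric over-representation:
p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n), with the universe N defaulting to the
detected genes — the background must be the set that could have been called
(full-panel universe available via config). k = 0 gives p = 1 exactly.
Up- and down-regulated lists are always analysed separately. The
co-annotation network links two query genes when they share at least `w`
gene sets (default 1), weighted by the co-occurrence count — a
pathway-style interaction sketch that needs no external database.
A small hand-written toy GMT ships with the package for tests; runs on
simulated data use a seeded synthetic collection built over the simulated
gene names, with a few sets deliberately enriched for the planted
differential genes.

## Clustering and reports

Heatmap input is log2 normalized data, z-scaled per gene (ddof = 1) so all
genes carry equal variance; constant rows are set to zero and flagged.
Samples and genes are clustered agglomeratively on Euclidean distance with
average linkage by default (complete and Ward available) via scipy's
implementation, whose merge order is deterministic; equal-distance ties
follow scipy's internal order. The sample tree cut at k = 2 is the
unsupervised partition compared against known labels with the adjusted Rand
index. Volcano coordinates are (Δ, −log10 p); p = 0 is capped at y = 320
and flagged. Dendrograms are exported as Newick with branch lengths.

## Synthetic data generator

Counts are negative binomial with mean
μ_gs = d_s·b_g·2^{lfc(g,s)} + β_s for endogenous and housekeeping probes
and μ = β_s for negatives, variance μ + φμ² (φ = 0 degenerates to Poisson).
Background is additive — a hybridization floor under the signal — which
keeps SNR well defined; degradation d_s is purely multiplicative per
sample, so housekeeping normalization removes it exactly in expectation,
making normalization correctness testable. One RNG stream per dataset,
keyed by the config seed; identical configs are bit-identical.

Defaults describe the study conditions the pipeline was built around: a
579-gene immunology codeset with 8 negative controls and 15 housekeeping
candidates, 11 cases vs 4 controls; 48/579 up- and 21/579 down-regulated
genes planted with linear fold changes cycling through 1.6–6.4 (the
magnitude range such panel studies report); dropout fraction 130/579 so the
expected detected count is ≈449; baselines log-normal (log2 mean 9, sd 1.2;
housekeeping 11 ± 0.8); background means uniform on 8–14; degradation
factors uniform on 0.1–1.0 (archival blocks span roughly an order of
magnitude in usable RNA); dispersion φ = 0.05. The degradation spread and
dispersion were set jointly so that emulated housekeeping genes correlate
pairwise at r ≈ 0.85–0.95 on log2 counts, the range reported for manually
selected reference panels on such material. Dropout genes draw baselines
below 2·SD(negatives)/d_s, capping their expected SNR at ≤ 1 in every
sample; planted differential genes are disjoint from dropout genes so
effects remain observable.

What the generator does *not* emulate: probe-level affinity differences,
fragment-length-dependent loss (degradation is a scalar per sample),
positive-control drift, lane artefacts, and correlated co-regulation among
genes. Passing recovery tests therefore demonstrates the pipeline's
correctness under its own model assumptions, not performance on real FFPE
data.

## Validation sizes and numerical choices

The validation suite runs at the study's own scale — 602 probes × 15
samples — since simulation there is cheap: 100 random geNorm instances
against a brute-force all-pairs oracle (1e-9); a 2000-gene global null at
11 vs 4 for the t-test's type-I error (±3 Monte-Carlo SD around 0.05);
10 seeds of planted |FC| = 2.5 for sensitivity (≥ 0.8) and median |Δ| error
(≤ 0.2); 20 low-dispersion seeds for degradation recovery (r > 0.99);
20 strong-effect seeds for clustering recovery (ARI = 1 in ≥ 95%);
and exhaustive enumeration of every hypergeometric instance with N ≤ 12.
Degenerate inputs (zero-variance genes, all-zero negatives, θ = 0, p = 0)
each have a defined, warned behaviour rather than an exception wherever a
downstream stage can proceed meaningfully.

## Known limitations

- The t-test on log2 NB counts with 4 controls is only approximately
  calibrated; the type-I guarantee is stated (and tested) under normal
  noise.
- The additive background biases estimated |Δ| slightly toward zero for
  low-expressed genes; at default baselines the bias is well under the
  0.2-log2 accuracy budget.
- geNorm's pairwise-variation panel-size criterion V(n/n+1) is not
  implemented; panel size is fixed by the user.
- No positive-control or content normalization; no imaging/binding-density
  QC — inputs are assumed to have passed instrument-level QC upstream.
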