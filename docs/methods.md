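# Methods

## Data model and scales

The pipeline operates on gene-by-sample matrices of upper-quartile-
normalised RSEM-like expression values. Scale is tracked explicitly:
`raw` values are non-negative; `log2` is `log2(x + pseudocount)` with a
default pseudocount of 1 (so zeros map to zero, the standard choice for
RSEM); `zscore` is per-gene standardisation with sample sd (ddof = 1)
and exists for heatmap display only. All statistics — ranking scores,
centroids, distances — are computed on the log2 scale, never on
z-scores. Duplicate gene symbols in an input matrix are an error rather
than being averaged; genes missing from a cohort are dropped with a
warning, never imputed. Gene symbols are trimmed and upper-cased on
entry and never alias-resolved: an unmatched symbol is reported, not
silently remapped.

## Panels

Four immune panels are packaged: the 722-gene immune-profiling panel
(shipped verbatim) and stand-ins for the type-I interferon (97 genes),
type-II interferon (200 genes) and T-cell cytotoxicity (115 genes)
pathway sets. The three pathway panels are synthetic — flagged in their
filenames and headers — because the original pathway memberships are
held by an external database; they mix thematically matching genes from
the profiling panel with clearly artificial `SYN*` symbols. Their
overlap structure is one consistent choice among many: 1134 member
entries collapsing onto a 924-gene union (210 overlaps). Analyses that
depend only on panel sizes and union cardinality are faithful;
analyses of which *specific* pathway genes rank highly are only
meaningful for the 722-gene panel.

## Ranking ensemble

One-vs-rest discrimination of a cluster is scored by five deterministic
statistics per gene: absolute Welch *t*; |AUC − 0.5| computed from
midrank sums (equivalent to the Wilcoxon rank-sum statistic); the
signal-to-noise ratio |μ₁−μ₀|/(σ₁+σ₀) with sample sds; the absolute
difference of group means; and the mutual information (in nats) between
the one-vs-rest label and expression binarised strictly above the
pooled median. The set was chosen to span parametric, rank-based and
information-theoretic views of separation while remaining fully
reproducible (no resampling, no seeds). Per ranker, genes receive
average ranks on ties; a gene's aggregate is the mean of its five
ranks; the final order breaks aggregate ties lexicographically by
symbol and is re-numbered 1..m without gaps. Degenerate cases: a
constant gene scores 0 (worst) everywhere; a zero within-group variance
with a nonzero mean difference is a perfect separator and scores +inf.
All five statistics are invariant to adding a constant to one gene
across all samples, so ranking is unaffected by per-gene location
shifts.

Signatures take the top `ceil(q*m)` genes of each table and merge the
selections into a sorted union. `ceil` is used because the published
selection counts cannot disambiguate the rounding rule; requesting
`q*m < 1` for any table is an error rather than silently selecting one
gene. `q` is monotone: a larger fraction always yields a superset.

## Dual-centroid classification

Training computes, per cluster, the arithmetic mean log2 expression of
its samples (main centroid) and of all other samples (alternative
centroid) over the signature genes — eight vectors. Assignment finds
the nearest main centroid in Euclidean distance and accepts it only if
it is strictly nearer than the same cluster's alternative centroid;
otherwise the sample is `UNCLASSIFIED`. A tied nearest main centroid
is also unclassified (logged) — a measure-zero event on continuous
data, resolved this way to preserve the strict-inequality spirit of the
rule. Consequently the assigned-label set is always a subset of what a
plain nearest-centroid rule would give: each sample either agrees or
abstains. Distances use unstandardised log2 values by default; an
optional per-gene z-scoring flag freezes training means/sds into the
model and standardises queries with them (off by default — the
centroids are defined as mean expression, and standardisation is a
robustness option rather than part of the procedure). Signature genes
absent from a prediction cohort are dropped from the model
symmetrically, with a warning above 10% missing.

## Hierarchical clustering

Samples are clustered with Euclidean distance and average linkage on
row-z-scored log2 signature expression; genes, when ordered for
heatmaps, the same way. No metric or linkage is canonical for this
analysis, so these common heatmap defaults were chosen and are recorded
in every result object (`LinkageResult` keeps the linkage matrix,
metric/linkage names and leaf order together; trees export to Newick).
Trees are deterministic given input order; the cut-to-k partition is
invariant to sample order on continuous data (ties between merge
heights could break this, but have measure zero). Partition agreement
is scored by the adjusted Rand index (chance-corrected; 1 iff the
partitions coincide).

## Overrepresentation test

For a category holding K of the N reference genes and k hits in an
n-gene list, the expected count is E = nK/N, fold enrichment k/E
(direction "+" iff k ≥ E, with k = E reported as "+" and FE 1.0), and
the p-value is the one-sided binomial tail — P(X ≥ k) for "+",
P(X ≤ k) for "−", X ~ Binomial(n, K/N) — Bonferroni-multiplied by the
number of categories tested (overridable; the published analyses used
B = 158 for both gene lists). E = 0 with k > 0 is flagged as infinite
enrichment rather than reported as a number. n is deliberately an
input, not always |list|: annotation databases map some symbols to
multiple reference entries (377 symbols → 385 entries, 157 → 158), so
the mapped list size from a published table header can be supplied
directly; when the catalog carries an explicit reference universe, n
defaults to |list ∩ reference|. Reporting follows the published table
conventions — E and FE to two decimals, p to three significant figures
in scientific notation — with full precision kept in machine output.
The binomial model intentionally ignores the without-replacement
correction; it tracks the hypergeometric (Fisher) tail within an order
of magnitude at these list sizes, which the test suite checks as a
sanity bound, not an equality.

## Synthetic cohorts

`generate_cohort` draws, per gene, a baseline from N(8, 2²) log2 units,
marks a fraction (default 0.5) of panel genes "responsive", and shifts
each responsive gene's mean by `gradient[cluster]` — default
(0, 1, 2, 3) log2 units — before adding i.i.d. N(0, noise_sd²) noise
(default sd 0.5). Defaults mirror the study scale: cluster sizes
(30, 30, 31, 31) ≈ a 122-sample discovery cohort, 2 000 background
genes next to the ~900-gene panel; a validation cohort of
(56, 56, 56, 57) ≈ 225 samples shares the gene model (baselines and
responsive set) but has an independent noise stream, selected by
`cohort_id`. No effect-size estimate exists for the real cluster I→IV
gradient, so the one-log2-unit step is a package choice — deliberately
strong enough that failures indicate implementation defects, not
borderline statistics. The marker-design variant
(`generate_marker_cohort`) instead gives each cluster its own disjoint
set of up-shifted marker genes, the right structure for testing
signature recovery. Per-cluster noise blocks are seeded by the
cluster's rank in the sorted (size, gradient) list, which makes
permuting the cluster order together with the gradient an exact
relabelling of the output — a convenient, testable invariance.
Deliberately not modelled: tumour purity, batch effects, count-level
(negative-binomial) noise, gene–gene correlation beyond the shared
cluster shift. Passing recovery tests on these cohorts demonstrates
the pipeline's correctness, not its power on noisy clinical data.

`generate_annotation` builds a synthetic gene-set catalog with one
category forced to overlap a supplied list far above chance and all
others drawn uniformly from the reference, for end-to-end enrichment
tests.

## Problem sizes and numerical choices

The recovery experiments run at the study's own scale — 122-sample
discovery and 225-sample validation cohorts over the 924-gene combined
panel plus 2 000 background genes, averaged over 20 generator seeds —
which completes in seconds thanks to fully vectorised scoring. The
binomial-tail oracle check enumerates all n ≤ 12 exhaustively.
Tolerances: exact-arithmetic identities (weighted-mean, FE·E = k,
complement consistency) at 1e-9–1e-12; printed-table reproduction at
the tables' own precision (two decimals for E and FE, three significant
figures for p). The two under-representation rows of the published
pathway tables print p = 0.00E+00 while the computed lower tails are
≈1e-38 and ≈5e-15; this is a display-underflow convention of the
original tool, so those two cells are compared on E and FE only.

## Limitations

- The five-ranker ensemble is this package's documented construction;
  the original feature-selection ensemble is unpublished, so the exact
  published gene lists (377/44/91/62/157) are not reproducible and are
  not targets.
- The three pathway panels are synthetic stand-ins; supply real gene
  lists via `load_panel` for substantive pathway-level analyses.
- The classifier offers no confidence measure beyond the unclassified
  fallback, and no shrunken-centroid regularisation.
- Bonferroni is the only multiple-testing correction provided.
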