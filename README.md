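# immunosig

Immune gene-signature subtyping of bulk tumour transcriptomes.

Muscle-invasive bladder cancer falls into four transcriptomic clusters
(I–IV, spanning luminal to basal biology) that differ sharply in their
immune activity: interferon-response and T-cell-recruitment genes (e.g.
*CXCL9/10/11* and their receptor *CXCR3*) run from under-expressed in
cluster I to over-expressed in cluster IV. `immunosig` implements the
analysis pipeline behind that observation as a tested, reusable Python
library:

- **Panels** — curated immune gene sets (a 722-gene immune-profiling
  panel plus interferon-α/γ and cytotoxicity pathway sets) combined
  into a 924-gene union.
- **Ranking** — one-vs-rest discriminator ranking of panel genes per
  cluster, by an ensemble of five statistics: the absolute Welch *t*,
  |AUC − ½|, the signal-to-noise ratio |μ₁−μ₀|/(σ₁+σ₀), the absolute
  mean difference on log₂ data, and the mutual information of the label
  with median-binarised expression. Ranks are aggregated by mean rank.
- **Signatures** — the top fraction *q* of each ranking table, merged:
  *q* = 0.20 within a panel and *q* = 0.05 on the combined panel mirror
  the published 377- and 157-gene signature constructions.
- **Dual-centroid classifier** — per cluster *c*, a *main* centroid
  (mean log₂ expression of the cluster's samples) and an *alternative*
  centroid (mean of all other samples), 8 vectors total. A sample gets
  label `argmin_c d(s, main_c)` only if that distance is strictly below
  `d(s, alt_c)`; otherwise it is `UNCLASSIFIED`.
- **Hierarchical clustering** — unsupervised validation on row-z-scored
  signature expression (Euclidean, average linkage), with cut-to-*k*
  labels and adjusted-Rand-index agreement scoring.
- **Enrichment** — the classic binomial over/under-representation test:
  for a category with *K* of *N* reference genes and *k* hits in an
  *n*-gene list, *E* = *nK/N*, fold enrichment *k/E*, one-sided binomial
  tail p-value, Bonferroni-corrected.
- **Synthetic cohorts** — a generator producing labelled four-cluster
  cohorts with a monotone log₂ immune gradient and background genes, so
  every stage is testable end to end without access to patient data.

## Worked example

```python
import dataclasses
from immunosig import (SyntheticConfig, default_registry, generate_cohort,
                       build_ranking_tables, top_fraction_union,
                       fit_centroids, assign_cohort)

registry = default_registry()                   # 4 panels, union = 924 genes
config = SyntheticConfig(seed=7)                # 122 samples: (30,30,31,31)
discovery = generate_cohort(config, registry.combined, cohort_id=1)
validation = generate_cohort(
    dataclasses.replace(config, cluster_sizes=(56, 56, 56, 57)),
    registry.combined, cohort_id=2)

tables = build_ranking_tables(discovery.matrix, discovery.labels, [registry.combined])
signature = top_fraction_union(tables, q=0.05)  # -> 152 genes
model = fit_centroids(discovery.matrix, discovery.labels, signature)
result = assign_cohort(validation.matrix, model)
print(result.counts.to_dict())
print((result.assigned == validation.labels).mean())
```

prints

```
{'IV': 57, 'I': 56, 'II': 56, 'III': 56}
1.0
```

i.e. the top-5% signature (152 genes) trained on the 122-sample
discovery cohort assigns every sample of the independent 225-sample
validation cohort to its true cluster, with none left unclassified —
the expected outcome under the simulated one-log₂-unit-per-cluster
gradient. The `examples/` directory holds one short script per
capability (panels, ranking, classification, clustering, enrichment).

A thin CLI wraps the same functions: `immunosig simulate | preprocess |
rank | select | fit | assign | cluster | enrich | run` (see
`immunosig --help`); `immunosig run` executes the whole pipeline from a
YAML config and writes a manifest with SHA-256 checksums of every
output.

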