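"""One-vs-rest gene ranking and top-fraction signature construction.

Each gene is scored on its ability to separate one cluster's samples
from all remaining samples, by an ensemble of five deterministic
discriminators spanning parametric, rank-based and information-theoretic
statistics:

1. ``welch_t`` — absolute Welch two-sample t statistic;
2. ``auc``     — rank-sum separation expressed as \\|AUC − 0.5\\|;
3. ``snr``     — signal-to-noise ratio \\|mu1 − mu0\\| / (sd1 + sd0);
4. ``lfc``     — absolute difference of group means (log2 fold change
   of means, since scores are computed on log2 data);
5. ``mi``      — mutual information between the one-vs-rest label and
   expression binarised at the pooled median.

Per ranker, genes receive ranks (1 = best, average ranks on ties); the
aggregate rank of a gene is the mean of its five per-ranker ranks, and
the final table orders genes by aggregate rank with lexicographic
tie-breaking, re-numbered 1..m without gaps.  All five statistics are
invariant to adding a constant to a gene across all samples.

Signatures are built by taking the top ceil(q*m) genes of each ranking
table and merging the per-table selections into a sorted set union —
q = 0.20 within a panel and q = 0.05 on the combined panel reproduce
the published 377-gene and 157-gene signature constructions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panels import GenePanel, PanelRegistry
from .preprocess import ExpressionMatrix, subset_to_panel

logger = logging.getLogger(__name__)

RANKERS = ("welch_t", "auc", "snr", "lfc", "mi")


class RankingError(ValueError):
    pass


@dataclass
class RankingTable:
    """Ordered discriminator ranking of one panel's genes for one cluster.

    ``rows``: DataFrame ordered by final rank, with columns ``gene``,
    ``rank``, ``mean_rank``, and per-ranker ``score_*`` / ``rank_*``.
    """

    panel: str
    target_cluster: str
    rows: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return self.rows["gene"].tolist()

    def top(self, count: int) -> list[str]:
        return self.rows["gene"].head(count).tolist()

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SignatureSet:
    """A merged top-fraction gene signature with provenance."""

    genes: tuple[str, ...]
    fraction: float
    source_tables: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")


def _ensemble_scores(values: np.ndarray, in_target: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised five-ranker scores for all genes at once.

    ``values``: genes x samples (log2); ``in_target``: boolean per sample.
    Degenerate genes (zero variance, no separation) score 0 — the worst
    score — for every ranker; a zero-denominator with a nonzero mean
    difference is a perfect separator and scores +inf.
    """
    x1 = values[:, in_target]
    x0 = values[:, ~in_target]
    n1, n0 = x1.shape[1], x0.shape[1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
    diff = np.abs(m1 - m0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(v1 / n1 + v0 / n0)
        snr = diff / (np.sqrt(v1) + np.sqrt(v0))
    t = np.where(np.isnan(t), 0.0, t)          # 0/0: constant gene
    snr = np.where(np.isnan(snr), 0.0, snr)

    # AUC via rank sums, midranks for ties
    ranks = rankdata(values, axis=1, method="average")
    u1 = ranks[:, in_target].sum(axis=1) - n1 * (n1 + 1) / 2
    auc = np.abs(u1 / (n1 * n0) - 0.5)

    # MI of (expression > pooled median) vs the one-vs-rest label, in nats
    med = np.median(values, axis=1, keepdims=True)
    high = values > med
    n = n1 + n0
    a = high[:, in_target].sum(axis=1).astype(float)   # high & target
    b = high[:, ~in_target].sum(axis=1).astype(float)  # high & rest
    mi = np.zeros(values.shape[0])
    for cell, row_tot, col_tot in (
        (a, lambda: a + b, n1),
        (b, lambda: a + b, n0),
        (n1 - a, lambda: n - a - b, n1),
        (n0 - b, lambda: n - a - b, n0),
    ):
        row = row_tot()
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (cell / n) * np.log(n * cell / (row * col_tot))
        mi += np.where(cell > 0, term, 0.0)
    mi = np.maximum(mi, 0.0)  # clip float round-off below zero

    return {"welch_t": t, "auc": auc, "snr": snr, "lfc": diff, "mi": mi}


def rank_one_vs_rest(
    matrix: ExpressionMatrix, labels: pd.Series, target: str
) -> RankingTable:
    """Rank every gene of ``matrix`` on separating ``target`` vs the rest."""
    if matrix.scale != "log2":
        raise RankingError(f"ranking expects log2-scale data, got {matrix.scale!r}")
    lab = labels.reindex(matrix.samples)
    if lab.isna().any():
        raise RankingError("labels missing for some matrix samples")
    in_target = (lab == target).to_numpy()
    if target not in set(lab):
        raise RankingError(f"target cluster {target!r} absent from labels")
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise RankingError(f"need >=2 samples in cluster {target!r} and in the rest")

    genes = np.array(matrix.genes)
    scores = _ensemble_scores(matrix.values, in_target)
    per_ranker_ranks = {k: rankdata(-s, method="average") for k, s in scores.items()}
    mean_rank = np.mean(list(per_ranker_ranks.values()), axis=0)
    order = np.lexsort((genes, mean_rank))

    rows = pd.DataFrame({"gene": genes[order]})
    rows.insert(0, "rank", np.arange(1, len(genes) + 1))
    rows["mean_rank"] = mean_rank[order]
    for k in RANKERS:
        rows[f"score_{k}"] = scores[k][order]
        rows[f"rank_{k}"] = per_ranker_ranks[k][order]
    return RankingTable(panel=matrix.meta.get("panel", "matrix"), target_cluster=target, rows=rows)


def build_ranking_tables(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    registry: PanelRegistry | list[GenePanel],
    include_combined: bool = False,
    clusters: tuple[str, ...] = ("I", "II", "III", "IV"),
) -> list[RankingTable]:
    """One table per (panel x cluster): 4 panels x 4 clusters = 16 tables,
    plus 4 more for the combined panel when ``include_combined`` is set."""
    panels = list(registry.panels.values()) if isinstance(registry, PanelRegistry) else list(registry)
    if include_combined:
        if not isinstance(registry, PanelRegistry):
            raise RankingError("include_combined requires a PanelRegistry")
        panels = panels + [registry.combined]
    tables = []
    for panel in panels:
        sub, missing = subset_to_panel(matrix, panel)
        sub.meta["panel"] = panel.name
        for cluster in clusters:
            tables.append(rank_one_vs_rest(sub, labels, cluster))
    return tables


def top_fraction_union(tables: list[RankingTable], q: float) -> SignatureSet:
    """Union of the top ceil(q*m) genes from each ranking table."""
    if not tables:
        raise RankingError("no ranking tables supplied")
    if not 0 < q <= 1:
        raise RankingError(f"fraction q={q} outside (0, 1]")
    selected: set[str] = set()
    provenance = []
    for t in tables:
        m = len(t)
        if q * m < 1:
            raise RankingError(
                f"table {t.panel}/{t.target_cluster}: q*m = {q * m:.3g} < 1 selects no gene"
            )
        count = math.ceil(q * m)
        selected.update(t.top(count))
        provenance.append(f"{t.panel}/{t.target_cluster}")
    return SignatureSet(genes=tuple(sorted(selected)), fraction=q, source_tables=tuple(provenance))
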