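"""Ranking-ensemble tests, including a naive single-gene oracle.

The oracle below recomputes each of the five discriminator statistics
from its textbook definition, one gene at a time (explicit pair
counting for the AUC, plogp sums for mutual information), independent
of the vectorised implementation.
"""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunosig.panels import GenePanel, PanelRegistry
from immunosig.preprocess import ExpressionMatrix
from immunosig.ranking import (
    RankingError,
    build_ranking_tables,
    rank_one_vs_rest,
    top_fraction_union,
)
from immunosig.simulate import SyntheticConfig, generate_marker_cohort


def make_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale="log2")


def labels_for(matrix, n_target):
    labs = ["I"] * n_target + ["II"] * (len(matrix.samples) - n_target)
    return pd.Series(labs, index=matrix.samples)


# ---------------------------------------------------------------- oracle ----

def oracle_scores(x, y):
    """Five discriminator statistics for one gene, from first principles."""
    x1 = [v for v, t in zip(x, y) if t]
    x0 = [v for v, t in zip(x, y) if not t]
    m1, m0 = statistics.fmean(x1), statistics.fmean(x0)
    s1, s0 = statistics.stdev(x1), statistics.stdev(x0)
    diff = abs(m1 - m0)

    denom_t = math.sqrt(s1**2 / len(x1) + s0**2 / len(x0))
    t = diff / denom_t if denom_t else (math.inf if diff else 0.0)
    snr = diff / (s1 + s0) if (s1 + s0) else (math.inf if diff else 0.0)

    # AUC by explicit pair counting, ties count one half
    wins = sum((a > b) + 0.5 * (a == b) for a in x1 for b in x0)
    auc = abs(wins / (len(x1) * len(x0)) - 0.5)

    # MI of (value > pooled median) vs label, plogp over the 2x2 table
    med = statistics.median(x)
    n = len(x)
    cells = {}
    for v, lab in zip(x, y):
        key = (v > med, lab)
        cells[key] = cells.get(key, 0) + 1
    mi = 0.0
    for (hi, lab), c in cells.items():
        row = sum(v for (h, _), v in cells.items() if h == hi)
        col = len(x1) if lab else len(x0)
        mi += (c / n) * math.log(n * c / (row * col))
    return {"welch_t": t, "auc": auc, "snr": snr, "lfc": diff, "mi": max(mi, 0.0)}


def oracle_table(matrix, labels, target):
    y = [l == target for l in labels.reindex(matrix.samples)]
    per_gene = {g: oracle_scores(list(matrix.data.loc[g]), y) for g in matrix.genes}
    agg = {g: 0.0 for g in matrix.genes}
    for ranker in ("welch_t", "auc", "snr", "lfc", "mi"):
        scores = {g: per_gene[g][ranker] for g in matrix.genes}
        ranks = stats.rankdata([-scores[g] for g in matrix.genes], method="average")
        for g, r in zip(matrix.genes, ranks):
            agg[g] += r
    return sorted(matrix.genes, key=lambda g: (agg[g] / 5, g))


# ----------------------------------------------------------------- tests ----

class TestRankOneVsRest:
    def test_matches_oracle_on_small_instance(self):
        rng = np.random.default_rng(17)
        matrix = make_matrix(rng.normal(5, 1, size=(5, 8)))
        labels = labels_for(matrix, 4)
        table = rank_one_vs_rest(matrix, labels, "I")
        assert table.genes == oracle_table(matrix, labels, "I")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        matrix = make_matrix(rng.normal(0, 2, size=(7, 10)))
        labels = labels_for(matrix, 5)
        table = rank_one_vs_rest(matrix, labels, "I")
        assert table.genes == oracle_table(matrix, labels, "I")

    def test_planted_signal_gene_ranks_first(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, size=(30, 24))
        values[12, :8] += 5.0  # 5-sigma shift in the target cluster
        matrix = make_matrix(values)
        table = rank_one_vs_rest(matrix, labels_for(matrix, 8), "I")
        assert table.genes[0] == "G12"

    def test_permutation_null_rank_is_uniform(self):
        rng = np.random.default_rng(8)
        m, n = 20, 24
        values = rng.normal(0, 1, size=(m, n))
        values[4, :8] += 5.0
        ranks = []
        for _ in range(120):
            perm = rng.permutation(n)
            matrix = make_matrix(values[:, perm])
            table = rank_one_vs_rest(matrix, labels_for(matrix, 8), "I")
            ranks.append(table.genes.index("G4") + 1)
        # planted gene's rank should be uniform on 1..m once labels are shuffled
        p = stats.kstest(ranks, stats.randint(1, m + 1).cdf).pvalue
        assert p > 1e-3

    def test_identical_genes_tie_lexicographically(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=10)
        values = np.vstack([rng.normal(0, 1, size=10), base, base])
        matrix = make_matrix(values, genes=["ZZZ", "BBB", "AAA"])
        table = rank_one_vs_rest(matrix, labels_for(matrix, 5), "I")
        i, j = table.genes.index("AAA"), table.genes.index("BBB")
        assert j == i + 1

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, size=(8, 12))
        matrix = make_matrix(values)
        shifted = values.copy()
        shifted[3] += 7.25  # constant added to one gene everywhere
        order_a = rank_one_vs_rest(matrix, labels_for(matrix, 6), "I").genes
        order_b = rank_one_vs_rest(make_matrix(shifted), labels_for(matrix, 6), "I").genes
        assert order_a == order_b

    def test_small_cluster_rejected(self):
        matrix = make_matrix(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(RankingError, match=">=2"):
            rank_one_vs_rest(matrix, labels_for(matrix, 1), "I")

    def test_zero_variance_gene_ranks_last(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(6, 10))
        values[2] = 3.14
        matrix = make_matrix(values)
        table = rank_one_vs_rest(matrix, labels_for(matrix, 5), "I")
        assert table.genes[-1] == "G2"

    def test_rank_column_is_gapless(self):
        rng = np.random.default_rng(6)
        matrix = make_matrix(rng.normal(size=(9, 8)))
        table = rank_one_vs_rest(matrix, labels_for(matrix, 4), "I")
        assert table.rows["rank"].tolist() == list(range(1, 10))


class TestBuildRankingTables:
    def _cohort(self):
        rng = np.random.default_rng(10)
        genes = [f"G{i:03d}" for i in range(40)]
        samples = [f"S{i}" for i in range(20)]
        matrix = ExpressionMatrix(
            pd.DataFrame(rng.normal(5, 1, size=(40, 20)), index=genes, columns=samples),
            scale="log2",
        )
        labels = pd.Series((["I", "II", "III", "IV"] * 5), index=samples)
        return matrix, labels

    def test_four_panels_give_16_tables(self):
        matrix, labels = self._cohort()
        reg = PanelRegistry()
        for i in range(4):
            reg.add(GenePanel(f"p{i}", tuple(f"G{j:03d}" for j in range(i * 10, i * 10 + 10))))
        tables = build_ranking_tables(matrix, labels, reg)
        assert len(tables) == 16

    def test_single_panel_gives_4_tables(self):
        matrix, labels = self._cohort()
        tables = build_ranking_tables(matrix, labels, [GenePanel("p", tuple(matrix.genes))])
        assert len(tables) == 4

    def test_combined_panel_adds_4_tables(self):
        matrix, labels = self._cohort()
        reg = PanelRegistry()
        for i in range(4):
            reg.add(GenePanel(f"p{i}", tuple(f"G{j:03d}" for j in range(i * 10, i * 10 + 10))))
        tables = build_ranking_tables(matrix, labels, reg, include_combined=True)
        assert len(tables) == 20
        assert len(tables[-1]) == 40  # combined universe


class TestTopFractionUnion:
    def _tables(self, orders):
        out = []
        for i, genes in enumerate(orders):
            rows = pd.DataFrame({"rank": range(1, len(genes) + 1), "gene": genes})
            from immunosig.ranking import RankingTable

            out.append(RankingTable(panel="p", target_cluster=str(i), rows=rows))
        return out

    def test_identical_tables_full_overlap(self):
        genes = [f"G{i:03d}" for i in range(100)]
        sig = top_fraction_union(self._tables([genes] * 4), q=0.05)
        assert len(sig) == 5

    def test_disjoint_tops_no_overlap(self):
        tables = []
        for t in range(4):
            top = [f"T{t}_{i}" for i in range(5)]
            rest = [f"R{i:03d}" for i in range(95)]
            tables.append([*top, *rest])
        sig = top_fraction_union(self._tables(tables), q=0.05)
        assert len(sig) == 20

    def test_monotone_in_q(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i:03d}" for i in range(50)]
        orders = [list(rng.permutation(genes)) for _ in range(4)]
        small = set(top_fraction_union(self._tables(orders), q=0.1).genes)
        large = set(top_fraction_union(self._tables(orders), q=0.3).genes)
        assert small <= large

    def test_too_small_fraction_rejected(self):
        genes = [f"G{i}" for i in range(5)]
        with pytest.raises(RankingError, match="< 1"):
            top_fraction_union(self._tables([genes]), q=0.1)

    def test_marker_recovery(self):
        """Per-cluster planted markers are recovered by the top-fraction union."""
        recovered = []
        panel = GenePanel("toy", tuple(f"G{i:03d}" for i in range(200)))
        for seed in range(5):
            cfg = SyntheticConfig(
                cluster_sizes=(12, 12, 12, 12), n_background_genes=0,
                noise_sd=0.5, seed=seed,
            )
            cohort = generate_marker_cohort(cfg, panel, markers_per_cluster=10, marker_effect=2.0)
            tables = build_ranking_tables(cohort.matrix, cohort.labels, [panel])
            sig = top_fraction_union(tables, q=10 / 200)
            planted = set(cohort.truth[cohort.truth != "background"].index)
            recovered.append(len(planted & set(sig.genes)) / len(planted))
        assert np.mean(recovered) >= 0.9
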