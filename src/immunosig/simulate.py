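"""Synthetic labelled expression cohorts with a four-cluster immune gradient.

The generator emulates the structure the downstream analysis assumes: a
cohort of bulk tumour samples partitioned into four molecular clusters
(I–IV) in which a subset of immune-panel genes shows a monotone
log2-expression gradient from under-expression in cluster I to
over-expression in cluster IV, on a background of uninformative genes.

Model: for gene g and sample s in cluster c,

    x[g, s] = baseline[g] + shift[g, c] + eps[g, s],   eps ~ N(0, noise_sd)

with shift = gradient[c] for responsive panel genes and 0 otherwise.
Baselines are drawn once per gene from N(baseline_mean, baseline_sd).
All values are on the log2 scale; an optional raw-scale export applies
2**x − 1 so that the preprocessing log2(x+1) round-trips.

Cluster noise blocks are drawn from per-cluster child seeds keyed by
each cluster's rank in the sorted (size, gradient) list, so permuting
the cluster order together with the gradient yields the same cohort up
to relabelling — an exact invariance, convenient for testing.

Deliberately not modelled: tumour purity, batch effects, and count-level
(negative-binomial) sequencing noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationCatalog
from .panels import GenePanel
from .preprocess import ExpressionMatrix, unlog_transform, write_labels

logger = logging.getLogger(__name__)

CLUSTERS = ("I", "II", "III", "IV")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: a 122-sample discovery cohort (30/30/31/31)
    over a ~900-gene immune panel plus 2000 background genes, with a
    one-log2-unit-per-cluster expression gradient and 0.5 log2 units of
    per-observation noise."""

    cluster_sizes: tuple[int, int, int, int] = (30, 30, 31, 31)
    n_background_genes: int = 2000
    responsive_fraction: float = 0.5
    gradient: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 3.0)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != 4 or any(s < 1 for s in self.cluster_sizes):
            raise SimulationError("cluster_sizes must be 4 integers >= 1")
        if len(self.gradient) != 4:
            raise SimulationError("gradient must have 4 entries")
        if any(b > a for a, b in zip(self.gradient[1:], self.gradient[:-1])):
            raise SimulationError("gradient must be non-decreasing")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise SimulationError("responsive_fraction must lie in [0, 1]")
        if self.n_background_genes < 0:
            raise SimulationError("n_background_genes must be non-negative")


@dataclass
class LabeledCohort:
    """A simulated cohort: log2 expression, cluster labels, per-gene truth.

    ``truth`` maps each gene to ``background``, ``responsive`` (gradient
    design) or the cluster whose marker it is (marker design).
    """

    matrix: ExpressionMatrix
    labels: pd.Series
    truth: pd.Series

    def __post_init__(self) -> None:
        if not set(self.labels.unique()) <= set(CLUSTERS):
            raise SimulationError(f"labels outside {CLUSTERS}: {sorted(set(self.labels.unique()))}")
        if list(self.labels.index) != self.matrix.samples:
            raise SimulationError("labels do not cover the matrix samples in order")
        if self.matrix.data.isna().any().any():
            raise SimulationError("cohort matrix contains missing values")

    def to_raw(self, pseudocount: float = 1.0) -> ExpressionMatrix:
        """Raw-scale export (2**x − pseudocount); round-trips through log2(x+1)."""
        return unlog_transform(self.matrix, pseudocount=pseudocount)

    def write(self, expression_path: str | Path, labels_path: str | Path) -> None:
        self.matrix.to_tsv(expression_path)
        write_labels(self.labels, labels_path)


def _cluster_slots(config: SyntheticConfig) -> list[int]:
    """Permutation-stable slot index per cluster, keyed by (size, gradient)."""
    keyed = sorted(range(4), key=lambda i: (config.cluster_sizes[i], config.gradient[i]))
    # assign sorted positions back; ties get distinct slots in sorted order,
    # which is harmless because tied clusters are exchangeable
    slots = [0] * 4
    for slot, i in enumerate(keyed):
        slots[i] = slot
    return slots


def _gene_layout(config: SyntheticConfig, panel: GenePanel, rng: np.random.Generator):
    panel_genes = list(panel.genes)
    background = [f"BG{i:05d}" for i in range(1, config.n_background_genes + 1)]
    clash = set(panel_genes) & set(background)
    if clash:
        raise SimulationError(f"background gene names collide with panel: {sorted(clash)[:3]}")
    genes = panel_genes + background
    if not genes:
        raise SimulationError("degenerate config: no genes to simulate")
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    return genes, baselines


def generate_cohort(
    config: SyntheticConfig, panel: GenePanel, cohort_id: int = 1
) -> LabeledCohort:
    """Simulate a gradient-design cohort over ``panel`` + background genes.

    A fixed fraction of panel genes (chosen reproducibly from the seed)
    is "responsive": its cluster-conditional mean is shifted by
    ``gradient[cluster]``.  ``cohort_id`` selects an independent noise
    stream with the same gene model, so a discovery and a validation
    cohort share baselines and responsive genes, as two samples from
    one population would.
    """
    if len(panel) == 0:
        raise SimulationError("panel must be non-empty")
    gene_rng = np.random.default_rng([config.seed, 0])
    genes, baselines = _gene_layout(config, panel, gene_rng)
    n_resp = int(round(config.responsive_fraction * len(panel)))
    resp_idx = np.sort(gene_rng.choice(len(panel), size=n_resp, replace=False))
    responsive = np.zeros(len(genes), dtype=bool)
    responsive[resp_idx] = True

    slots = _cluster_slots(config)
    blocks, sample_ids, labels = [], [], []
    for ci, cluster in enumerate(CLUSTERS):
        size = config.cluster_sizes[ci]
        block_rng = np.random.default_rng([config.seed, 1000 * cohort_id + slots[ci]])
        noise = block_rng.normal(0.0, config.noise_sd, size=(len(genes), size))
        mean = baselines[:, None] + np.where(responsive, config.gradient[ci], 0.0)[:, None]
        blocks.append(mean + noise)
        sample_ids.extend(f"C{cohort_id}_{cluster}_{j:03d}" for j in range(1, size + 1))
        labels.extend([cluster] * size)

    data = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    truth = pd.Series(np.where(responsive, "responsive", "background"), index=genes, name="truth")
    return LabeledCohort(
        matrix=ExpressionMatrix(data=data, scale="log2", meta={"seed": config.seed, "cohort": cohort_id}),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        truth=truth,
    )


def generate_marker_cohort(
    config: SyntheticConfig,
    panel: GenePanel,
    markers_per_cluster: int = 10,
    marker_effect: float = 2.0,
    cohort_id: int = 1,
) -> LabeledCohort:
    """Simulate a marker-design cohort: each cluster owns a disjoint set
    of ``markers_per_cluster`` panel genes up-shifted by
    ``marker_effect`` log2 units in that cluster only.

    This is the design for signature-recovery experiments: one-vs-rest
    ranking should place a cluster's own markers at the top of its
    table.  ``truth`` records the owning cluster per marker gene.
    """
    if len(panel) == 0:
        raise SimulationError("panel must be non-empty")
    if 4 * markers_per_cluster > len(panel):
        raise SimulationError("panel too small for the requested markers")
    gene_rng = np.random.default_rng([config.seed, 0])
    genes, baselines = _gene_layout(config, panel, gene_rng)
    marker_idx = gene_rng.choice(len(panel), size=4 * markers_per_cluster, replace=False)
    owner = np.full(len(genes), "", dtype=object)
    for ci, cluster in enumerate(CLUSTERS):
        owner[marker_idx[ci * markers_per_cluster : (ci + 1) * markers_per_cluster]] = cluster

    slots = _cluster_slots(config)
    blocks, sample_ids, labels = [], [], []
    for ci, cluster in enumerate(CLUSTERS):
        size = config.cluster_sizes[ci]
        block_rng = np.random.default_rng([config.seed, 1000 * cohort_id + slots[ci]])
        noise = block_rng.normal(0.0, config.noise_sd, size=(len(genes), size))
        mean = baselines[:, None] + np.where(owner == cluster, marker_effect, 0.0)[:, None]
        blocks.append(mean + noise)
        sample_ids.extend(f"C{cohort_id}_{cluster}_{j:03d}" for j in range(1, size + 1))
        labels.extend([cluster] * size)

    data = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    truth = pd.Series(
        [o if o else "background" for o in owner], index=genes, name="truth"
    )
    return LabeledCohort(
        matrix=ExpressionMatrix(data=data, scale="log2", meta={"seed": config.seed, "cohort": cohort_id}),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        truth=truth,
    )


def generate_annotation(
    n_categories: int,
    category_sizes: Sequence[int],
    reference_size: int,
    enriched_category: str,
    overlap_with: Sequence[str],
    overlap_size: int,
    seed: int = 0,
) -> AnnotationCatalog:
    """Build a synthetic annotation catalog with one planted enrichment.

    The category named ``enriched_category`` (one of CAT01..CATnn, or a
    custom name given in place of its positional slot) is forced to
    contain ``overlap_size`` members of ``overlap_with``; every other
    category is a uniform draw from the reference, hence at chance.
    """
    if len(category_sizes) != n_categories:
        raise SimulationError("need one size per category")
    query = [str(g).strip().upper() for g in overlap_with]
    if len(set(query)) != len(query):
        raise SimulationError("overlap_with contains duplicates")
    if overlap_size > len(query):
        raise SimulationError("requested overlap exceeds the supplied gene list")
    names = [f"CAT{i:02d}" for i in range(1, n_categories + 1)]
    if enriched_category not in names:
        names[0] = enriched_category
    target_size = category_sizes[names.index(enriched_category)]
    if overlap_size > target_size:
        raise SimulationError("requested overlap exceeds the category size")
    if len(query) > reference_size:
        raise SimulationError("gene list larger than the reference universe")

    filler = [f"REF{i:05d}" for i in range(1, reference_size - len(query) + 1)]
    reference = query + filler
    rng = np.random.default_rng([seed, 42])
    non_query = np.array(filler)
    categories: dict[str, frozenset[str]] = {}
    for name, size in zip(names, category_sizes):
        if not 1 <= size <= reference_size:
            raise SimulationError(f"category size {size} outside [1, {reference_size}]")
        if name == enriched_category:
            forced = list(rng.choice(np.array(query), size=overlap_size, replace=False))
            rest = list(rng.choice(non_query, size=size - overlap_size, replace=False))
            categories[name] = frozenset(forced + rest)
        else:
            categories[name] = frozenset(rng.choice(np.array(reference), size=size, replace=False))
    return AnnotationCatalog(
        reference_size=reference_size, categories=categories, reference=frozenset(reference)
    )
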