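"""Binomial over/under-representation analysis of gene lists.

Re-implements the classic PANTHER-style test: for a category containing
K of the N reference genes, the number of hits k in an analysed list of
n genes is compared with its expectation E = n·K/N under random
sampling, via a one-sided binomial tail — P(X ≥ k) for over-represented
categories, P(X ≤ k) for under-represented ones, X ~ Binomial(n, K/N).
Raw p-values are Bonferroni-corrected by the number of categories
tested (overridable, e.g. the 158 used for the published pathway
analyses).

Reporting follows the original tool's table conventions: expected
counts and fold enrichments to two decimals, p-values to three
significant figures in scientific notation; machine output keeps full
precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationCatalog:
    """Gene-set catalog with an explicit reference-universe size.

    ``reference_size`` is N, the number of genes in the reference list
    (the whole genome for the published analyses).  ``categories`` maps
    category ID to its member genes; ``reference`` optionally holds the
    full reference gene universe, enabling k and n to be computed from
    a query list.
    """

    reference_size: int
    categories: Mapping[str, frozenset[str]]
    reference: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.reference_size <= 0:
            raise EnrichmentError("reference_size must be positive")
        for name, members in self.categories.items():
            if not 1 <= len(members) <= self.reference_size:
                raise EnrichmentError(
                    f"category {name!r}: size {len(members)} outside [1, {self.reference_size}]"
                )
        if self.reference is not None and len(self.reference) != self.reference_size:
            raise EnrichmentError("reference set size disagrees with reference_size")


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's result, mirroring the published table columns."""

    category: str
    K: int          # reference count
    k: int          # observed count in the analysed list
    n: int          # analysed-list size (reference-mapped)
    expected: float  # E = n*K/N, unrounded
    direction: str   # "+" if k >= E else "-"
    fold_enrichment: float | None  # k/E; None flags infinite enrichment (E == 0, k > 0)
    p_raw: float
    bonferroni_count: int
    p_corrected: float

    @property
    def expected_2dp(self) -> float:
        return round(self.expected, 2)

    @property
    def fold_enrichment_2dp(self) -> float | None:
        return None if self.fold_enrichment is None else round(self.fold_enrichment, 2)

    @property
    def p_formatted(self) -> str:
        return format_pvalue(self.p_corrected)


def format_pvalue(p: float) -> str:
    """Three-significant-figure scientific notation, e.g. ``1.50E-04``."""
    return f"{p:.2E}"


def expected_count(n: int, K: int, N: int) -> float:
    """Expected category hits E = n*K/N for an n-gene list."""
    if N <= 0:
        raise EnrichmentError("reference size N must be positive")
    if not 0 <= K <= N:
        raise EnrichmentError(f"category reference count K={K} outside [0, {N}]")
    if n < 0:
        raise EnrichmentError("list size n must be non-negative")
    return n * K / N


def fold_enrichment(k: int, expected: float) -> tuple[float | None, str]:
    """Fold enrichment k/E and its direction sign.

    Direction is "+" when k >= E (ties resolved to "+", FE 1.0).
    E == 0 with k > 0 is flagged as infinite enrichment (FE None).
    """
    if expected < 0:
        raise EnrichmentError("expected count must be non-negative")
    if expected == 0:
        return (None, "+") if k > 0 else (0.0, "+")
    return k / expected, ("+" if k >= expected else "-")


def binomial_tail_p(k: int, n: int, p: float, direction: str) -> float:
    """One-sided binomial tail: P(X >= k) for "+", P(X <= k) for "-"."""
    if not 0 < p < 1:
        raise EnrichmentError(f"success probability p={p} outside (0, 1)")
    if not 0 <= k <= n:
        raise EnrichmentError(f"observed count k={k} outside [0, n={n}]")
    if direction == "+":
        return float(binom.sf(k - 1, n, p))
    if direction == "-":
        return float(binom.cdf(k, n, p))
    raise EnrichmentError(f"direction must be '+' or '-', got {direction!r}")


def bonferroni(p_raw: float, count: int) -> float:
    """Bonferroni correction min(1, p_raw * count)."""
    if count < 1:
        raise EnrichmentError("Bonferroni count must be >= 1")
    return min(1.0, p_raw * count)


def score_category(
    category: str, K: int, k: int, n: int, N: int, bonferroni_count: int
) -> EnrichmentRow:
    """Full test for one category from its printed-table inputs."""
    E = expected_count(n, K, N)
    fe, direction = fold_enrichment(k, E)
    p_raw = binomial_tail_p(k, n, K / N, direction)
    return EnrichmentRow(
        category=category,
        K=K,
        k=k,
        n=n,
        expected=E,
        direction=direction,
        fold_enrichment=fe,
        p_raw=p_raw,
        bonferroni_count=bonferroni_count,
        p_corrected=bonferroni(p_raw, bonferroni_count),
    )


def run_overrepresentation(
    gene_list: Iterable[str],
    catalog: AnnotationCatalog,
    bonferroni_count: int | None = None,
    n_mapped: int | None = None,
) -> list[EnrichmentRow]:
    """Score every catalog category against a gene list.

    ``n`` (the binomial trial count) is the number of list genes mapped
    to the reference.  When the catalog carries an explicit reference
    universe it is computed as |list ∩ reference| (unmapped genes are
    dropped and logged); otherwise, or when ``n_mapped`` is given, the
    supplied/implied value is used directly — annotation databases map
    some symbols to multiple reference entries, so published list sizes
    (385 for 377 symbols, 158 for 157) are accepted as inputs.

    Rows are ordered with over-represented categories first, by fold
    enrichment descending, then under-represented ones.
    """
    genes = {str(g).strip().upper() for g in gene_list}
    if not genes:
        raise EnrichmentError("empty gene list")
    if catalog.reference is not None:
        mapped = genes & catalog.reference
        dropped = len(genes) - len(mapped)
        if dropped:
            logger.info("%d/%d query genes not in reference (dropped)", dropped, len(genes))
        if not mapped:
            raise EnrichmentError("no query gene maps to the reference list")
        genes = mapped
    n = n_mapped if n_mapped is not None else len(genes)
    B = bonferroni_count if bonferroni_count is not None else len(catalog.categories)
    rows = [
        score_category(name, len(members), len(genes & members), n, catalog.reference_size, B)
        for name, members in catalog.categories.items()
    ]
    plus = sorted(
        (r for r in rows if r.direction == "+"),
        key=lambda r: (-(math.inf if r.fold_enrichment is None else r.fold_enrichment), r.category),
    )
    minus = sorted((r for r in rows if r.direction == "-"), key=lambda r: (r.fold_enrichment or 0.0, r.category))
    return plus + minus


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate results with both full-precision and table-style columns."""
    return pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "reference_count": [r.K for r in rows],
            "observed": [r.k for r in rows],
            "expected": [r.expected_2dp for r in rows],
            "direction": [r.direction for r in rows],
            "fold_enrichment": [r.fold_enrichment_2dp for r in rows],
            "p_corrected": [r.p_formatted for r in rows],
            "p_raw_full": [r.p_raw for r in rows],
            "p_corrected_full": [r.p_corrected for r in rows],
        }
    )


def write_enrichment_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    rows_to_frame(rows).to_csv(path, sep="\t", index=False)


# --- GMT catalog I/O ---------------------------------------------------------
# The GMT line format (name <tab> description <tab> member genes...) is simple
# enough to parse directly; the reference size N travels in a "#reference_size="
# comment header or is supplied by the caller.


def read_gmt(
    path: str | Path, reference_size: int | None = None, reference: Iterable[str] | None = None
) -> AnnotationCatalog:
    """Read a GMT gene-set file into an :class:`AnnotationCatalog`.

    ``reference_size`` may be embedded as a ``#reference_size=N`` header
    line; an explicit argument overrides it.  If neither is present the
    union of all category members is used as the reference universe.
    """
    cats: dict[str, frozenset[str]] = {}
    embedded_N: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "reference_size=" in line:
                    embedded_N = int(line.split("reference_size=")[1].split()[0])
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0].strip()
            members = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not members:
                raise EnrichmentError(f"{path}:{lineno}: category {name!r} has no members")
            if name in cats:
                raise EnrichmentError(f"{path}:{lineno}: duplicate category {name!r}")
            cats[name] = members
    if not cats:
        raise EnrichmentError(f"{path}: no categories found")
    ref = frozenset(g.strip().upper() for g in reference) if reference is not None else None
    N = reference_size or embedded_N
    if N is None:
        if ref is None:
            ref = frozenset().union(*cats.values())
        N = len(ref)
    return AnnotationCatalog(reference_size=N, categories=cats, reference=ref)


def write_gmt(catalog: AnnotationCatalog, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference_size={catalog.reference_size}\n")
        for name, members in catalog.categories.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def load_pathway_table(path: str | Path) -> tuple[pd.DataFrame, int, int]:
    """Read a printed-table input TSV (category_id, category, K, k).

    Header comments carry ``reference_size`` and ``mapped_list_size``.
    Returns (table, N, n).
    """
    N = n = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for key in ("reference_size", "mapped_list_size"):
                if key + "=" in line:
                    val = int(line.split(key + "=")[1].split()[0])
                    N, n = (val, n) if key == "reference_size" else (N, val)
    if N is None or n is None:
        raise EnrichmentError(f"{path}: missing reference_size/mapped_list_size header")
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, N, n


def score_pathway_table(path: str | Path, bonferroni_count: int = 158) -> list[EnrichmentRow]:
    """Score every row of a printed-table input file (K, k per category)."""
    df, N, n = load_pathway_table(path)
    return [
        score_category(row.category, int(row.K), int(row.k), n, N, bonferroni_count)
        for row in df.itertuples()
    ]
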