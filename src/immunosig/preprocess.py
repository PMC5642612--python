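"""Expression matrices and the preprocessing steps that feed the pipeline.

The unit of data is a gene-by-sample matrix of upper-quartile-normalised
RSEM-like expression values.  The matrix tracks its scale explicitly
(``raw`` → ``log2`` → ``zscore``) so that downstream stages can assert
they received the scale they expect: ranking and centroid fitting run on
log2 values; per-gene z-scoring exists for heatmap display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import GenePanel

logger = logging.getLogger(__name__)

SCALES = ("raw", "log2", "zscore")


class MatrixError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with a tracked scale.

    ``data`` is a pandas DataFrame indexed by gene symbol with sample
    IDs as columns.  Invariants enforced on construction: unique genes
    and samples, finite values on log scales, non-negative values on the
    raw scale.
    """

    data: pd.DataFrame
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate gene symbols: {dup[:5]}{'...' if len(dup) > 5 else ''}")
        if self.data.columns.has_duplicates:
            raise MatrixError("duplicate sample IDs")
        values = self.data.to_numpy(dtype=float)
        if self.scale == "raw":
            if np.isnan(values).any():
                raise MatrixError("missing values in raw matrix")
            if (values < 0).any():
                raise MatrixError("negative values in raw-scale matrix")
        else:
            if not np.isfinite(values).all():
                raise MatrixError(f"non-finite values in {self.scale}-scale matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "raw") -> "ExpressionMatrix":
        """Read a genes-x-samples TSV (header row of sample IDs).

        The first column may be labelled ``gene`` or ``gene_id`` (or
        anything else); it is taken as the gene-symbol index.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "gene"
        return cls(data=df.astype(float), scale=scale)

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format=float_format)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on a raw-scale matrix.

    The pseudocount default of 1 maps RSEM zeros to 0 on the log scale.
    """
    if matrix.scale != "raw":
        raise MatrixError(f"log2_transform expects a raw-scale matrix, got {matrix.scale!r}")
    if pseudocount < 0:
        raise MatrixError("pseudocount must be non-negative")
    values = matrix.values
    if pseudocount == 0 and (values == 0).any():
        raise MatrixError("pseudocount 0 with zero expression values would produce -inf")
    out = pd.DataFrame(np.log2(values + pseudocount), index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data=out, scale="log2", meta={**matrix.meta, "pseudocount": pseudocount})


def unlog_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`: 2**x − pseudocount, back to raw scale."""
    if matrix.scale != "log2":
        raise MatrixError(f"unlog_transform expects a log2-scale matrix, got {matrix.scale!r}")
    out = pd.DataFrame(
        np.exp2(matrix.values) - pseudocount, index=matrix.data.index, columns=matrix.data.columns
    )
    # clip tiny negative round-off so the raw-scale invariant holds
    out[out < 0] = out[out < 0].where(out < -1e-9, 0.0)
    return ExpressionMatrix(data=out, scale="raw", meta=dict(matrix.meta))


def subset_to_panel(
    matrix: ExpressionMatrix, panel: GenePanel
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to panel genes, in panel order.

    Returns the restricted matrix and the list of panel genes missing
    from the matrix.  Matching is case-insensitive (panel symbols are
    upper-case).  Raises if no panel gene is measured.
    """
    upper_index = {g.upper(): g for g in matrix.data.index}
    present, missing = [], []
    for g in panel.genes:
        if g in upper_index:
            present.append(upper_index[g])
        else:
            missing.append(g)
    if not present:
        raise MatrixError(f"no genes of panel {panel.name!r} present in matrix")
    if missing:
        logger.warning(
            "panel %s: %d/%d genes absent from matrix (dropped)", panel.name, len(missing), len(panel)
        )
    sub = ExpressionMatrix(data=matrix.data.loc[present], scale=matrix.scale, meta=dict(matrix.meta))
    return sub, missing


def zscore_rows(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-gene standardisation (mean 0, sd 1 with sample sd, ddof=1).

    Display convention for heatmaps; never used for ranking or
    centroid distances.  Errors on any zero-variance gene, naming it.
    """
    if matrix.scale != "log2":
        raise MatrixError(f"zscore_rows expects a log2-scale matrix, got {matrix.scale!r}")
    values = matrix.values
    sd = values.std(axis=1, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise MatrixError(f"zero-variance gene(s): {[matrix.genes[i] for i in bad[:5]]}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    out = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data=out, scale="zscore", meta=dict(matrix.meta))


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample→cluster TSV into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] != 1:
        raise MatrixError(f"{path}: expected exactly two columns (sample, cluster)")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    s.name = "cluster"
    return s


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("cluster")
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
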