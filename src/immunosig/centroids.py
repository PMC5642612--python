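"""Dual-centroid nearest-distance subtype classifier.

For each of the four clusters the model stores two centroids computed
on a labelled discovery cohort: the *main* centroid (mean log2
expression of the cluster's samples over the signature genes) and the
*alternative* centroid (mean over all samples *not* in the cluster) —
eight vectors in total.  A new sample is assigned to the cluster whose
main centroid is nearest in Euclidean distance, but only if that
distance is strictly smaller than the distance to the same cluster's
alternative centroid; otherwise the sample is left ``UNCLASSIFIED``.
A non-unique nearest main centroid is likewise unclassified (logged);
that is a measure-zero event on continuous data.

Distances are computed on unstandardised log2 values by default.  An
optional per-gene z-scoring flag freezes the training means/sds into
the model and standardises query samples with them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess import ExpressionMatrix
from .ranking import SignatureSet

logger = logging.getLogger(__name__)

CLUSTERS = ("I", "II", "III", "IV")
UNCLASSIFIED = "UNCLASSIFIED"


class ClassifierError(ValueError):
    pass


@dataclass
class CentroidModel:
    """Signature genes plus 8 centroid vectors (main + alternative per cluster)."""

    genes: tuple[str, ...]
    clusters: tuple[str, ...]
    main: np.ndarray        # (n_clusters, n_genes)
    alt: np.ndarray         # (n_clusters, n_genes)
    zscore: bool = False
    train_mean: np.ndarray | None = None
    train_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        G = len(self.genes)
        if self.main.shape != (len(self.clusters), G) or self.alt.shape != (len(self.clusters), G):
            raise ClassifierError("centroid matrices must be (n_clusters, n_genes)")
        if not (np.isfinite(self.main).all() and np.isfinite(self.alt).all()):
            raise ClassifierError("non-finite centroid values")

    @property
    def n_centroids(self) -> int:
        return 2 * len(self.clusters)

    def restrict(self, genes: list[str]) -> "CentroidModel":
        """Drop model genes absent from a prediction cohort (symmetric subset)."""
        keep = [i for i, g in enumerate(self.genes) if g in set(genes)]
        if not keep:
            raise ClassifierError("no model gene present in the prediction cohort")
        frac_missing = 1 - len(keep) / len(self.genes)
        if frac_missing > 0.10:
            logger.warning("%.0f%% of signature genes missing from prediction cohort", 100 * frac_missing)
        return CentroidModel(
            genes=tuple(self.genes[i] for i in keep),
            clusters=self.clusters,
            main=self.main[:, keep],
            alt=self.alt[:, keep],
            zscore=self.zscore,
            train_mean=None if self.train_mean is None else self.train_mean[keep],
            train_sd=None if self.train_sd is None else self.train_sd[keep],
            meta=dict(self.meta),
        )

    def save(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        """Serialise as a TSV bundle (gene list + 8 centroid columns) + JSON header."""
        tsv_path = Path(tsv_path)
        cols = {}
        for ci, c in enumerate(self.clusters):
            cols[f"main_{c}"] = self.main[ci]
            cols[f"alt_{c}"] = self.alt[ci]
        if self.zscore:
            cols["train_mean"] = self.train_mean
            cols["train_sd"] = self.train_sd
        df = pd.DataFrame(cols, index=pd.Index(self.genes, name="gene"))
        df.to_csv(tsv_path, sep="\t")
        header = {"clusters": list(self.clusters), "zscore": self.zscore, **self.meta}
        with open(json_path or tsv_path.with_suffix(".json"), "w") as fh:
            json.dump(header, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, tsv_path: str | Path, json_path: str | Path | None = None) -> "CentroidModel":
        tsv_path = Path(tsv_path)
        with open(json_path or tsv_path.with_suffix(".json")) as fh:
            header = json.load(fh)
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
        clusters = tuple(header["clusters"])
        zscore = bool(header.get("zscore", False))
        return cls(
            genes=tuple(df.index.astype(str)),
            clusters=clusters,
            main=np.vstack([df[f"main_{c}"].to_numpy() for c in clusters]),
            alt=np.vstack([df[f"alt_{c}"].to_numpy() for c in clusters]),
            zscore=zscore,
            train_mean=df["train_mean"].to_numpy() if zscore else None,
            train_sd=df["train_sd"].to_numpy() if zscore else None,
            meta={k: v for k, v in header.items() if k not in ("clusters", "zscore")},
        )


def fit_centroids(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    signature: SignatureSet | list[str],
    zscore: bool = False,
) -> CentroidModel:
    """Fit the 8 centroids on a labelled log2 cohort restricted to a signature."""
    if matrix.scale != "log2":
        raise ClassifierError(f"fit_centroids expects log2-scale data, got {matrix.scale!r}")
    lab = labels.reindex(matrix.samples)
    if lab.isna().any():
        raise ClassifierError("labels missing for some matrix samples")
    for c in CLUSTERS:
        if (lab == c).sum() < 1:
            raise ClassifierError(f"cluster {c!r} absent from training labels")

    sig_genes = list(signature.genes if isinstance(signature, SignatureSet) else signature)
    present = [g for g in sig_genes if g in set(matrix.genes)]
    if not present:
        raise ClassifierError("no signature gene present in the training matrix")
    if len(present) < len(sig_genes):
        logger.warning("%d signature genes absent from training matrix (dropped)",
                       len(sig_genes) - len(present))
    X = matrix.data.loc[present].to_numpy(dtype=float)  # genes x samples

    train_mean = train_sd = None
    if zscore:
        train_mean = X.mean(axis=1)
        train_sd = X.std(axis=1, ddof=1)
        if (train_sd == 0).any():
            raise ClassifierError("zero-variance signature gene; cannot z-score")
        X = (X - train_mean[:, None]) / train_sd[:, None]

    main = np.vstack([X[:, (lab == c).to_numpy()].mean(axis=1) for c in CLUSTERS])
    alt = np.vstack([X[:, (lab != c).to_numpy()].mean(axis=1) for c in CLUSTERS])
    return CentroidModel(
        genes=tuple(present), clusters=CLUSTERS, main=main, alt=alt,
        zscore=zscore, train_mean=train_mean, train_sd=train_sd,
        meta={"n_training_samples": int(len(lab))},
    )


def assign(sample_vector: np.ndarray, model: CentroidModel) -> str:
    """Assign one expression vector (over the model's genes) to a cluster."""
    v = np.asarray(sample_vector, dtype=float)
    if v.shape != (len(model.genes),):
        raise ClassifierError(f"vector length {v.shape} != number of model genes {len(model.genes)}")
    if not np.isfinite(v).all():
        raise ClassifierError("non-finite values in sample vector")
    if model.zscore:
        v = (v - model.train_mean) / model.train_sd
    d_main = np.sqrt(((model.main - v) ** 2).sum(axis=1))
    d_alt = np.sqrt(((model.alt - v) ** 2).sum(axis=1))
    best = int(np.argmin(d_main))
    if (d_main == d_main[best]).sum() > 1:
        logger.warning("tied nearest main centroids; sample left unclassified")
        return UNCLASSIFIED
    return model.clusters[best] if d_main[best] < d_alt[best] else UNCLASSIFIED


@dataclass
class AssignmentResult:
    """Per-sample distances to all 8 centroids plus the assigned label."""

    table: pd.DataFrame  # index: sample; columns: assigned, d_main_*, d_alt_*

    @property
    def assigned(self) -> pd.Series:
        return self.table["assigned"]

    @property
    def counts(self) -> pd.Series:
        return self.table["assigned"].value_counts()

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def assign_cohort(matrix: ExpressionMatrix, model: CentroidModel) -> AssignmentResult:
    """Vectorised per-sample assignment of a cohort (genes may be a superset)."""
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ClassifierError("empty expression matrix")
    working = model.restrict(matrix.genes) if set(model.genes) - set(matrix.genes) else model
    X = matrix.data.loc[list(working.genes)].to_numpy(dtype=float).T  # samples x genes
    if not np.isfinite(X).all():
        raise ClassifierError("non-finite values in cohort matrix")
    if working.zscore:
        X = (X - working.train_mean) / working.train_sd
    d_main = cdist(X, working.main)  # samples x clusters
    d_alt = cdist(X, working.alt)
    best = d_main.argmin(axis=1)
    row = np.arange(len(X))
    unique = (d_main == d_main[row, best][:, None]).sum(axis=1) == 1
    ok = unique & (d_main[row, best] < d_alt[row, best])
    labels = np.where(ok, np.array(working.clusters, dtype=object)[best], UNCLASSIFIED)

    table = pd.DataFrame({"assigned": labels}, index=matrix.samples)
    for ci, c in enumerate(working.clusters):
        table[f"d_main_{c}"] = d_main[:, ci]
        table[f"d_alt_{c}"] = d_alt[:, ci]
    result = AssignmentResult(table=table)
    logger.info("assignment counts: %s", result.counts.to_dict())
    return result
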