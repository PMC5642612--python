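"""End-to-end orchestration of the subtyping analysis.

Stage order mirrors the study design: a labelled discovery cohort is
preprocessed and ranked per panel (one-vs-rest, 4 panels x 4 clusters =
16 tables, plus 4 on the combined panel); the top 20% of the main
panel's tables and the top 5% of the combined tables form the two gene
signatures; dual centroids fitted on the discovery cohort assign the
validation cohort; both cohorts are hierarchically clustered on the
combined signature; and both signatures are scored for category
overrepresentation.  Every output is written with a manifest recording
parameters and SHA-256 checksums, so two runs with the same config are
byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import centroids, cluster, enrichment, preprocess, ranking, simulate
from .panels import PanelRegistry, default_registry, load_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serialisable to/from YAML."""

    outdir: str = "immunosig_run"
    # input paths; None means "simulate from seed"
    expression1: str | None = None
    labels1: str | None = None
    expression2: str | None = None
    panel_paths: dict[str, str] = field(default_factory=dict)  # name -> file
    catalog: str | None = None       # GMT path; None -> synthetic catalog
    input_scale: str = "raw"         # scale of the expression TSVs
    # stage parameters
    pseudocount: float = 1.0
    q_panel: float = 0.20
    q_combined: float = 0.05
    main_panel: str = "nanostring"   # panel whose q_panel signature trains the classifier
    metric: str = "euclidean"
    linkage: str = "average"
    zscore_classifier: bool = False
    bonferroni_count: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _load_registry(config: PipelineConfig) -> PanelRegistry:
    if not config.panel_paths:
        return default_registry()
    reg = PanelRegistry()
    for name, path in config.panel_paths.items():
        reg.add(load_panel(path, name=name))
    return reg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(path: Path) -> Path:
        outputs.append(path)
        return path

    with _stage("panels"):
        registry = _load_registry(config)

    with _stage("input"):
        if config.expression1 is None:
            sim_cfg = simulate.SyntheticConfig(seed=config.seed)
            cohort1 = simulate.generate_cohort(sim_cfg, registry.combined, cohort_id=1)
            cohort2_cfg = dataclasses.replace(sim_cfg, cluster_sizes=(56, 56, 56, 57))
            cohort2 = simulate.generate_cohort(cohort2_cfg, registry.combined, cohort_id=2)
            mat1, labels1 = cohort1.matrix, cohort1.labels
            mat2 = cohort2.matrix
            cohort1.write(emit(outdir / "cohort1_log2.tsv"), emit(outdir / "cohort1_labels.tsv"))
            cohort2.write(emit(outdir / "cohort2_log2.tsv"), emit(outdir / "cohort2_labels.tsv"))
        else:
            if config.labels1 is None:
                raise FileNotFoundError("labels1 is required with expression1")
            for p in (config.expression1, config.labels1, config.expression2):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
            mat1 = preprocess.ExpressionMatrix.from_tsv(config.expression1, scale=config.input_scale)
            labels1 = preprocess.read_labels(config.labels1)
            mat2 = (
                preprocess.ExpressionMatrix.from_tsv(config.expression2, scale=config.input_scale)
                if config.expression2
                else None
            )
            if config.input_scale == "raw":
                mat1 = preprocess.log2_transform(mat1, config.pseudocount)
                mat2 = preprocess.log2_transform(mat2, config.pseudocount) if mat2 is not None else None

    with _stage("rank"):
        tables = ranking.build_ranking_tables(mat1, labels1, registry, include_combined=True)
        n_panels = len(registry)
        panel_tables = tables[: 4 * n_panels]
        combined_tables = tables[4 * n_panels :]
        for t in tables:
            t.to_tsv(emit(outdir / f"ranking_{t.panel}_{t.target_cluster}.tsv"))

    with _stage("select"):
        main_tables = [t for t in panel_tables if t.panel == config.main_panel]
        if not main_tables:
            raise PipelineError(f"main panel {config.main_panel!r} not in registry")
        sig_main = ranking.top_fraction_union(main_tables, config.q_panel)
        sig_combined = ranking.top_fraction_union(combined_tables, config.q_combined)
        sig_main.write(emit(outdir / f"signature_{config.main_panel}_q{config.q_panel:g}.txt"))
        sig_combined.write(emit(outdir / f"signature_combined_q{config.q_combined:g}.txt"))

    with _stage("fit"):
        model = centroids.fit_centroids(mat1, labels1, sig_main, zscore=config.zscore_classifier)
        model.save(emit(outdir / "centroid_model.tsv"), emit(outdir / "centroid_model.json"))

    with _stage("assign"):
        assignments = {"cohort1": centroids.assign_cohort(mat1, model)}
        if mat2 is not None:
            assignments["cohort2"] = centroids.assign_cohort(mat2, model)
        for name, res in assignments.items():
            res.write(emit(outdir / f"assignments_{name}.tsv"))

    with _stage("cluster"):
        cluster_out = {}
        for name, mat in (("cohort1", mat1), ("cohort2", mat2)):
            if mat is None:
                continue
            sub, _ = preprocess.subset_to_panel(mat, _as_panel(sig_combined))
            z = preprocess.zscore_rows(sub)
            tree = cluster.hierarchical_cluster(z, axis="samples",
                                                metric=config.metric, linkage=config.linkage)
            cut = cluster.cut_to_k(tree, 4)
            cut.to_csv(emit(outdir / f"cut4_{name}.tsv"), sep="\t")
            emit(outdir / f"tree_{name}.nwk").write_text(tree.to_newick() + "\n")
            cluster_out[name] = tree

    with _stage("enrich"):
        if config.catalog:
            catalog = enrichment.read_gmt(config.catalog)
        else:
            catalog = simulate.generate_annotation(
                n_categories=20,
                category_sizes=[50] * 20,
                reference_size=20972,
                enriched_category="CAT01",
                overlap_with=list(sig_combined)[:20],
                overlap_size=10,
                seed=config.seed,
            )
        for name, sig in (("main", sig_main), ("combined", sig_combined)):
            rows = enrichment.run_overrepresentation(
                list(sig), catalog, bonferroni_count=config.bonferroni_count
            )
            enrichment.write_enrichment_tsv(rows, emit(outdir / f"enrichment_{name}.tsv"))

    with _stage("manifest"):
        manifest = {
            "parameters": dataclasses.asdict(config),
            "counts": {
                "ranking_tables": len(tables),
                "ranking_tables_per_panel": 4,
                "signatures": 2,
                "models": 1,
                "centroid_vectors": model.n_centroids,
                "assignment_tables": len(assignments),
                "enrichment_tables": 2,
            },
            "signature_sizes": {"main": len(sig_main), "combined": len(sig_combined)},
            "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest


def _as_panel(signature: ranking.SignatureSet):
    from .panels import GenePanel

    return GenePanel(name="signature", genes=tuple(signature.genes), source="signature")
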