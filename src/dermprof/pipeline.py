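"""End-to-end pipeline: simulate/ingest -> QC -> integrate -> configuration
grid -> DEG intersection -> robustness ANOVA + clustering -> ranking and
cross-validated classification.

Driven by a single :class:`PipelineConfig`; every stage persists TSV/JSON
artifacts under the output directory and the run closes with a manifest
recording seeds, per-stage outputs and content checksums, so identical
(config, seed) runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from dermprof import __version__
from dermprof.batchfx import BATCH_METHODS
from dermprof.degsel import run_configuration_grid, select_final_degs
from dermprof.qc import apply_qc, qc_screen
from dermprof.rankclass import incremental_curves, mrmr_rank
from dermprof.robust import anova_main_effects, ls_deviation_table, ward_cluster
from dermprof.synthio import (
    StudyConfig,
    generate_study,
    read_series_bundle,
    write_series_bundle,
)

logger = logging.getLogger("dermprof")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    study: StudyConfig | None = None  # synthetic study; None -> read bundles
    bundle_dirs: list[str] = field(default_factory=list)
    qc_d_threshold: float = 0.15
    qc_max_rounds: int = 10
    qc_flag_rule: str = "majority"
    methods: tuple[str, ...] = BATCH_METHODS
    unions: tuple[str, ...] = ("mean", "median")
    lfc_min: float = 4.0
    p_max: float = 0.001
    p_type: str = "raw"
    anova_factors: tuple[str, ...] = ("TYPE", "BATCH", "METHOD", "COUNTRY")
    reference_config: tuple[str, str] = ("MRS", "mean")
    samples_per_class_cluster: int = 5
    mi_k: int = 3
    cv_schemes: tuple[str, ...] = ("loo", "kfold")
    kfold: int = 10

    def validate(self) -> None:
        if not self.out_dir:
            raise ValueError("output directory is required")
        if self.lfc_min <= 0 or self.p_max <= 0:
            raise ValueError("thresholds must be positive")
        unknown = set(self.methods) - set(BATCH_METHODS)
        if unknown:
            raise ValueError(f"unknown batch methods: {sorted(unknown)}")
        if self.study is None and not self.bundle_dirs:
            raise ValueError("either a study config or bundle directories required")
        for d in self.bundle_dirs:
            if not Path(d).exists():
                raise ValueError(f"bundle directory does not exist: {d}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = raw.pop("study", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if study is not None:
            allowed = {f.name for f in dataclasses.fields(StudyConfig)}
            study = {k: v for k, v in study.items() if k in allowed}
            for key in ("classes_per_series", "samples_per_class_per_series", "probes_per_gene"):
                if key in study:
                    study[key] = tuple(study[key])
            cfg.study = StudyConfig(**study)
        for key in ("methods", "unions", "cv_schemes", "anova_factors", "reference_config"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.strftime("%Y-%m-%dT%H:%M:%S")}
        return name

    def record(name: str, **info) -> None:
        manifest["stages"][name].update(info)

    # --- simulate / ingest ------------------------------------------------
    name = stage("ingest")
    try:
        if config.study is not None:
            study = dataclasses.replace(config.study, seed=config.seed)
            bundles, truth = generate_study(study)
            bdir = out / "bundles"
            for b in bundles:
                write_series_bundle(b, bdir / b.series_id)
            truth.to_json(out / "ground_truth.json")
            record(name, mode="synthetic", n_series=len(bundles))
        else:
            bundles = [read_series_bundle(d) for d in config.bundle_dirs]
            truth = None
            record(name, mode="bundles", n_series=len(bundles))
    except Exception as exc:
        raise PipelineError(name, exc)

    # --- qc ---------------------------------------------------------------
    name = stage("qc")
    try:
        reports = []
        cleaned = []
        for b in bundles:
            rep = qc_screen(
                b,
                d_threshold=config.qc_d_threshold,
                max_rounds=config.qc_max_rounds,
                flag_rule=config.qc_flag_rule,
            )
            reports.append(rep)
            cleaned.append(apply_qc(b, rep))
        (out / "qc_report.json").write_text(
            json.dumps([json.loads(r.to_json()) for r in reports], indent=2)
        )
        record(
            name,
            removed=sum(len(r.removed_samples) for r in reports),
            initial=sum(len(b.samples) for b in bundles),
            retained=sum(len(b.samples) for b in cleaned),
        )
        bundles = cleaned
    except Exception as exc:
        raise PipelineError(name, exc)

    # --- integrate + grid + final DEGs -------------------------------------
    name = stage("grid")
    try:
        grid = run_configuration_grid(
            bundles,
            methods=config.methods,
            unions=config.unions,
            lfc_min=config.lfc_min,
            p_max=config.p_max,
            p_type=config.p_type,
        )
        counts = grid.count_table()
        counts.index.name = "batch_method"
        counts.to_csv(out / "grid_deg_counts.tsv", sep="\t")
        record(
            name,
            n_cells=len(grid.cells),
            errors={f"{m}/{u}": c.error for (m, u), c in grid.cells.items() if c.error},
        )
    except Exception as exc:
        raise PipelineError(name, exc)

    name = stage("deg")
    try:
        selection = select_final_degs(
            grid,
            reference=tuple(config.reference_config),
            lfc_min=config.lfc_min,
            p_max=config.p_max,
            p_type=config.p_type,
        )
        (out / "deg_sets.json").write_text(
            json.dumps(
                {
                    "per_config": {k: sorted(v) for k, v in selection.per_config_sets.items()},
                    "contributing": selection.contributing,
                    "intersection": sorted(selection.intersection),
                    "status": selection.status,
                },
                indent=2,
            )
        )
        if selection.summary is not None:
            selection.summary.to_csv(out / "final_degs.tsv", sep="\t", index=False)
        record(
            name,
            n_final=len(selection.intersection),
            contributing=selection.contributing,
            status=selection.status,
        )
    except Exception as exc:
        raise PipelineError(name, exc)

    final_genes = sorted(selection.intersection)
    ref = tuple(config.reference_config)
    ref_cell = grid.cells.get(ref)
    if ref_cell is None or ref_cell.merged is None:
        usable = [c for c in grid.cells.values() if c.merged is not None and c.deg_set]
        ref_cell = usable[0] if usable else None

    # --- robustness: LS-deviation ANOVA + Ward clustering -------------------
    name = stage("anova")
    anova = None
    try:
        if final_genes and ref_cell is not None:
            variants = [
                (c.batch_method, c.union_method, c.merged.expression.loc[final_genes])
                for c in grid.cells.values()
                if c.error is None and c.merged is not None and c.deg_set
            ]
            obs = ls_deviation_table(variants, ref_cell.merged.samples)
            factors = [f for f in config.anova_factors if obs[f].nunique() >= 2]
            if len(factors) >= 1:
                anova = anova_main_effects(obs, factors)
                anova.to_tsv(out / "anova.tsv")
                record(name, factors=factors, n_observations=len(obs))
            else:
                record(name, skipped="no factor with >= 2 levels")
        else:
            record(name, skipped="no final DEGs")
    except Exception as exc:
        raise PipelineError(name, exc)

    name = stage("cluster")
    try:
        if final_genes and ref_cell is not None:
            sub = ref_cell.merged.expression.loc[final_genes]
            classes = {a.sample_id: a.class_label for a in ref_cell.merged.samples}
            clustering = ward_cluster(
                sub, classes, samples_per_class=config.samples_per_class_cluster
            )
            (out / "dendrogram.nwk").write_text(clustering.to_newick() + "\n")
            pd.DataFrame(
                {
                    "order": range(1, len(clustering.leaf_order) + 1),
                    "sample_id": clustering.leaf_order,
                    "class_label": [classes[s] for s in clustering.leaf_order],
                }
            ).to_csv(out / "cluster_order.tsv", sep="\t", index=False)
            record(name, n_leaves=len(clustering.leaf_order))
        else:
            record(name, skipped="no final DEGs")
    except Exception as exc:
        raise PipelineError(name, exc)

    # --- ranking + classification -------------------------------------------
    name = stage("classify")
    try:
        if final_genes and ref_cell is not None:
            expr = ref_cell.merged.expression.loc[final_genes]
            labels = ref_cell.merged.class_labels()
            ranking = mrmr_rank(expr, labels, k_mi=config.mi_k, jitter_seed=config.seed)
            ranking.steps.to_csv(out / "mrmr_ranking.tsv", sep="\t", index=False)
            report = incremental_curves(
                expr,
                labels,
                ranking,
                schemes=config.cv_schemes,
                n_folds=config.kfold,
                seed=20180511,  # fixed fold seed; study seed drives the data
            )
            report.to_json(out / "cv_report.json")
            report.curve_table().to_csv(out / "cv_curves.tsv", sep="\t", index=False)
            full = report.curve_table()
            best = full["accuracy_7class"].max() if len(full) else float("nan")
            record(name, ranking=ranking.order, best_accuracy_7class=best)
        else:
            record(name, skipped="no final DEGs")
    except Exception as exc:
        raise PipelineError(name, exc)

    # --- manifest -----------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
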