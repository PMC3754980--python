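"""End-to-end pipeline: filter -> dual-scale FDR -> intersect -> correlate ->
annotate -> OPLS/LDA panel, with a reproducible run manifest.

Every stage writes its artifact to the output directory through a
``.partial`` temp name that is renamed on success, so an aborted run never
leaves a truncated file masquerading as a finished one.  The manifest
records the package version, the full effective configuration, the seed,
per-stage row counts and a SHA-256 of every artifact; two runs with the
same config and seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    ADDUCTS_BY_NAME,
    AnnotationConfig,
    annotate_cluster,
)
from .cohort_stats import cohort_balance_table
from .containers import FeatureTable, ValidationError
from .correlation import (
    CorrelationConfig,
    build_clusters,
    cluster_report,
    correlation_matrix,
    edge_list,
)
from .mwas import MwasConfig, manhattan_export, presence_filter, run_mwas
from .panel import PanelConfig, run_panel
from .synthetic_cohort import SimulationConfig, simulate_dataset
from .tabular_io import (
    read_feature_table,
    read_metabolite_db,
    read_samples,
    write_feature_table,
    write_samples,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Nested stage configs plus input paths and the global seed."""

    feature_table: Optional[str] = None
    samples: Optional[str] = None
    db: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    mwas: MwasConfig = field(default_factory=MwasConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    seed: int = 0
    annotate: bool = True
    run_panel: bool = True

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim = dict(kwargs["simulation"])
            if "mz_range" in sim:
                sim["mz_range"] = tuple(sim["mz_range"])
            kwargs["simulation"] = SimulationConfig(**sim)
        for key, klass in (
            ("mwas", MwasConfig),
            ("correlation", CorrelationConfig),
            ("panel", PanelConfig),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**dict(kwargs[key]))
        if "annotation" in kwargs and kwargs["annotation"] is not None:
            a = dict(kwargs["annotation"])
            if "adducts" in a:
                a["adducts"] = tuple(ADDUCTS_BY_NAME[n] for n in a["adducts"])
            if "mz_range" in a:
                a["mz_range"] = tuple(a["mz_range"])
            kwargs["annotation"] = AnnotationConfig(**a)
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("annotation"):
            d["annotation"]["adducts"] = [
                a["name"] for a in d["annotation"]["adducts"]
            ]
        return d


def _write(df: pd.DataFrame, path: Path, index_label: Optional[str] = None) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    if index_label is not None:
        df.rename_axis(index_label).reset_index().to_csv(tmp, sep="\t", index=False)
    else:
        df.to_csv(tmp, sep="\t", index=False)
    tmp.rename(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> Path:
    """Run every configured stage and write artifacts plus manifest.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    artifacts: list[Path] = []

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        db = None
        if config.db:
            db = read_metabolite_db(config.db)
        if config.simulation is not None:
            if db is None:
                raise ValidationError("simulation requires a metabolite db path")
            sim_cfg = config.simulation
            table, samples, truth = simulate_dataset(sim_cfg, db)
            write_feature_table(table, out / "feature_table.tsv")
            write_samples(samples, out / "samples.tsv")
            truth_path = out / "truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "chemical_features": truth.chemical_features,
                        "chemical_effects": truth.chemical_effects,
                        "feature_truth": truth.feature_truth,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            artifacts += [out / "feature_table.tsv", out / "samples.tsv", truth_path]
        else:
            if not config.feature_table or not config.samples:
                raise ValidationError(
                    "need feature_table and samples paths (or a simulation block)"
                )
            table = read_feature_table(config.feature_table)
            samples = read_samples(config.samples)
        if config.annotate and db is None:
            raise ValidationError("annotation enabled but no db path configured")
        counts["total_features"] = table.n_features
        counts["samples"] = table.n_samples
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, exc) from exc

    # ---- cohort balance --------------------------------------------------
    stage = "cohort"
    try:
        covars = [c for c in samples.columns if c != "group"]
        if covars:
            balance = cohort_balance_table(samples)
            _write(balance, out / "balance_table.tsv")
            artifacts.append(out / "balance_table.tsv")
            counts["cohort_covariates"] = len(balance)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- univariate screen ----------------------------------------------
    stage = "mwas"
    try:
        filtered = presence_filter(table, config.mwas.presence_threshold)
        counts["filtered_features"] = filtered.n_features
        result = run_mwas(filtered, samples, config.mwas)
        _write(result.table, out / "mwas_results.tsv", index_label="feature_id")
        _write(manhattan_export(result), out / "manhattan.tsv", index_label="feature_id")
        artifacts += [out / "mwas_results.tsv", out / "manhattan.tsv"]
        counts["significant_raw"] = len(result.significant_raw)
        counts["significant_log2"] = len(result.significant_log2)
        counts["intersection"] = len(result.intersection)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- correlation clustering -----------------------------------------
    stage = "cluster"
    try:
        matrix = correlation_matrix(filtered, config.correlation)
        clusters, independents = build_clusters(
            result.intersection, matrix, filtered, config.correlation
        )
        report_df = cluster_report(clusters, independents, filtered.mz)
        _write(report_df, out / "clusters.tsv")
        _write(
            edge_list(matrix, config.correlation.r_threshold),
            out / "correlation_edges.tsv",
        )
        artifacts += [out / "clusters.tsv", out / "correlation_edges.tsv"]
        counts["clusters"] = len(clusters)
        counts["independent_seeds"] = len(independents)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- annotation ------------------------------------------------------
    stage = "annotate"
    try:
        if config.annotate:
            rows = []
            for cl in clusters + independents:
                ca = annotate_cluster(cl, filtered.mz, db, config.annotation)
                for fid, hits in ca.hits.items():
                    if not hits:
                        rows.append(
                            {
                                "cluster": cl.cluster_id,
                                "feature_id": fid,
                                "mz": float(filtered.mz[fid]),
                                "record_id": "No Match",
                                "adduct": "",
                                "theoretical_mz": np.nan,
                                "ppm_error": np.nan,
                            }
                        )
                    for h in hits:
                        rows.append(
                            {
                                "cluster": cl.cluster_id,
                                "feature_id": fid,
                                "mz": float(filtered.mz[fid]),
                                "record_id": h.record_id,
                                "adduct": h.adduct,
                                "theoretical_mz": h.theoretical_mz,
                                "ppm_error": h.ppm_error,
                            }
                        )
            ann_df = pd.DataFrame(
                rows,
                columns=[
                    "cluster",
                    "feature_id",
                    "mz",
                    "record_id",
                    "adduct",
                    "theoretical_mz",
                    "ppm_error",
                ],
            )
            _write(ann_df, out / "annotations.tsv")
            artifacts.append(out / "annotations.tsv")
            counts["annotation_rows"] = len(ann_df)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- multivariate panel ---------------------------------------------
    stage = "panel"
    try:
        if config.run_panel:
            rep = run_panel(filtered, samples, config.panel)
            panel_payload = {
                "selected_features": rep.selected_features,
                "variance_explained_orthogonal": rep.variance_explained_orth,
                "variance_explained_predictive": rep.variance_explained_pred,
                "resubstitution_accuracy": rep.resubstitution_accuracy,
                "cv_accuracy": rep.cv_accuracy,
            }
            (out / "panel.json").write_text(json.dumps(panel_payload, indent=1))
            _write(rep.scores, out / "scores.tsv", index_label="sample_id")
            artifacts += [out / "panel.json", out / "scores.tsv"]
            counts["panel_features"] = len(rep.selected_features)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- manifest --------------------------------------------------------
    manifest = {
        "software": "mzmwas",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": counts,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def report(outdir: Union[str, Path]) -> str:
    """Human-readable summary of a finished pipeline run."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    counts = manifest["counts"]
    lines = [
        "# MWAS pipeline summary",
        "",
        f"samples: {counts.get('samples', '?')}",
        "feature cascade: "
        f"total {counts.get('total_features', '?')} >= "
        f"filtered {counts.get('filtered_features', '?')} >= "
        f"significant (raw) {counts.get('significant_raw', '?')} >= "
        f"intersection {counts.get('intersection', '?')}",
        f"significant (log2): {counts.get('significant_log2', '?')}",
        "",
    ]
    if counts.get("significant_raw", 0) == 0:
        lines.append("no discriminatory features at the configured FDR levels")
        lines.append("")
    clusters_path = out / "clusters.tsv"
    if clusters_path.exists():
        lines.append("## Ion clusters (cluster | m/z | correlated features)")
        lines.append(clusters_path.read_text().rstrip("\n") or "(empty)")
        lines.append("")
    ann_path = out / "annotations.tsv"
    if ann_path.exists():
        df = pd.read_csv(ann_path, sep="\t")
        lines.append("## Annotations")
        if df.empty:
            lines.append("(no annotated features)")
        else:
            top = df.groupby("feature_id", sort=True).head(1)
            for _, r in top.iterrows():
                lines.append(
                    f"- {r['mz']:.3f} [{r['cluster']}]: {r['record_id']}"
                    + (
                        f" via {r['adduct']} ({r['ppm_error']:+.1f} ppm)"
                        if isinstance(r["adduct"], str) and r["adduct"]
                        else ""
                    )
                )
        lines.append("")
    panel_path = out / "panel.json"
    if panel_path.exists():
        panel = json.loads(panel_path.read_text())
        lines.append("## Panel")
        lines.append(f"selected features: {len(panel['selected_features'])}")
        lines.append(
            "variance explained (orth | pred): "
            f"{['%.3f' % v for v in panel['variance_explained_orthogonal']]} | "
            f"{['%.3f' % v for v in panel['variance_explained_predictive']]}"
        )
        lines.append(
            f"resubstitution accuracy: {panel['resubstitution_accuracy']:.3f}"
        )
        for scheme, acc in panel["cv_accuracy"].items():
            lines.append(f"{scheme} accuracy: {acc:.3f}")
        lines.append("")
    return "\n".join(lines)
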