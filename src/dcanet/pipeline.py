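"""End-to-end pipeline driver: inputs -> every serialized artifact.

Runs io -> embedding -> trimers -> clustering -> network -> link
prediction -> evaluation in order, writing each stage's output and a
manifest (config echo, seed, version, per-stage record counts) that
suffices to re-run the pipeline identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .evaluation import CVConfig
from .io import write_edge_list, write_report, write_score_matrix
from .linkpred import SignificanceThresholds
from .model import DCAModel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("dcanet")


@dataclasses.dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults mirror the reference protocol.

    ``k="auto"`` uses the number of distinct drugs as the cluster count;
    ``significant_cutoff="auto"`` uses the fold-resampling standard-error
    estimate.
    """

    property_table: str | None = None
    complex_table: str | None = None
    out_dir: str = "dca_out"
    k: int | str = "auto"
    n_components: int = 5
    linkage: str = "average"
    method: str = "CN"
    significant_cutoff: float | str = "auto"
    important_fraction: float = 0.2
    n_folds: int = 10
    negatives_per_positive: float = 1.0
    benchmark_repetitions: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` text config."""
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ValueError(f"unknown config key {key!r}")
            field = {f.name: f for f in dataclasses.fields(cls)}[key]
            if raw == "auto" or field.type in ("str", "str | None"):
                values[key] = raw
            elif field.type == "int":
                values[key] = int(raw)
            elif field.type == "float":
                values[key] = float(raw)
            else:
                try:
                    values[key] = int(raw)
                except ValueError:
                    try:
                        values[key] = float(raw)
                    except ValueError:
                        values[key] = raw
        return cls(**values)


def _stage(name: str, counts: dict, manifest: dict) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))
    manifest["stages"][name] = counts


def run_pipeline(config: PipelineConfig, model: DCAModel | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``model`` may be passed directly (e.g. a synthetic preset); otherwise
    it is built from the configured input paths.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "version": __version__,
        "stages": {},
    }
    try:
        if model is None:
            if not (config.property_table and config.complex_table):
                raise ValueError("property_table and complex_table paths required")
            model = DCAModel.from_files(
                config.property_table,
                config.complex_table,
                n_components=config.n_components,
                k=config.k,
                linkage=config.linkage,
            )
        _stage("io", {"complexes": len(model.complexes),
                      "properties": model.property_table.n_properties}, manifest)

        res = model.fit()
        res.embedding.to_json(out / "embedding.json")
        _stage("embedding", {"components": res.embedding.n_components,
                             "kept_columns": len(res.embedding.kept_columns)}, manifest)

        trimer_df = res.trimer_table()
        trimer_df.to_csv(out / "trimers.tsv", sep="\t", index=False)
        _stage("trimers", {"occurrences": len(trimer_df),
                           "distinct": len(res.trimer_vectors),
                           "skipped_complexes": res.skipped_complexes}, manifest)

        res.clustering.to_tsv(out / "clusters.tsv", out / "centroids.tsv")
        _stage("clustering", {"k": res.clustering.k}, manifest)

        res.network.edge_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            res.network.adjacency,
            index=list(res.network.drugs),
            columns=[str(c) for c in res.network.clusters],
        ).to_csv(out / "adjacency.tsv", sep="\t")
        ev_rows = [
            {"drug_id": d, "cluster_index": c, "protein_id": p,
             "complex_id": cx, "trimer_key": t}
            for (d, c), evs in sorted(res.network.evidence.items())
            for p, cx, t in evs
        ]
        write_edge_list(ev_rows, out / "evidence.tsv")
        _stage("network", {"drugs": res.network.n_drugs,
                           "clusters": res.network.n_clusters,
                           "edges": res.network.n_edges}, manifest)

        thresholds = None
        if config.significant_cutoff != "auto":
            thresholds = SignificanceThresholds(
                significant_cutoff=float(config.significant_cutoff),
                important_fraction=config.important_fraction,
            )
        pred = res.predict(config.method, thresholds, cv_seed=config.seed)
        write_score_matrix(pred["matrix"], out / f"scores_{config.method}.tsv")
        write_edge_list(
            [{"drug_id": d, "cluster_index": c, "score": s}
             for d, c, s in pred["significant"]],
            out / "significant.tsv",
            columns=["drug_id", "cluster_index", "score"],
        )
        write_edge_list(
            [{"drug_id": d, "cluster_index": c, "score": s}
             for d, c, s in pred["important"]],
            out / "important.tsv",
            columns=["drug_id", "cluster_index", "score"],
        )
        write_edge_list(pred["drug_trimer"], out / "drug_trimer_predictions.tsv",
                        columns=["drug_id", "trimer_key", "cluster_index", "score", "novel"])
        write_edge_list(pred["drug_protein"], out / "drug_protein_predictions.tsv",
                        columns=["drug_id", "protein_id", "via_cluster", "score", "novel"])
        _stage("link_prediction", {
            "method": config.method,
            "significant_cutoff": float(pred["thresholds"].significant_cutoff),
            **pred["counts"],
            "drug_trimer_candidates": len(pred["drug_trimer"]),
            "drug_protein_candidates": len(pred["drug_protein"]),
        }, manifest)

        cv = CVConfig(
            n_folds=config.n_folds,
            negatives_per_positive=config.negatives_per_positive,
            repetitions=config.benchmark_repetitions,
            seed=config.seed,
        )
        report = res.evaluate(config.method, cv, benchmark=True)
        write_report(report, out / "report.json")
        _stage("evaluation", {
            "mean_auc": round(report.mean_auc, 6),
            "mean_aupr": round(report.mean_aupr, 6),
            "baseline_auc": round(report.baseline_auc, 6),
        }, manifest)
    except Exception as exc:
        manifest["error"] = {"last_completed_stage": _last_stage(manifest),
                             "cause": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out


def _last_stage(manifest: dict) -> str:
    stages = list(manifest["stages"])
    return stages[-1] if stages else "io"
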