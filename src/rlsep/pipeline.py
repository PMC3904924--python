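"""End-to-end runs: preprocess -> partition -> RLS per feature space ->
optimal-subspace selection -> report files, with a JSON run manifest that
captures every configuration value actually used."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import CplSpec, LabeledDataset, read_cohort
from .diagmap import map_frame, project
from .evaluate import feature_outcome_correlations
from .pathsearch import LambdaSchedule, RlsPath, rank_features, run_rls, select_optimal_subspace
from .preprocess import Standardizer, impute_nearest_neighbour, partition_spaces
from .synthetic import SynthConfig, generate_cohort

__all__ = ["run_pipeline", "load_config", "synth_to_files"]

DEFAULTS = {
    "spaces": ["phenotypic", "genetic", "combined"],
    "schedule": {},          # LambdaSchedule kwargs
    "standardize": True,
    "impute": True,
    "knn_k": 5,
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    merged = {**DEFAULTS, **cfg}
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _path_csv(path: RlsPath, out: Path) -> None:
    path.as_frame().to_csv(out, index=False, float_format="%.10g")


def synth_to_files(config: SynthConfig, outdir: str | Path) -> dict:
    """Generate a synthetic cohort and write cohort CSV + metadata sidecar
    + ground-truth JSON; returns the written file paths."""
    from .datamodel import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_cohort(config)
    table = outdir / "cohort.csv"
    meta = outdir / "cohort.meta.yaml"
    write_cohort(dataset, table, meta)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2))
    return {"table": str(table), "metadata": str(meta), "truth": str(truth_path)}


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the full analysis described by ``config`` and write reports.

    Config keys: ``table``/``metadata`` (cohort files) or ``synth`` (a
    SynthConfig mapping), ``spaces`` (subset of phenotypic/genetic/combined),
    ``schedule`` (lambda grid settings), ``standardize``, ``impute``,
    ``knn_k``. Returns the manifest dict (also written as manifest.json).
    """
    cfg = {**DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(cfg),
        "inputs": {},
        "timings": {},
        "spaces": {},
    }

    # --- load ------------------------------------------------------------
    if "synth" in cfg:
        synth_cfg = SynthConfig(**cfg["synth"])
        dataset, truth = generate_cohort(synth_cfg)
        manifest["inputs"]["synth"] = asdict(synth_cfg)
        manifest["inputs"]["ground_truth"] = _jsonable(asdict(truth))
    else:
        table, meta = Path(cfg["table"]), Path(cfg["metadata"])
        dataset = read_cohort(table, meta)
        manifest["inputs"] = {
            "table": str(table), "table_sha256": _sha256(table),
            "metadata": str(meta), "metadata_sha256": _sha256(meta),
        }

    # --- preprocess --------------------------------------------------------
    t0 = time.time()
    if cfg["impute"] and not dataset.is_complete:
        dataset = impute_nearest_neighbour(dataset)
    scaler = None
    if cfg["standardize"]:
        scaler = Standardizer().fit(dataset)
        dataset = scaler.transform(dataset)
        manifest["standardizer"] = {
            "mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist(),
        }
    manifest["timings"]["preprocess_s"] = round(time.time() - t0, 3)

    partition = partition_spaces(dataset)
    schedule = LambdaSchedule(**cfg["schedule"])
    spec = CplSpec()

    for space in cfg["spaces"]:
        if space not in partition.available():
            raise ValueError(f"requested space {space!r} is empty for this cohort")
        ds = partition[space]
        t0 = time.time()
        path = run_rls(ds, spec, schedule)
        best = select_optimal_subspace(path)
        manifest["timings"][f"rls_{space}_s"] = round(time.time() - t0, 3)

        _path_csv(path, outdir / f"path_{space}.csv")
        ranking = rank_features(best.classifier, ds.feature_names)
        if ds.crp is not None:
            corr = feature_outcome_correlations(ds)
            ranking = ranking.merge(corr[["feature", "r", "p_value"]],
                                    on="feature", how="left")
        ranking.to_csv(outdir / f"ranking_{space}.csv", index=False,
                       float_format="%.10g")

        chosen = {
            "space": space,
            "dimension": best.dimension,
            "lambda": best.lam,
            "AE": best.apparent_error,
            "CVE": best.cve,
            "separable": best.separable,
            "features": [ds.feature_names[i] for i in best.subspace.indices],
            "weights": best.classifier.weights.tolist(),
            "threshold": best.classifier.threshold,
            "confusion": (None if best.confusion is None else
                          asdict(best.confusion)),
        }
        (outdir / f"chosen_{space}.json").write_text(json.dumps(chosen, indent=2))
        manifest["spaces"][space] = {k: chosen[k] for k in
                                     ("dimension", "lambda", "AE", "CVE", "separable")}

        if space == "combined":
            pts = project(best.classifier, ds)
            map_frame(pts, best.classifier.threshold).to_csv(
                outdir / "map_combined.csv", index=False, float_format="%.10g")

    manifest["timings"]["total_s"] = round(time.time() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
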