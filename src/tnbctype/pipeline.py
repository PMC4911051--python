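"""End-to-end orchestration: simulate/ingest -> receptor calls ->
subtype -> refine -> clinical report, with a versioned JSON manifest.

Configuration is a flat YAML mapping with a single ``seed``; per-stage
seeds are derived by fixed offsets so a run is reproducible without
seed bookkeeping.  Stage order is fixed and a failure in any stage
halts the run with a stage-named error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import tnbctype
from tnbctype.centroid_subtyping import CentroidSet, results_to_frame, subtype_samples
from tnbctype.io_formats import (read_clinical, read_expression,
                                 read_til_table, write_expression)
from tnbctype.receptor_mixture import (MARKERS, calls_to_frame,
                                       call_receptor_status,
                                       fit_marker_mixtures, identify_tnbc)
from tnbctype.clinical_stats import subtype_outcome_report
from tnbctype.til_immune import im_til_association
from tnbctype.synthetic_data import CohortConfig, generate_cohort

log = logging.getLogger("tnbctype.pipeline")

__all__ = ["ConfigError", "MissingInputError", "StageError",
           "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Configuration violates the documented schema (CLI exit code 2)."""


class MissingInputError(FileNotFoundError):
    """A referenced input file does not exist (CLI exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_SCHEMA: dict[str, type | tuple] = {
    "seed": int,
    "out": str,
    "simulate": bool,
    "n_samples": int,
    "n_genes": int,
    "tnbc_fraction": (int, float),
    "signal_sd": (int, float),
    "noise_sd": (int, float),
    "expression": str,
    "centroids": str,
    "clinical": str,
    "til": str,
    "posterior_threshold": (int, float),
    "uns_threshold": (int, float),
    "min_overlap": (int, float),
    "correlation_method": str,
    "fc_cut": (int, float),
    "q_cut": (int, float),
    "ci_method": str,
}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "posterior_threshold": 0.5,
    "uns_threshold": 0.1,
    "min_overlap": 0.5,
    "correlation_method": "spearman",
    "fc_cut": 2.0,
    "q_cut": 0.01,
    "ci_method": "wilson",
}


def load_config(path: str | Path) -> dict:
    """Load and validate the flat YAML config."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config: top level must be a mapping")
    cfg = dict(_DEFAULTS)
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"config: unknown field {key!r}")
        expected = _SCHEMA[key]
        if isinstance(value, bool) and expected is int:
            raise ConfigError(f"config: field {key!r} must be an integer")
        if not isinstance(value, expected):
            raise ConfigError(
                f"config: field {key!r} must be {expected}, got {type(value).__name__}")
        cfg[key] = value
    if not cfg.get("simulate") and "expression" not in cfg:
        raise ConfigError("config: either simulate: true or an expression path")
    if not cfg.get("simulate") and "centroids" not in cfg:
        raise ConfigError("config: centroids path required when not simulating")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None
                 ) -> Path:
    """Execute the full analysis; returns the output directory.

    Stages: (1) simulate or ingest inputs, (2) per-marker mixture fits
    and receptor calls, (3) centroid subtyping with four-way refinement
    on the TNBC samples, (4) subtype-stratified clinical report and TIL
    association when clinical/TIL tables are available, (5) manifest.
    """
    cfg = load_config(config) if not isinstance(config, dict) else \
        {**_DEFAULTS, **config}
    out = Path(out_dir or cfg.get("out", "tnbc_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "package_version": tnbctype.__version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "input_hashes": {},
    }

    def _stage(name):
        t0 = time.time()
        log.info("stage %s: start (seed %d)", name, seed)

        def done(rows: int):
            manifest["stages"][name] = {
                "rows": rows, "seconds": round(time.time() - t0, 3)}
            log.info("stage %s: done (%d rows)", name, rows)
        return done

    try:
        done = _stage("inputs")
        clinical = til = None
        if cfg.get("simulate", True):
            sim_kwargs = {k: cfg[k] for k in
                          ("n_samples", "n_genes", "tnbc_fraction",
                           "signal_sd", "noise_sd") if k in cfg}
            sim = generate_cohort(CohortConfig(seed=seed, **sim_kwargs))
            expr = sim["expression"]
            centroids = sim["centroids"]
            clinical = sim["clinical"]
            til = sim["til"]
            write_expression(expr, out / "expression.tsv")
            centroids.to_tsv(out / "centroids.tsv")
            sim["truth"].to_csv(out / "truth.csv", index=False)
            clinical.to_csv(out / "clinical.csv", index=False)
            til.to_csv(out / "til.csv", index=False)
        else:
            for key in ("expression", "centroids", "clinical", "til"):
                if key in cfg and not Path(cfg[key]).exists():
                    raise MissingInputError(f"{key} file not found: {cfg[key]}")
                if key in cfg:
                    manifest["input_hashes"][key] = _sha256(Path(cfg[key]))
            expr = read_expression(cfg["expression"])
            centroids = CentroidSet.from_tsv(cfg["centroids"])
            if "clinical" in cfg:
                clinical = read_clinical(cfg["clinical"])
            if "til" in cfg:
                til = read_til_table(cfg["til"])
        done(len(expr.sample_ids))
    except (ConfigError, MissingInputError):
        raise
    except Exception as exc:
        raise StageError(f"stage inputs failed: {exc}") from exc

    try:
        done = _stage("receptors")
        fits = fit_marker_mixtures(expr, MARKERS, seed=seed + 1)
        calls = call_receptor_status(expr, fits,
                                     threshold=cfg["posterior_threshold"])
        tnbc_ids = identify_tnbc(calls)
        frame = calls_to_frame(calls)
        frame.to_csv(out / "receptor_calls.csv", index=False)
        done(len(frame))
    except Exception as exc:
        raise StageError(f"stage receptors failed: {exc}") from exc

    try:
        done = _stage("subtype")
        if not tnbc_ids:
            raise RuntimeError("no TNBC samples identified")
        sub = expr.subset_samples(tnbc_ids)
        results = subtype_samples(sub, centroids,
                                  method=cfg["correlation_method"],
                                  uns_threshold=cfg["uns_threshold"],
                                  min_overlap=cfg["min_overlap"])
        sframe = results_to_frame(results)
        sframe.to_csv(out / "subtypes.csv", index=False)
        done(len(sframe))
    except Exception as exc:
        raise StageError(f"stage subtype failed: {exc}") from exc

    try:
        done = _stage("clinical")
        n_rows = 0
        if clinical is not None:
            merged = clinical.merge(
                sframe[["sample_id", "call4", "im_score"]], on="sample_id",
                how="inner", suffixes=("_annot", ""))
            merged["subtype"] = merged["call4"]
            if len(merged):
                report = subtype_outcome_report(
                    merged, by="subtype", ci_method=cfg["ci_method"])
                report["pcr_table"].to_csv(out / "pcr_table.csv", index=False)
                serializable = {k: v for k, v in report.items()
                                if k != "pcr_table"}
                (out / "clinical_report.json").write_text(
                    json.dumps(serializable, indent=2, default=_jsonable))
                n_rows = len(merged)
            if til is not None and len(merged) >= 3:
                im = merged.set_index("sample_id")["im_score"]
                try:
                    assoc = im_til_association(im, til)
                    (out / "til_association.json").write_text(
                        json.dumps(assoc, indent=2, default=_jsonable))
                except ValueError as exc:
                    log.warning("TIL association skipped: %s", exc)
        done(n_rows)
    except Exception as exc:
        raise StageError(f"stage clinical failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return str(obj)
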