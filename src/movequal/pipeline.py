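"""Stage orchestration: config, logging, run manifests.

The pipeline mirrors the two-channel study design: channel 1 takes the
expert ratings through the agreement gate; channel 2 takes the pose
recordings through signal and feature extraction; the channels join in
per-parameter classification.  Each stage is idempotent for a fixed
config and inputs, writes only into its own output folder, and a run
manifest makes every reported number traceable to a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    AgreementReport,
    RatingTable,
    build_report,
)
from .classify import (
    BoostParams,
    cross_validate,
    train_adaboost,
)
from .errors import ConfigurationError, GatedParameterError, InsufficientDataError
from .features import FeatureTable, build_feature_table
from .kinematics import default_catalogue, load_catalogue
from .pose_io import PoseSequence, fill_missing, read_jsonl, write_jsonl
from .simulate import ERROR_MODES, SimulationConfig, generate_dataset

log = logging.getLogger("movequal")

DEFAULTS: dict[str, Any] = {
    "paths": {"pose_dir": None, "ratings_csv": None, "out_dir": "movequal_out"},
    "pose": {"missing_threshold": 0.1, "max_gap_frames": 5, "fps": 30.0},
    "catalogue": None,  # optional YAML override path
    "features": {"mode": "rom"},
    "agreement": {"kappa_min": 0.41, "min_minority": 8, "tie_rule": None},
    "boost": {
        "n_learners": 50,
        "learning_rate": 0.1,
        "max_depth": 3,
        "feature_subset": "sqrt",
        "seed": 42,
        "split": [0.80, 0.15, 0.05],
        "cv_folds": 5,
    },
    "simulate": {},  # SimulationConfig field overrides
    "seed": 0,
    "log_level": "INFO",
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with explicit overrides."""
    cfg = DEFAULTS
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def setup_logging(cfg: dict, quiet: bool = False) -> None:
    level = logging.ERROR if quiet else getattr(
        logging, str(cfg.get("log_level", "INFO")).upper(), logging.INFO)
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s", force=True)


def _out_dir(cfg: dict) -> Path:
    out = Path(cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _boost_params(cfg: dict) -> tuple[BoostParams, int]:
    b = dict(cfg["boost"])
    folds = int(b.pop("cv_folds", 5))
    b["split"] = tuple(b["split"])
    return BoostParams(**b), folds


def _catalogue(cfg: dict):
    return load_catalogue(cfg["catalogue"]) if cfg["catalogue"] else default_catalogue()


# ---------------------------------------------------------------------------
# Recording store: one JSON-lines file per recording, metadata in the name
# ---------------------------------------------------------------------------

def _recording_filename(seq: PoseSequence) -> str:
    return f"{seq.subject_id}__{seq.test_id}__{seq.limb}.jsonl"


def _parse_recording_name(path: Path) -> dict:
    parts = path.stem.split("__")
    if len(parts) != 3:
        raise ConfigurationError(
            f"{path.name}: expected '<subject>__<test>__<limb>.jsonl'"
        )
    return {"subject_id": parts[0], "test_id": parts[1], "limb": parts[2]}


def load_recordings(pose_dir: str | Path, cfg: dict) -> list[PoseSequence]:
    """Read, clean and gap-fill every recording in a pose directory."""
    pose_dir = Path(pose_dir)
    files = sorted(pose_dir.glob("*.jsonl"))
    if not files:
        raise InsufficientDataError(f"no recordings (*.jsonl) in {pose_dir}")
    sequences = []
    n_dropped = n_filled = 0
    for f in files:
        meta = _parse_recording_name(f)
        seq, read_report = read_jsonl(
            f, fps=cfg["pose"]["fps"],
            missing_threshold=cfg["pose"]["missing_threshold"], **meta)
        seq, fill_report = fill_missing(seq, cfg["pose"]["max_gap_frames"])
        n_dropped += len(read_report.dropped_frames)
        n_filled += fill_report.n_filled
        sequences.append(seq)
    log.info("extract: %d recordings, %d frames dropped, %d keypoints gap-filled",
             len(sequences), n_dropped, n_filled)
    return sequences


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: dict) -> dict:
    """Generate a synthetic cohort and write it in the pipeline's input formats."""
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs.setdefault("seed", cfg["seed"])
    sim = SimulationConfig(**sim_kwargs)
    cohort = generate_dataset(sim)

    out = _out_dir(cfg)
    pose_dir = out / "poses"
    pose_dir.mkdir(exist_ok=True)
    for seq in cohort.sequences:
        write_jsonl(seq, pose_dir / _recording_filename(seq))
    cohort.true_labels.to_csv(out / "true_labels.csv", index=False)
    for test, table in cohort.ratings.items():
        table.to_csv(out / f"ratings_{test}.csv")
    log.info("simulate: %d recordings (%d subjects x %s)",
             len(cohort.sequences), sim.n_subjects, list(sim.tests))
    return {
        "stage": "simulate",
        "n_recordings": len(cohort.sequences),
        "n_subjects": sim.n_subjects,
        "outputs": [str(pose_dir), str(out / "true_labels.csv")]
        + [str(out / f"ratings_{t}.csv") for t in cohort.ratings],
    }


def run_extract(cfg: dict) -> dict:
    """Pose recordings -> tidy per-recording signal CSVs."""
    from .kinematics import compute_signals, signals_to_tidy

    out = _out_dir(cfg)
    sig_dir = out / "signals"
    sig_dir.mkdir(exist_ok=True)
    catalogue = _catalogue(cfg)
    sequences = load_recordings(_pose_dir(cfg), cfg)
    written = []
    for seq in sequences:
        signals = compute_signals(seq, catalogue)
        path = sig_dir / f"{seq.subject_id}__{seq.test_id}__{seq.limb}.csv"
        signals_to_tidy(signals, seq).to_csv(path, index=False)
        written.append(str(path))
    log.info("extract: wrote %d signal files", len(written))
    return {"stage": "extract", "n_recordings": len(sequences),
            "outputs": [str(sig_dir)]}


def run_features(cfg: dict) -> dict:
    """Pose recordings -> one feature table CSV."""
    out = _out_dir(cfg)
    sequences = load_recordings(_pose_dir(cfg), cfg)
    table = build_feature_table(sequences, _catalogue(cfg),
                                mode=cfg["features"]["mode"])
    path = out / "features.csv"
    table.to_csv(path)
    if table.excluded:
        log.warning("features: excluded %d recordings: %s",
                    len(table.excluded), table.excluded)
    log.info("features: %d recordings x %d features",
             len(table.frame), len(table.feature_names))
    return {"stage": "features", "n_recordings": len(table.frame),
            "n_excluded": len(table.excluded), "outputs": [str(path)]}


def _pose_dir(cfg: dict) -> Path:
    pose_dir = cfg["paths"]["pose_dir"] or (Path(cfg["paths"]["out_dir"]) / "poses")
    pose_dir = Path(pose_dir)
    if not pose_dir.exists():
        raise ConfigurationError(
            f"pose directory {pose_dir} does not exist; "
            "run the simulate stage or point paths.pose_dir at recordings"
        )
    return pose_dir


def _ratings_files(cfg: dict) -> list[Path]:
    if cfg["paths"]["ratings_csv"]:
        return [Path(cfg["paths"]["ratings_csv"])]
    out = Path(cfg["paths"]["out_dir"])
    files = sorted(out.glob("ratings_*.csv"))
    if not files:
        raise ConfigurationError(
            "no ratings found; set paths.ratings_csv or run the simulate stage"
        )
    return files


def run_agreement(cfg: dict) -> dict:
    """Rating tables -> per-parameter agreement reports with the gate applied."""
    out = _out_dir(cfg)
    ag = cfg["agreement"]
    outputs = []
    gated_in = gated_out = 0
    for path in _ratings_files(cfg):
        table = RatingTable.from_csv(path)
        report = build_report(table, kappa_min=ag["kappa_min"],
                              min_minority=ag["min_minority"],
                              tie_rule=ag["tie_rule"])
        stem = path.stem.replace("ratings", "agreement")
        report.to_csv(out / f"{stem}.csv")
        outputs.append(str(out / f"{stem}.csv"))
        eligible = report.eligible_parameters()
        gated_in += len(eligible)
        gated_out += len(report.frame) - len(eligible)
        log.info("agreement[%s]: %d/%d parameters eligible: %s",
                 path.stem, len(eligible), len(report.frame), eligible)
    return {"stage": "agreement", "parameters_in": gated_in,
            "parameters_out": gated_out, "outputs": outputs}


def run_train_eval(cfg: dict, parameter: str | None = None) -> dict:
    """Train and evaluate the boosted classifier per eligible parameter.

    Classification refuses parameters the agreement gate rejected; asking
    for one explicitly raises :class:`GatedParameterError`.
    """
    out = _out_dir(cfg)
    params, folds = _boost_params(cfg)
    ag = cfg["agreement"]

    features_path = out / "features.csv"
    if not features_path.exists():
        run_features(cfg)
    table = FeatureTable.from_csv(features_path)

    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    rows = []
    outputs = []
    for ratings_path in _ratings_files(cfg):
        test = ratings_path.stem.replace("ratings_", "")
        ratings = RatingTable.from_csv(ratings_path)
        report = build_report(ratings, kappa_min=ag["kappa_min"],
                              min_minority=ag["min_minority"],
                              tie_rule=ag["tie_rule"])
        eligible = set(report.eligible_parameters())
        requested = [parameter] if parameter else sorted(eligible)
        sub = table.frame[table.frame["test_id"] == test]
        if sub.empty:
            continue
        X = sub[table.feature_names].to_numpy(dtype=float)
        subject_order = list(sub["subject_id"].astype(str))
        for p in requested:
            if p not in ratings.parameters:
                continue
            if p not in eligible:
                raise GatedParameterError(
                    f"parameter {p!r} ({test}) was rejected by the agreement "
                    f"gate (kappa >= {ag['kappa_min']}, minority >= "
                    f"{ag['min_minority']}) and cannot be classified"
                )
            labels = pd.Series(report.consensus[p],
                               index=ratings.subjects).reindex(subject_order)
            y = labels.to_numpy(dtype=int)
            result = cross_validate(X, y, params, k=folds)
            model = train_adaboost(X, y, params)
            model_path = models_dir / f"{test}__{_slug(p)}.json"
            model.to_json(model_path)
            outputs.append(str(model_path))
            rows.append({"test_id": test, "parameter": p, **result.as_row()})
            log.info("train[%s/%s]: sens %.2f spec %.2f acc %.2f (n=%d)",
                     test, p, result.sensitivity, result.specificity,
                     result.accuracy, result.n)
    eval_df = pd.DataFrame(rows)
    eval_path = out / "evaluation.csv"
    eval_df.to_csv(eval_path, index=False)
    outputs.append(str(eval_path))
    return {"stage": "train_eval", "n_models": len(rows), "outputs": outputs}


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def run_all(cfg: dict) -> dict:
    """Chain all stages in study order and write the run manifest."""
    out = _out_dir(cfg)
    stages = []
    if cfg["paths"]["pose_dir"] is None:
        stages.append(run_simulate(cfg))
    stages.append(run_extract(cfg))
    stages.append(run_features(cfg))
    stages.append(run_agreement(cfg))
    stages.append(run_train_eval(cfg))
    manifest = {
        "config_hash": config_hash(cfg),
        "package_version": __version__,
        "stages": stages,
        "outputs": sorted({o for s in stages for o in s.get("outputs", [])}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run_all: manifest written to %s", out / "manifest.json")
    return manifest
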