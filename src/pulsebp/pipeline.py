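"""Stage orchestration: simulate → preprocess → train → evaluate.

Each stage reads its inputs from and writes its artifacts to the configured
output directory; a JSON manifest records the configuration hash, seeds,
library versions, per-stage record/segment tallies and the failure point if
any stage aborts.  Re-running with an unchanged configuration reproduces
all counts and metrics bit-for-bit within one software environment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .config import PipelineConfig, config_hash, to_dict
from .evaluation import evaluate
from .preprocess import RejectionTally, preprocess_record
from .records import (
    SegmentStore,
    read_segments,
    select_eligible_records,
    write_record,
    write_segments,
)
from .synthetic import generate_dataset
from .training import run_protocol
from .network import BPNet

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs were missing."""


def _paths(out_dir: Path) -> dict[str, Path]:
    return {
        "records": out_dir / "records",
        "truth": out_dir / "ground_truth.csv",
        "segments": out_dir / "segments.csv",
        "checkpoint": out_dir / "model.npz",
        "curves": out_dir / "training_curves.csv",
        "report": out_dir / "report.json",
        "manifest": out_dir / "manifest.json",
    }


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the requested stages in order and return the manifest dict."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = _paths(out)
    manifest: dict = {
        "config_hash": config_hash(config),
        "config": to_dict(config),
        "versions": {
            "pulsebp": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "seed": config.seed,
        "stages": {},
        "status": "ok",
    }

    # precondition pass before any compute
    if "preprocess" in stages and "simulate" not in stages and not paths["records"].exists():
        raise StageError(f"preprocess requested but no records at {paths['records']}")
    if "train" in stages and "preprocess" not in stages and not paths["segments"].exists():
        raise StageError(f"train requested but no segment store at {paths['segments']}")
    if "evaluate" in stages:
        if "train" not in stages and not paths["checkpoint"].exists():
            raise StageError(f"evaluate requested but no checkpoint at {paths['checkpoint']}")
        if "preprocess" not in stages and "train" not in stages and not paths["segments"].exists():
            raise StageError(f"evaluate requested but no segment store at {paths['segments']}")

    try:
        for stage in stages:
            t0 = time.monotonic()
            info = _STAGE_FNS[stage](config, paths)
            info["seconds"] = round(time.monotonic() - t0, 2)
            manifest["stages"][stage] = info
            logger.info("stage %s done in %.1f s: %s", stage, info["seconds"], info)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
        raise
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: PipelineConfig, paths: dict[str, Path]) -> dict:
    records, truth = generate_dataset(config.synth)
    paths["records"].mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_record(rec, paths["records"] / f"{rec.subject_id}.csv")
    truth.beats.to_csv(paths["truth"], index=False)
    return {"n_records": len(records), "n_beats": int(len(truth.beats))}


def _stage_preprocess(config: PipelineConfig, paths: dict[str, Path]) -> dict:
    files = sorted(paths["records"].glob("*.csv"))
    records = select_eligible_records(files)
    store = SegmentStore()
    tally = RejectionTally()
    for rec in records:
        for seg in preprocess_record(rec, config.preprocess, tally):
            store.append(seg)
    if len(store) == 0:
        raise StageError("preprocessing produced no segments")
    write_segments(store, paths["segments"])
    return {
        "n_record_files": len(files),
        "n_eligible_records": len(records),
        **dataclasses.asdict(tally),
    }


def _stage_train(config: PipelineConfig, paths: dict[str, Path]) -> dict:
    store = read_segments(paths["segments"])
    best, test, results = run_protocol(store.segments, config.train, config.split)
    best.save(paths["checkpoint"])
    rows = []
    for res in results:
        for epoch, (tl, vm) in enumerate(zip(res.train_losses, res.val_maes)):
            rows.append(
                {"fold": res.fold_index, "epoch": epoch, "train_mse": tl, "val_mae": vm}
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(paths["curves"], index=False)
    return {
        "target": config.train.target,
        "n_segments": len(store),
        "n_test": len(test),
        "n_folds_trained": len(results),
        "selected_fold": int(
            next(r.fold_index for r in results if r.net is best)
        ),
    }


def _stage_evaluate(config: PipelineConfig, paths: dict[str, Path]) -> dict:
    store = read_segments(paths["segments"])
    net = BPNet.load(paths["checkpoint"])
    net.target = config.train.target
    from .training import split_per_subject

    _, test = split_per_subject(store.segments, config.split)
    report, grades, ba = evaluate(net, test)
    payload = {
        "target": config.train.target,
        "metrics": dataclasses.asdict(report),
        "grades": dataclasses.asdict(grades),
        "bland_altman": dataclasses.asdict(ba),
    }
    paths["report"].write_text(json.dumps(payload, indent=2))
    return {
        "n_test": len(test),
        "mae": round(report.mae, 3),
        "sd": round(report.sd, 3),
        "r": round(report.r, 4) if report.r_defined else None,
        "grades": dataclasses.asdict(grades),
    }


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
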