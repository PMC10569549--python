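"""End-to-end pipeline: simulate -> preprocess -> train -> predict ->
postprocess -> evaluate -> stats, with per-stage toggles and reproducible
artifacts (every output records the config hash and seed)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, phantom, postprocess, preprocess, stats, unet
from .core import StageError, logger
from .io import write_specimen_table, write_volume

PROFILES = ("mini", "desk", "full")


@dataclass
class PipelineConfig:
    out_dir: str = "beemorph_run"
    seed: int = 0
    profile: str = "mini"
    species: str = "honeybee"
    n_train: int = 8
    n_val: int = 2
    n_test: int = 4
    grid: int | None = None          # phantom grid edge; profile default if None
    denoise: bool = True
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "train", "predict", "postprocess",
        "evaluate", "stats",
    )
    net_overrides: dict = field(default_factory=dict)
    phantom_overrides: dict = field(default_factory=dict)

    def net_config(self) -> unet.NetConfig:
        maker = {"mini": unet.NetConfig.mini, "desk": unet.NetConfig.desk,
                 "full": unet.NetConfig.full}[self.profile]
        return maker(seed=self.seed, **self.net_overrides)

    def phantom_params(self) -> phantom.PhantomParams:
        grid = self.grid
        if grid is None:
            grid = {"mini": 32, "desk": 96, "full": 256}[self.profile]
        maker = (phantom.PhantomParams.bumblebee
                 if self.species == "bumblebee" else phantom.PhantomParams.honeybee)
        return maker(grid_shape=(grid,) * 3, seed=self.seed, **self.phantom_overrides)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "profile": cfg.profile,
        "stages": list(cfg.stages),
    }
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "train": _stage_train,
        "predict": _stage_predict,
        "postprocess": _stage_postprocess,
        "evaluate": _stage_evaluate,
        "stats": _stage_stats,
    }
    for stage in cfg.stages:
        if stage not in runners:
            raise StageError(stage, "unknown stage")
        logger.info("stage %s ...", stage)
        try:
            runners[stage](cfg, state, summary, out)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    summary["runtime_s"] = round(time.time() - t_start, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "run.log").write_text(
        f"config_hash={summary['config_hash']} seed={cfg.seed} "
        f"runtime_s={summary['runtime_s']}\n"
    )
    return summary


def _stage_simulate(cfg, state, summary, out):
    params = cfg.phantom_params()
    n = cfg.n_train + cfg.n_val + cfg.n_test
    cohort = phantom.sample_cohort(params, n, {"H1": (n + 1) // 2, "H2": n // 2})
    phantoms, cohort = phantom.render_cohort(cohort, params)
    table = phantom.cohort_to_table(cohort)
    write_specimen_table(out / "cohort.csv", table)
    write_volume(out / "phantom_000_image.nrrd", phantoms[0][0])
    write_volume(out / "phantom_000_labels.nrrd", phantoms[0][1])
    state["phantoms"] = phantoms
    state["cohort"] = cohort
    state["params"] = params
    summary["simulate"] = {"n_specimens": n, "grid": params.grid_shape}


def _stage_preprocess(cfg, state, summary, out):
    if "phantoms" not in state:
        raise StageError("preprocess", "no volumes; run simulate or load data")
    if cfg.denoise:
        state["phantoms"] = [
            (preprocess.denoise_mean3(v), l) for v, l in state["phantoms"]
        ]
    summary["preprocess"] = {"denoised": cfg.denoise}


def _stage_train(cfg, state, summary, out):
    ph = state.get("phantoms")
    if not ph:
        raise StageError("train", "no training volumes available")
    ncfg = cfg.net_config()
    train = ph[: cfg.n_train]
    val = ph[cfg.n_train: cfg.n_train + cfg.n_val]
    model = unet.train_unet(train, val, ncfg)
    state["model"] = model
    np.savez_compressed(out / "model_weights.npz", *model.weights)
    (out / "training_history.json").write_text(
        json.dumps(model.history, default=float)
    )
    summary["train"] = {
        "best_epoch": model.best_epoch,
        "best_val_dice": model.best_val_dice,
        "n_parameters": model.history["n_parameters"],
    }


def _stage_predict(cfg, state, summary, out):
    if "model" not in state:
        raise StageError("predict", "model not found")
    ph = state.get("phantoms")
    test = ph[cfg.n_train + cfg.n_val:]
    preds = [unet.predict_volume(state["model"], v) for v, _ in test]
    state["predictions"] = preds
    state["test_truth"] = [l for _, l in test]
    summary["predict"] = {"n_test": len(preds)}


def _stage_postprocess(cfg, state, summary, out):
    preds = state.get("predictions")
    if preds is None:
        raise StageError("postprocess", "no predictions available")
    records = []
    cleaned = []
    for i, lv in enumerate(preds):
        lv2 = postprocess.remove_islands(lv)
        sides = postprocess.split_left_right(lv2)
        rec = postprocess.measure_volumes(
            lv2, sides, meta={"specimen_id": f"test{i:03d}", "species": cfg.species}
        )
        records.append(rec)
        cleaned.append(lv2)
    state["predictions"] = cleaned
    frame = postprocess.records_to_frame(records)
    frame.insert(0, "config_hash", summary["config_hash"])
    frame.to_csv(out / "measured_volumes.csv", index=False)
    summary["postprocess"] = {"n_records": len(records)}


def _stage_evaluate(cfg, state, summary, out):
    preds = state.get("predictions")
    truth = state.get("test_truth")
    if not preds or not truth:
        raise StageError("evaluate", "need predictions and ground truth")
    rows = []
    for i, (p, t) in enumerate(zip(preds, truth)):
        ev = metrics.evaluate(p, t)
        rows.append({
            "specimen": f"test{i:03d}",
            "total_dice": ev.total_dice,
            "total_assd_vox": ev.total_assd_vox,
            "error_pct": ev.error_pct,
            "category": ev.category,
            **{f"dice_{k}": v for k, v in ev.per_label_dice.items()},
        })
    frame = pd.DataFrame(rows)
    frame.insert(0, "config_hash", summary["config_hash"])
    frame.to_csv(out / "evaluation.csv", index=False)
    summary["evaluate"] = {
        "mean_total_dice": float(frame["total_dice"].mean()),
        "mean_total_assd_vox": float(frame["total_assd_vox"].mean()),
        "categories": frame["category"].value_counts().to_dict(),
    }


def _stage_stats(cfg, state, summary, out):
    cohort = state.get("cohort")
    if cohort is None:
        raise StageError("stats", "no cohort table available")
    table = phantom.cohort_to_table(cohort)
    result = {
        "percent_variation_total": stats.percent_variation(table["total_mm3"]),
        "allometric_slope_MB": dataclasses.asdict(
            stats.allometric_slope(table["total_mm3"], table["MB_mm3"])
        ),
    }
    if table["hive"].nunique() >= 2:
        res = stats.colony_effect_test(table, "total_mm3")
        result["colony_effect_total"] = dataclasses.asdict(res)
    lat = stats.lateralization_test(table, "OL")
    result["lateralization_OL"] = dataclasses.asdict(lat)
    result["asymmetry_quadrants"] = stats.asymmetry_quadrants(table)
    (out / "stats.json").write_text(json.dumps(result, indent=2, default=float))
    summary["stats"] = {"percent_variation_total": result["percent_variation_total"]}
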