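"""End-to-end orchestration: simulate → sense → calibrate → train → evaluate → explain.

`run_pipeline` chains every stage with a single seed tree (numpy
SeedSequence spawning one stream per stage), structured per-stage logging,
and a run manifest recording the configuration snapshot, stage seeds,
artifact hashes and timings, so a rerun with the same manifest reproduces
the same metric JSONs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, cohort, metrics as metrics_mod, pipeline, sensors, shapley
from .nn import MTLConfig

log = logging.getLogger("empatch")

STAGES = ("simulate", "sense", "calibrate", "train", "evaluate", "explain")


DEFAULT_RUN_CONFIG = {
    "seed": 0,
    "cohort": {"n_per_group": 125, "weeks": 4},
    "windows": {"T": 60, "sample_rate_hz": 1.0},
    "folds": {"k": 5, "group_by_subject": True},
    "model": {"epochs": 40, "batch_size": 32, "lr": 1e-3,
              "loss_weight_lambda": 1.0, "conv_channels": [16, 32, 32, 64, 64]},
    "explain": {"n_samples": 120},
    "baselines": True,
}


def load_run_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = dict(path_or_dict or {})
    merged = json.loads(json.dumps(DEFAULT_RUN_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES) + 2)
    names = list(STAGES) + ["demo", "spare"]
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    artifacts: dict
    timings_s: dict
    version: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def run_pipeline(config=None, out_dir: str | Path = "runs/default") -> RunManifest:
    """Run the full default experiment and write all artifacts to ``out_dir``.

    Artifacts: panels CSV (+ manifest), example traces CSV, calibration
    JSON, fold-assignment CSV, five model checkpoints, metrics JSON,
    attribution CSVs and the run manifest.
    """
    from . import __version__

    cfg = load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def stage(name):
        log.info("stage %s: start (seed=%d)", name, seeds[name])
        return time.perf_counter()

    # -- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    if int(cfg["cohort"].get("weeks", 4)) < 1:
        raise ValueError("simulate: weeks must be >= 1 (got "
                         f"{cfg['cohort'].get('weeks')})")
    ccfg = cohort.CohortConfig(seed=seeds["simulate"], **cfg["cohort"])
    panels = cohort.simulate_chronic(ccfg)
    cohort.validate_panels(panels)
    cohort.write_panels(panels, out / "panels.csv", config=ccfg)
    artifacts["panels"] = "panels.csv"
    timings["simulate"] = time.perf_counter() - t0

    # -- sense --------------------------------------------------------------
    t0 = stage("sense")
    params = sensors.device_channel_params()
    ws = pipeline.build_windows(
        panels, params, T=int(cfg["windows"]["T"]),
        sample_rate_hz=float(cfg["windows"]["sample_rate_hz"]),
        seed=seeds["sense"],
    )
    example_traces = [
        sensors.channel_forward(cohort.DEFAULT_BASELINE_MEANS[c], params[ch],
                                duration_s=60.0, seed=seeds["sense"] + i)
        for i, (c, ch) in enumerate(
            zip(cohort.ANALYTE_COLUMNS, sensors.CHANNELS))
    ]
    sensors.traces_to_csv(example_traces, out / "traces.csv")
    artifacts["traces"] = "traces.csv"
    timings["sense"] = time.perf_counter() - t0

    # -- calibrate ----------------------------------------------------------
    t0 = stage("calibrate")
    curves = calibration.calibrate_all(
        {ch: sensors.noiseless(p) for ch, p in params.items()}
    )
    calibration.curves_to_json(curves, out / "calibration.json",
                               input_hash=calibration.table_hash(panels))
    artifacts["calibration"] = "calibration.json"
    timings["calibrate"] = time.perf_counter() - t0

    # -- train --------------------------------------------------------------
    t0 = stage("train")
    mcfg = MTLConfig(seed=seeds["train"],
                     conv_channels=tuple(cfg["model"]["conv_channels"]),
                     epochs=int(cfg["model"]["epochs"]),
                     batch_size=int(cfg["model"]["batch_size"]),
                     lr=float(cfg["model"]["lr"]),
                     loss_weight_lambda=float(cfg["model"]["loss_weight_lambda"]))
    folds = pipeline.make_stratified_folds(
        ws.y_class, ws.y_degree, k=int(cfg["folds"]["k"]), seed=seeds["train"],
        subject_ids=ws.subject_ids if cfg["folds"].get("group_by_subject", True) else None,
    )
    pd.DataFrame({"sample": np.arange(len(ws)), "fold": folds.assignments}).to_csv(
        out / "folds.csv", index=False)
    artifacts["folds"] = "folds.csv"
    models, cv_metrics, history = pipeline.train_mtl(ws, folds, mcfg)
    for m in models:
        m.save(out / f"model_fold{m.fold}.npz")
    artifacts["checkpoints"] = [f"model_fold{f}.npz" for f in range(folds.k)]
    history.to_csv(out / "history.csv", index=False)
    artifacts["history"] = "history.csv"
    timings["train"] = time.perf_counter() - t0

    # -- evaluate -----------------------------------------------------------
    t0 = stage("evaluate")
    all_metrics = {"cv": cv_metrics.to_dict(orient="records")}
    proba_parts, deg_parts, ytrue_parts, ydeg_parts = [], [], [], []
    for m in models:
        va = folds.val_idx(m.fold)
        proba, degree = pipeline.predict(m, ws.x[va])
        proba_parts.append(proba)
        deg_parts.append(degree)
        ytrue_parts.append(ws.y_class[va])
        ydeg_parts.append(ws.y_degree[va])
    proba = np.concatenate(proba_parts)
    y_true = np.concatenate(ytrue_parts)
    cls = metrics_mod.classification_metrics(y_true, proba)
    reg = metrics_mod.regression_metrics(
        np.concatenate(ydeg_parts), np.concatenate(deg_parts))
    all_metrics["pooled_classification"] = metrics_mod.metrics_to_json(cls)
    all_metrics["pooled_regression"] = reg
    if cfg.get("baselines", True):
        feats = pipeline.steady_features(ws)
        base = pipeline.train_baselines(feats, ws.y_class, ws.y_degree, folds,
                                        seed=seeds["evaluate"])
        all_metrics["baselines"] = base.to_dict(orient="records")
    (out / "metrics.json").write_text(json.dumps(all_metrics, indent=2))
    artifacts["metrics"] = "metrics.json"
    timings["evaluate"] = time.perf_counter() - t0

    # -- explain ------------------------------------------------------------
    t0 = stage("explain")
    rng = np.random.default_rng(seeds["explain"])
    model0 = models[0]
    va = folds.val_idx(0)
    take = rng.choice(va, size=min(int(cfg["explain"]["n_samples"]), va.size),
                      replace=False)
    report = shapley.attribute_model(model0, ws.x[take])
    summary = shapley.shap_summary(report)
    summary["importance"].to_csv(out / "shap_importance.csv", index=False)
    summary["sign_by_class"].to_csv(out / "shap_sign_by_class.csv", index=False)
    pd.DataFrame(report.phi_class, columns=list(report.channels)).to_csv(
        out / "shap_phi_class.csv", index=False)
    artifacts["attribution"] = ["shap_importance.csv", "shap_sign_by_class.csv",
                                "shap_phi_class.csv"]
    timings["explain"] = time.perf_counter() - t0

    manifest = RunManifest(config=cfg, seeds=seeds, artifacts=artifacts,
                           timings_s={k: round(v, 3) for k, v in timings.items()},
                           version=__version__)
    manifest.write(out / "manifest.json")
    return manifest


def default_cv_experiment(seed: int = 0) -> dict:
    """The default chronic-cohort cross-validation experiment.

    Simulates the default cohort (125 animals per diet group, weeks 1–4 on
    diet → 1500 six-channel windows), renders sensor windows, builds
    animal-grouped stratified fivefold splits and trains the multi-task
    network with default hyperparameters. Returns the window set, folds,
    models and the per-fold metrics table. All randomness derives from
    ``seed``.
    """
    seeds = _stage_seeds(int(seed))
    ccfg = cohort.CohortConfig(seed=seeds["simulate"])
    panels = cohort.simulate_chronic(ccfg)
    cohort.validate_panels(panels)
    ws = pipeline.build_windows(panels, seed=seeds["sense"])
    folds = pipeline.make_stratified_folds(
        ws.y_class, ws.y_degree, k=5, seed=seeds["train"],
        subject_ids=ws.subject_ids,
    )
    models, metrics, history = pipeline.train_mtl(ws, folds,
                                                  MTLConfig(seed=seeds["train"]))
    return {"panels": panels, "windows": ws, "folds": folds, "models": models,
            "metrics": metrics, "history": history, "seeds": seeds}


def dynamic_transfer_demo(
    models: list,
    config=None,
    seed: int = 0,
    segment_groups: tuple[str, str] = ("HFFD", "HFFSD"),
    n_windows_per_segment: int = 30,
    week: int = 4,
) -> pd.DataFrame:
    """Two consecutive monitoring segments streamed through a trained model.

    Emulates moving the patch from one animal to another mid-session:
    windows are drawn from each segment's generating group at the given
    study week and predicted one by one. Returns the prediction stream with
    a ``segment_match`` summary (fraction of windows whose argmax class is
    the generating group) in ``df.attrs``.
    """
    if not models:
        raise ValueError("no trained model supplied")
    if n_windows_per_segment < 1:
        raise ValueError("segments must contain at least one window")
    cfg = load_run_config(config)
    ccfg = cohort.CohortConfig(
        n_per_group=n_windows_per_segment, weeks=week, seed=seed,
    )
    panels = cohort.simulate_chronic(ccfg)
    model = models[0]
    rows = []
    match = {}
    t_cursor = 0.0
    window_T = int(cfg["windows"]["T"])
    for seg_idx, group in enumerate(segment_groups):
        seg = panels[(panels["group"] == group) & (panels["week"] == week)]
        ws = pipeline.build_windows(seg, T=window_T, seed=seed + 17 * seg_idx)
        proba, degree = pipeline.predict(model, ws.x)
        pred = proba.argmax(axis=1)
        for i in range(len(ws)):
            rows.append({
                "t_min": t_cursor, "segment": seg_idx, "generating_group": group,
                "pred_class": cohort.CHRONIC_GROUPS[pred[i]],
                "p_CON": proba[i, 0], "p_HFFD": proba[i, 1], "p_HFFSD": proba[i, 2],
                "degree": degree[i],
            })
            t_cursor += window_T / 60.0
        match[group] = float(np.mean(
            pred == pipeline.CLASS_TO_INDEX[group]))
    df = pd.DataFrame(rows)
    df.attrs["segment_match"] = match
    return df
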