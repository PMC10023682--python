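"""End-to-end pipeline: simulate -> window -> train -> predict -> evaluate.

Every stage writes its artifacts into a working directory together with a
manifest stamping the configuration hash and seed, and logs per-recording
exclusion accounting (kept + excluded-by-reason = total windows).  Any
suffix of the chain is runnable standalone through the CLI.
"""
from __future__ import annotations

import json
import logging
import os
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import DISCARD_NONE, WindowedRecording
from .io_preprocess import write_rr_text, read_rr_text
from .metrics import evaluate_cohort, reports_to_frame
from .model import ArNet2Model, ModelConfig
from .synthetic import CohortSpec, make_cohort
from .windowing import (ExclusionConfig, apply_exclusion_cascade,
                        save_windows, segment_windows)

log = logging.getLogger("arnet2")


def _manifest(config: PipelineConfig, stage: str, outputs: List[str]) -> dict:
    return {"stage": stage, "config_hash": config.config_hash(),
            "seed": config.seed, "outputs": outputs}


def _write_manifest(workdir: str, stage: str, config: PipelineConfig,
                    outputs: List[str]) -> None:
    path = os.path.join(workdir, f"manifest_{stage}.json")
    with open(path, "w") as f:
        json.dump(_manifest(config, stage, outputs), f, indent=1)


def model_config_from(config: PipelineConfig) -> ModelConfig:
    m = config.model
    return ModelConfig(
        n_b=m.n_b, n_f=m.n_f, f_l=m.f_l, d_r1=m.d_r1, d_r2=m.d_r2,
        n_d=m.n_d, n_dense=m.n_dense, h=m.h, lr=m.lr, pos_weight=m.pos_weight,
        early_stop_min_delta=m.early_stop_min_delta,
        early_stop_patience=m.early_stop_patience, gru_units=m.gru_units,
        stage2_dense=m.stage2_dense, max_grad_norm=m.max_grad_norm,
        max_epochs=m.max_epochs,
        batch_size=m.batch_size, seed=config.seed)


def exclusion_config_from(config: PipelineConfig) -> ExclusionConfig:
    w = config.window
    return ExclusionConfig(bsqi_min=w.bsqi_min,
                           missing_max_ms=w.missing_max_s * 1000.0,
                           patient_missing_max=w.patient_missing_max,
                           noise_max=w.noise_max)


def stage_simulate(config: PipelineConfig, workdir: str) -> pd.DataFrame:
    """Generate the synthetic cohort as RR-text files + ground-truth table."""
    os.makedirs(workdir, exist_ok=True)
    s = config.simulate
    spec = CohortSpec(n_patients=s.n_patients, duration_h=s.duration_h,
                      seed=config.seed, episode_rhythm=s.episode_rhythm,
                      min_episode_s=s.min_episode_s, max_episode_s=s.max_episode_s,
                      at_fraction_of_patients=s.at_fraction_of_patients,
                      at_burden=s.at_burden, unknown_fraction=s.unknown_fraction)
    recordings, truth = make_cohort(spec)
    rr_dir = os.path.join(workdir, "rr")
    os.makedirs(rr_dir, exist_ok=True)
    for beats in recordings:
        write_rr_text(beats, os.path.join(rr_dir, f"{beats.record_id}.csv"))
    truth_path = os.path.join(workdir, "ground_truth.csv")
    truth.to_csv(truth_path, index=False)
    _write_manifest(workdir, "simulate", config, [truth_path, rr_dir])
    log.info("simulated %d recordings into %s", len(recordings), rr_dir)
    return truth


def stage_window(config: PipelineConfig, workdir: str) -> List[WindowedRecording]:
    """Window all RR files and apply the exclusion cascade, with accounting."""
    rr_dir = os.path.join(workdir, "rr")
    excl = exclusion_config_from(config)
    recs = []
    for name in sorted(os.listdir(rr_dir)):
        if not name.endswith(".csv"):
            continue
        beats = read_rr_text(os.path.join(rr_dir, name),
                             record_id=os.path.splitext(name)[0])
        rec = apply_exclusion_cascade(segment_windows(beats), excl)
        counts = rec.exclusion_counts()
        total = len(rec.windows)
        kept = counts["NONE"] if rec.discard_reason == DISCARD_NONE else 0
        assert sum(counts.values()) == total
        log.info("record %s: %d windows, kept=%d, missing=%d, low_quality=%d, "
                 "discard=%s", rec.record_id, total, kept,
                 counts["MISSING_LABELS"], counts["LOW_QUALITY"],
                 rec.discard_reason)
        recs.append(rec)
    out = os.path.join(workdir, "windows.csv")
    save_windows(recs, out)
    _write_manifest(workdir, "window", config, [out])
    return recs


def split_patients(recs: List[WindowedRecording], config: PipelineConfig) -> dict:
    """Deterministic patient-level train/val/test split (never by window)."""
    usable = [r for r in recs if r.discard_reason == DISCARD_NONE and r.included_windows]
    rng = np.random.Generator(np.random.PCG64(config.seed + 7))
    order = rng.permutation(len(usable))
    n = len(usable)
    n_train = max(int(round(config.model.train_fraction * n)), 1)
    n_val = max(int(round(config.model.val_fraction * n)), 1)
    train = [usable[i] for i in order[:n_train]]
    val = [usable[i] for i in order[n_train:n_train + n_val]]
    test = [usable[i] for i in order[n_train + n_val:]]
    return {"train": train, "val": val, "test": test}


def stage_train(config: PipelineConfig, workdir: str,
                recs: Optional[List[WindowedRecording]] = None) -> ArNet2Model:
    if recs is None:
        from .windowing import load_windows
        recs = load_windows(os.path.join(workdir, "windows.csv"))
    splits = split_patients(recs, config)
    model = ArNet2Model.train(splits["train"], splits["val"], model_config_from(config))
    ckpt = os.path.join(workdir, "model.ckpt")
    model.save(ckpt)
    split_path = os.path.join(workdir, "splits.json")
    with open(split_path, "w") as f:
        json.dump({k: [r.record_id for r in v] for k, v in splits.items()}, f, indent=1)
    _write_manifest(workdir, "train", config, [ckpt, split_path])
    log.info("stage-1 best val AUROC %.4f at epoch %d",
             model.stage1_log.best_val_auroc, model.stage1_log.best_epoch)
    return model


def stage_predict(config: PipelineConfig, workdir: str,
                  model: Optional[ArNet2Model] = None,
                  recs: Optional[List[WindowedRecording]] = None,
                  subset: Optional[List[str]] = None) -> pd.DataFrame:
    """Predict per-window labels; returns the prediction table."""
    if model is None:
        model = ArNet2Model.load(os.path.join(workdir, "model.ckpt"))
    if recs is None:
        from .windowing import load_windows
        recs = load_windows(os.path.join(workdir, "windows.csv"))
    if subset is not None:
        recs = [r for r in recs if r.record_id in set(subset)]
    rows = []
    for rec in recs:
        if rec.discard_reason != DISCARD_NONE:
            continue
        pred = model.predict(rec)
        windows = rec.included_windows
        for k in range(len(pred)):
            rows.append({
                "record_id": pred.record_id,
                "window_index": int(pred.window_indices[k]),
                "t_ms": float(pred.t_ms[k]),
                "y": int(windows[k].y),
                "p_stage1": float(pred.p_stage1[k]),
                "p": float(pred.p_stage2[k]),
                "y_hat": int(pred.y_hat[k]),
                "severity_used": pred.severity_used,
                "est_afb": pred.estimated_afb,
            })
    df = pd.DataFrame(rows)
    out = os.path.join(workdir, "predictions.csv")
    df.to_csv(out, index=False)
    _write_manifest(workdir, "predict", config, [out])
    return df


def stage_evaluate(config: PipelineConfig, workdir: str,
                   pred_df: Optional[pd.DataFrame] = None,
                   truth: Optional[pd.DataFrame] = None) -> dict:
    if pred_df is None:
        pred_df = pd.read_csv(os.path.join(workdir, "predictions.csv"))
    if truth is None:
        truth = pd.read_csv(os.path.join(workdir, "ground_truth.csv"))
    est = (pred_df.groupby("record_id")["est_afb"].first()
           .rename("est_afb").reset_index())
    rec_df = truth.merge(est, on="record_id", how="inner")
    result = evaluate_cohort(
        pred_df[["record_id", "t_ms", "y", "y_hat", "p"]], rec_df,
        strata=[c for c in config.metrics.strata if c in rec_df.columns])
    report = reports_to_frame(result["window"])
    report_path = os.path.join(workdir, "report_windows.csv")
    report.to_csv(report_path, index=False)
    patient_path = os.path.join(workdir, "report_patient.json")
    with open(patient_path, "w") as f:
        json.dump({"patient": result["patient"].as_dict(),
                   "fn_audit": result["fn_audit"].to_dict(orient="records")},
                  f, indent=1, default=float)
    _write_manifest(workdir, "evaluate", config, [report_path, patient_path])
    return result


def run_pipeline(config: PipelineConfig, workdir: str) -> dict:
    """Run the full chain on a synthetic cohort; returns the evaluation."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(workdir, exist_ok=True)
    truth = stage_simulate(config, workdir)
    recs = stage_window(config, workdir)
    model = stage_train(config, workdir, recs)
    splits = split_patients(recs, config)
    test_ids = [r.record_id for r in splits["test"]]
    pred_df = stage_predict(config, workdir, model, recs, subset=test_ids)
    result = stage_evaluate(config, workdir, pred_df, truth)
    result["model"] = model
    result["splits"] = {k: [r.record_id for r in v] for k, v in splits.items()}
    result["predictions"] = pred_df
    result["truth"] = truth
    return result
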