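"""Clinical and statistical evaluation.

AF burden (AFB) of a recording is the time-weighted fraction of included
windows labeled AF_l::

    AFB = sum_i t_i * I_i / sum_i t_i

with ``t_i`` the window duration (ms) and ``I_i`` the AF_l indicator.  The
burden estimation error is the signed, time-weighted difference between
predicted and reference labels::

    E_AF(%) = 100 * sum_i t_i * (yhat_i - y_i) / sum_i t_i

which equals ``100 * (AFB(yhat) - AFB(y))`` identically.  Patients are
stratified into four severity levels from (total AF_l time, AFB) and the
automated patient-level diagnosis thresholds the estimated AFB at 4%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

#: Severity / diagnosis boundaries.  Strict reading of the printed
#: inequalities: < 30 s total AF_l time -> NON_AFL; AFB < 4% -> AF_MILD;
#: 4% <= AFB <= 80% -> AF_MOD; AFB > 80% -> AF_SEV.  Patient positive iff
#: AFB >= 4%.
NON_AFL_MAX_TIME_MS = 30_000.0
MILD_MAX_AFB = 0.04
MOD_MAX_AFB = 0.80
DIAGNOSIS_AFB = 0.04


@dataclass
class BurdenResult:
    afb: float
    total_af_time_ms: float
    n_windows: int


@dataclass
class EvalReport:
    """Window- or patient-level classification statistics for one stratum."""

    stratum: str = ""
    n: int = 0
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    se: float = math.nan
    sp: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    f1: float = math.nan
    auroc: float = math.nan
    aucpr: float = math.nan
    eaf_abs_median: float = math.nan
    eaf_abs_q1: float = math.nan
    eaf_abs_q3: float = math.nan

    def as_dict(self) -> dict:
        return asdict(self)


def compute_afb(t_ms: Sequence[float], labels: Sequence[int]) -> Optional[BurdenResult]:
    """AF burden of a recording from included windows (Eq. AFB above).

    Returns ``None`` for an empty window list (undefined, not zero).
    Raises ``ValueError`` on non-positive durations or non-binary labels.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(labels)
    if t.size == 0:
        return None
    if t.shape != y.shape:
        raise ValueError("t_ms and labels must have equal length")
    if np.any(t <= 0):
        raise ValueError("window durations must be positive")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    af_time = float(np.sum(t * y))
    return BurdenResult(afb=af_time / float(t.sum()), total_af_time_ms=af_time,
                        n_windows=int(t.size))


def compute_eaf(t_ms: Sequence[float], y: Sequence[int], y_hat: Sequence[int]) -> float:
    """Signed AF-burden estimation error E_AF in percent."""
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if not (t.shape == y.shape == yh.shape):
        raise ValueError("t_ms, y and y_hat must have equal length")
    if t.size == 0:
        raise ValueError("E_AF undefined for empty input")
    return float(100.0 * np.sum(t * (yh - y)) / np.sum(t))


def classify_severity(total_af_time_ms: float, afb: float) -> str:
    """Map (total AF_l time, AFB) to one of the four severity strata."""
    if not (0.0 <= afb <= 1.0):
        raise ValueError(f"afb must be in [0, 1], got {afb}")
    if total_af_time_ms < NON_AFL_MAX_TIME_MS:
        return "NON_AFL"
    if afb < MILD_MAX_AFB:
        return "AF_MILD"
    if afb <= MOD_MAX_AFB:
        return "AF_MOD"
    return "AF_SEV"


def patient_diagnosis(afb: Optional[float]) -> Optional[int]:
    """Binary patient-level diagnosis: positive iff AFB >= 4%.

    A missing burden (``None``) yields a missing diagnosis.
    """
    if afb is None:
        return None
    if not (0.0 <= afb <= 1.0):
        raise ValueError(f"afb must be in [0, 1], got {afb}")
    return int(afb >= DIAGNOSIS_AFB)


def _confusion(y: np.ndarray, y_hat: np.ndarray) -> tuple:
    tp = int(np.sum((y == 1) & (y_hat == 1)))
    tn = int(np.sum((y == 0) & (y_hat == 0)))
    fp = int(np.sum((y == 0) & (y_hat == 1)))
    fn = int(np.sum((y == 1) & (y_hat == 0)))
    return tp, tn, fp, fn


def evaluate_windows(y: Sequence[int], y_hat: Sequence[int],
                     p: Optional[Sequence[float]] = None,
                     stratum: str = "") -> EvalReport:
    """Pooled binary classification statistics.

    Rank metrics (AUROC via trapezoidal ROC, AUCPR via step-wise
    precision-recall integration) require both classes and ``p``; they are
    reported missing (NaN) otherwise.  An undefined PPV (no positive
    predictions) is missing; F1 is then 0.
    """
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    tp, tn, fp, fn = _confusion(y, y_hat)
    rep = EvalReport(stratum=stratum, n=int(y.size), tp=tp, tn=tn, fp=fp, fn=fn)
    rep.se = tp / (tp + fn) if tp + fn else math.nan
    rep.sp = tn / (tn + fp) if tn + fp else math.nan
    rep.ppv = tp / (tp + fp) if tp + fp else math.nan
    rep.npv = tn / (tn + fn) if tn + fn else math.nan
    if math.isnan(rep.ppv) or (rep.se + rep.ppv) == 0:
        rep.f1 = 0.0
    else:
        rep.f1 = 2 * rep.se * rep.ppv / (rep.se + rep.ppv)
    if p is not None and len(set(y.tolist())) == 2:
        p = np.asarray(p, dtype=float)
        rep.auroc = float(roc_auc_score(y, p))
        rep.aucpr = float(average_precision_score(y, p))
    return rep


def summarize_eaf(eaf_values: Iterable[float]) -> tuple:
    """Median and (Q1, Q3) of |E_AF| using linear-interpolation quartiles."""
    v = np.abs(np.asarray(list(eaf_values), dtype=float))
    if v.size == 0:
        return math.nan, math.nan, math.nan
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def evaluate_cohort(window_df: pd.DataFrame,
                    recording_df: pd.DataFrame,
                    strata: Sequence[str] = ()) -> dict:
    """Stratified window-level and patient-level evaluation.

    Parameters
    ----------
    window_df : columns record_id, t_ms, y, y_hat and optionally p.
    recording_df : one row per recording with columns record_id, true_afb,
        est_afb (``est_afb`` may be NaN for recordings with no included
        windows) plus any stratum columns.
    strata : recording-level column names to stratify the window report by.

    Returns
    -------
    dict with keys ``"window"`` (list of EvalReport, one per stratum plus
    the pooled "all" stratum; |E_AF| quartiles taken across recordings) and
    ``"patient"`` (EvalReport of the 4%-rule diagnosis on estimated vs true
    AFB, with a false-negative audit listing each FN recording's true AF_l
    time).
    """
    wdf = window_df.merge(recording_df[["record_id", *strata]], on="record_id")

    def _window_report(sub: pd.DataFrame, name: str) -> EvalReport:
        p = sub["p"].to_numpy() if "p" in sub else None
        rep = evaluate_windows(sub["y"], sub["y_hat"], p, stratum=name)
        eafs = []
        for rid, g in sub.groupby("record_id"):
            eafs.append(compute_eaf(g["t_ms"], g["y"], g["y_hat"]))
        rep.eaf_abs_median, rep.eaf_abs_q1, rep.eaf_abs_q3 = summarize_eaf(eafs)
        return rep

    reports = [_window_report(wdf, "all")]
    for col in strata:
        for val, sub in wdf.groupby(col):
            if len(sub) == 0:
                continue
            reports.append(_window_report(sub, f"{col}={val}"))

    # patient level: 4% diagnosis on estimated AFB vs 4% rule on true AFB
    rec = recording_df.dropna(subset=["est_afb"])
    y_true = np.array([patient_diagnosis(a) for a in rec["true_afb"]], dtype=int)
    y_pred = np.array([patient_diagnosis(a) for a in rec["est_afb"]], dtype=int)
    p_est = rec["est_afb"].to_numpy(dtype=float)
    patient = evaluate_windows(y_true, y_pred, p_est, stratum="patient")
    fn_mask = (y_true == 1) & (y_pred == 0)
    fn_audit = rec[fn_mask]
    audit_cols = [c for c in ("record_id", "true_afb", "true_af_time_ms", "est_afb")
                  if c in rec.columns]
    return {
        "window": reports,
        "patient": patient,
        "fn_audit": fn_audit[audit_cols].reset_index(drop=True),
    }


def reports_to_frame(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """Tabular view of evaluation reports, one row per stratum."""
    return pd.DataFrame([r.as_dict() for r in reports])
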