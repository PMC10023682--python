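"""Segmentation into non-overlapping 60-beat windows and the quality /
exclusion cascade.

A window's binary AF_l label is the plurality vote of its 60 beat labels
(AF and AFL count as positive, everything else — including AT — as
negative; an exact 30/30 tie is resolved positive, favoring sensitivity
for a screening application).  The exclusion cascade runs in a fixed
order: (1) flag windows with more than 10 s of UNKNOWN-labeled beats;
(2) discard the recording if over 25% of windows are flagged; (3) flag
remaining windows with bSQI below 0.8; (4) discard the recording if the
total excluded fraction exceeds 75%.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .datatypes import (
    EXCL_LOW_QUALITY, EXCL_MISSING, EXCL_NONE,
    DISCARD_MISSING, DISCARD_NOISY, DISCARD_NONE,
    POSITIVE_LABELS, WINDOW_BEATS, WINDOW_RR,
    BeatSequence, RRWindow, WindowedRecording,
)
from .io_preprocess import compute_bsqi


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the exclusion cascade (paper defaults)."""

    bsqi_min: float = 0.8
    missing_max_ms: float = 10_000.0
    patient_missing_max: float = 0.25
    noise_max: float = 0.75

    def validate(self) -> None:
        if not 0.0 <= self.bsqi_min <= 1.0:
            raise ValueError("bsqi_min must be in [0, 1]")
        if self.missing_max_ms < 0:
            raise ValueError("missing_max_ms must be non-negative")
        for name in ("patient_missing_max", "noise_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def assign_window_label(beat_labels: np.ndarray) -> int:
    """Plurality AF_l label of a 60-beat window; 30/30 tie -> positive."""
    labels = np.asarray(beat_labels)
    if len(labels) != WINDOW_BEATS:
        raise ValueError(f"expected {WINDOW_BEATS} beat labels, got {len(labels)}")
    n_pos = int(np.isin(labels, tuple(POSITIVE_LABELS)).sum())
    return int(n_pos >= WINDOW_BEATS - n_pos)


def segment_windows(beats: BeatSequence) -> WindowedRecording:
    """Split a beat sequence into consecutive disjoint 60-beat windows.

    The trailing remainder (< 60 beats) is dropped.  Each window carries
    its 59 RR intervals, its plurality AF_l label and the duration of
    UNKNOWN-labeled beats (the summed RR intervals terminating at UNKNOWN
    beats).  bSQI defaults to 1.0 until attached by ``attach_bsqi``.
    """
    n_win = len(beats) // WINDOW_BEATS
    rec = WindowedRecording(record_id=beats.record_id)
    for k in range(n_win):
        sel = slice(k * WINDOW_BEATS, (k + 1) * WINDOW_BEATS)
        times = beats.beat_times[sel]
        labels = beats.beat_labels[sel]
        rr = np.diff(times)
        missing = float(rr[labels[1:] == "UNKNOWN"].sum())
        rec.windows.append(RRWindow(
            rr_ms=rr, start_ms=float(times[0]),
            y=assign_window_label(labels),
            missing_label_ms=missing, beat_labels=labels, index=k,
        ))
    return rec


def attach_bsqi(rec: WindowedRecording, ref: BeatSequence, test: BeatSequence,
                agreement_ms: float = 50.0) -> WindowedRecording:
    """Set each window's bSQI from two detectors over the window's span.

    The window span is the half-open interval [start, start + t_i); beats
    of both sequences falling in the span enter the agreement computation.
    """
    for w in rec.windows:
        stop = w.start_ms + w.t_ms
        w.bsqi = compute_bsqi(ref.slice_time(w.start_ms, stop + 1e-9),
                              test.slice_time(w.start_ms, stop + 1e-9),
                              agreement_ms=agreement_ms)
    return rec


def apply_exclusion_cascade(rec: WindowedRecording,
                            config: ExclusionConfig = ExclusionConfig(),
                            ) -> WindowedRecording:
    """Flag / discard windows and recordings in the specified order.

    Discarding is recorded as a status on the recording, never raised.
    The order matters: the missing-label patient rule is evaluated before
    any quality flags, so a recording with too many unannotated windows is
    discarded as TOO_MANY_MISSING even if low bSQI would also have
    condemned it.
    """
    config.validate()
    n = len(rec.windows)
    if n == 0:
        return rec
    # (1) missing-label windows
    for w in rec.windows:
        w.excluded = EXCL_MISSING if w.missing_label_ms > config.missing_max_ms else EXCL_NONE
    n_missing = sum(w.excluded == EXCL_MISSING for w in rec.windows)
    # (2) patient-level missing rule
    if n_missing / n > config.patient_missing_max:
        rec.discard_reason = DISCARD_MISSING
        return rec
    # (3) low-quality windows among the remaining
    for w in rec.windows:
        if w.excluded == EXCL_NONE and w.bsqi < config.bsqi_min:
            w.excluded = EXCL_LOW_QUALITY
    # (4) patient-level noise rule on the total exclusion rate
    n_excluded = sum(w.excluded != EXCL_NONE for w in rec.windows)
    if n_excluded / n > config.noise_max:
        rec.discard_reason = DISCARD_NOISY
    else:
        rec.discard_reason = DISCARD_NONE
    return rec


def windows_to_frame(rec: WindowedRecording) -> pd.DataFrame:
    """Delimited-table view: one row per window, rr_1..rr_59 columns."""
    rows = []
    for w in rec.windows:
        row = {
            "record_id": rec.record_id, "window_index": w.index,
            "start_ms": w.start_ms, "t_ms": w.t_ms, "bsqi": w.bsqi,
            "missing_ms": w.missing_label_ms, "excluded_reason": w.excluded,
            "y": w.y,
        }
        row.update({f"rr_{i + 1}": float(v) for i, v in enumerate(w.rr_ms)})
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df.insert(0, "discard_reason", rec.discard_reason)
    return df


def frame_to_windows(df: pd.DataFrame) -> list:
    """Rebuild WindowedRecording objects from a windows table."""
    rr_cols = [f"rr_{i + 1}" for i in range(WINDOW_RR)]
    recs = []
    for rid, g in df.groupby("record_id", sort=False):
        rec = WindowedRecording(record_id=str(rid))
        if "discard_reason" in g:
            rec.discard_reason = str(g["discard_reason"].iloc[0])
        for _, row in g.iterrows():
            rec.windows.append(RRWindow(
                rr_ms=row[rr_cols].to_numpy(dtype=float),
                start_ms=float(row["start_ms"]),
                y=None if pd.isna(row["y"]) else int(row["y"]),
                bsqi=float(row["bsqi"]),
                missing_label_ms=float(row["missing_ms"]),
                excluded=str(row["excluded_reason"]),
                index=int(row["window_index"]),
            ))
        recs.append(rec)
    return recs


def save_windows(recs: list, path) -> None:
    frames = [windows_to_frame(r) for r in recs if r.windows]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_windows(path) -> list:
    return frame_to_windows(pd.read_csv(path))
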