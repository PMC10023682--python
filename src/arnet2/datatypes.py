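"""Core domain containers shared across the pipeline.

Times are carried in milliseconds from record start, RR intervals in
milliseconds, burdens as fractions in [0, 1] (reported as percent only at
the presentation layer).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Beat-level rhythm label vocabulary.  AF and AFL collapse to the positive
#: class ("AF_l") downstream; AT and the remaining labels are negative.
RHYTHM_LABELS = ("AF", "AFL", "AT", "OTHER_SVT", "OTHER", "UNKNOWN")
POSITIVE_LABELS = frozenset({"AF", "AFL"})

#: Window / recording exclusion reasons.
EXCL_NONE = "NONE"
EXCL_MISSING = "MISSING_LABELS"
EXCL_LOW_QUALITY = "LOW_QUALITY"
DISCARD_NONE = "NONE"
DISCARD_MISSING = "TOO_MANY_MISSING"
DISCARD_NOISY = "TOO_NOISY"

#: Patient severity strata defined by (total AF_l time, AF burden).
SEVERITY_LEVELS = ("NON_AFL", "AF_MILD", "AF_MOD", "AF_SEV")

#: Number of beats per analysis window (59 RR intervals).
WINDOW_BEATS = 60
WINDOW_RR = WINDOW_BEATS - 1


@dataclass
class EcgRecord:
    """Single-lead ECG waveform."""

    samples: np.ndarray  # amplitude, mV
    fs: float            # sampling rate, Hz
    lead_name: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class BeatSequence:
    """Time-stamped beats with per-beat rhythm labels.

    ``beat_times`` are strictly increasing milliseconds from record start.
    A beat's label describes the rhythm of the RR interval terminating at
    that beat; ``UNKNOWN`` marks spans without annotation.
    """

    beat_times: np.ndarray
    beat_labels: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.beat_labels = np.asarray(self.beat_labels, dtype="U9")
        if self.beat_times.ndim != 1:
            raise ValueError("beat_times must be 1-D")
        if len(self.beat_times) != len(self.beat_labels):
            raise ValueError("beat_times and beat_labels length mismatch")
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")
        bad = set(np.unique(self.beat_labels)) - set(RHYTHM_LABELS)
        if bad and len(self.beat_labels):
            raise ValueError(f"unknown rhythm labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.beat_times)

    def slice_time(self, start_ms: float, stop_ms: float) -> "BeatSequence":
        """Beats with time in the half-open interval [start_ms, stop_ms)."""
        m = (self.beat_times >= start_ms) & (self.beat_times < stop_ms)
        return BeatSequence(self.beat_times[m], self.beat_labels[m], self.record_id)


@dataclass
class RRWindow:
    """One 60-beat unit: 59 RR intervals plus label/quality metadata."""

    rr_ms: np.ndarray
    start_ms: float
    y: Optional[int] = None          # binary AF_l label; None when unset
    bsqi: float = 1.0
    missing_label_ms: float = 0.0
    excluded: str = EXCL_NONE
    beat_labels: Optional[np.ndarray] = None  # the 60 source beat labels
    index: int = -1

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if len(self.rr_ms) != WINDOW_RR:
            raise ValueError(f"expected {WINDOW_RR} RR intervals, got {len(self.rr_ms)}")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def t_ms(self) -> float:
        """Window duration t_i: the sum of its 59 RR intervals (ms)."""
        return float(self.rr_ms.sum())


@dataclass
class WindowedRecording:
    """Ordered, non-overlapping 60-beat windows of one recording."""

    record_id: str
    windows: list = field(default_factory=list)
    discard_reason: str = DISCARD_NONE

    @property
    def included_windows(self) -> list:
        if self.discard_reason != DISCARD_NONE:
            return []
        return [w for w in self.windows if w.excluded == EXCL_NONE]

    def exclusion_counts(self) -> dict:
        counts = {EXCL_NONE: 0, EXCL_MISSING: 0, EXCL_LOW_QUALITY: 0}
        for w in self.windows:
            counts[w.excluded] += 1
        return counts


@dataclass
class PredictionSet:
    """Per-window model output for one recording."""

    record_id: str
    window_indices: np.ndarray
    p_stage1: np.ndarray
    p_stage2: np.ndarray
    y_hat: np.ndarray
    threshold: float
    t_ms: np.ndarray
    estimated_afb: Optional[float]            # from final (stage-2) labels
    estimated_af_time_ms: Optional[float]
    severity_used: str = "NON_AFL"            # head selected at inference

    def __len__(self) -> int:
        return len(self.window_indices)
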