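"""Synthetic cohort simulator.

Generates annotated beat sequences, RR tachograms and toy single-lead ECGs
with planted rhythm episodes at a target AF burden, so the whole pipeline
is exercisable without clinical data.

RR dynamics are an AR(1) process per rhythm: the three properties an
interval-based classifier exploits — mean rate, variability and short-range
autocorrelation — are directly controllable.  Default profiles encode the
rhythm phenomenology: normal sinus rhythm is slow and regular with strong
autocorrelation; AF is irregular and nearly memoryless; atrial flutter is
fast and *more* regular than sinus rhythm (which is exactly what makes AFL
invisible to beat-interval models); atrial tachycardia is fast and fairly
regular, and serves as the negative-class confounder.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datatypes import BeatSequence, EcgRecord

RR_MIN_MS = 250.0
RR_MAX_MS = 2500.0


@dataclass(frozen=True)
class RhythmProfile:
    rhythm: str
    mean_rr_ms: float
    rr_sd_ms: float
    lag1_autocorr: float

    def __post_init__(self):
        if self.mean_rr_ms <= 200:
            raise ValueError("mean RR must exceed 200 ms")
        if self.rr_sd_ms < 0:
            raise ValueError("RR sd must be non-negative")
        if not -1.0 <= self.lag1_autocorr <= 1.0:
            raise ValueError("lag-1 autocorrelation must be in [-1, 1]")


#: Default rhythm profiles (mean RR ms, sd ms, lag-1 autocorrelation).
PROFILES = {
    "NSR": RhythmProfile("OTHER", 850.0, 40.0, 0.8),
    "AF": RhythmProfile("AF", 700.0, 150.0, 0.05),
    "AFL": RhythmProfile("AFL", 430.0, 10.0, 0.9),
    "AT": RhythmProfile("AT", 450.0, 30.0, 0.7),
}


def simulate_rr(profile: RhythmProfile, duration_s: float,
                rng: np.random.Generator, t0_ms: float = 0.0) -> BeatSequence:
    """AR(1) RR series covering ``duration_s`` seconds from ``t0_ms``.

    rr_t = mean + phi * (rr_{t-1} - mean) + eps_t, with eps scaled so the
    stationary sd equals the profile's, truncated to physiologic bounds
    [250, 2500] ms.  Every beat carries the profile's rhythm label.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(np.ceil(duration_s * 1000.0 / max(profile.mean_rr_ms - 4 * profile.rr_sd_ms,
                                              RR_MIN_MS))) + 2
    phi = profile.lag1_autocorr
    eps_sd = profile.rr_sd_ms * np.sqrt(max(1.0 - phi * phi, 0.0))
    eps = rng.normal(0.0, eps_sd, size=n) if eps_sd > 0 else np.zeros(n)
    # stationary start
    eps[0] = rng.normal(0.0, profile.rr_sd_ms) if profile.rr_sd_ms > 0 else 0.0
    rr = profile.mean_rr_ms + lfilter([1.0], [1.0, -phi], eps)
    rr = np.clip(rr, RR_MIN_MS, RR_MAX_MS)
    times = t0_ms + np.cumsum(rr)
    keep = times <= t0_ms + duration_s * 1000.0
    if not keep.any():  # duration shorter than one beat
        times, rr = times[:1], rr[:1]
    else:
        times = times[keep]
    labels = np.full(len(times), profile.rhythm, dtype="U9")
    return BeatSequence(times, labels)


def _episode_intervals(total_ms: float, target_burden: float, min_dur_ms: float,
                       max_dur_ms: float, rng: np.random.Generator) -> list:
    """Uniform random non-overlapping episode intervals, greedy to target."""
    if not 0.0 <= target_burden <= 1.0:
        raise ValueError("target burden must be in [0, 1]")
    goal = target_burden * total_ms
    if goal == 0:
        return []
    if goal >= total_ms:
        return [(0.0, total_ms)]
    if min_dur_ms > total_ms or (0 < goal < min_dur_ms and target_burden < 1):
        if goal < min_dur_ms:
            raise ValueError("target burden smaller than one minimum-length episode")
        raise ValueError("record shorter than the minimum episode duration")
    intervals: list = []
    covered = 0.0
    attempts = 0
    while attempts < 10_000:
        attempts += 1
        remaining = goal - covered
        if remaining < 0.5 * min_dur_ms:
            break
        dur = rng.uniform(min_dur_ms, max_dur_ms)
        # trim toward the target: the last episode lands on the remainder
        dur = max(min(dur, remaining), min_dur_ms)
        start = rng.uniform(0.0, total_ms - dur)
        if any(start < s + d and s < start + dur for s, d in intervals):
            continue
        intervals.append((start, dur))
        covered += dur
    if covered < goal - max(max_dur_ms, 0.5 * min_dur_ms):
        raise ValueError("could not place episodes to reach the target burden")
    return sorted(intervals)


def plant_episodes(total_s: float, episode_profile: RhythmProfile,
                   target_burden: float, rng: np.random.Generator,
                   base_profile: RhythmProfile = PROFILES["NSR"],
                   min_dur_s: float = 60.0, max_dur_s: float = 900.0,
                   record_id: str = "") -> BeatSequence:
    """NSR record of ``total_s`` seconds with planted rhythm episodes.

    Non-overlapping episodes of ``episode_profile`` replace base-rhythm
    spans until the time in episodes reaches the target burden; each
    episode lasts at least ``min_dur_s``.  Realized burden lands within
    about one episode granularity of the target (tightened by the greedy
    trimming of the last episode).
    """
    total_ms = total_s * 1000.0
    intervals = _episode_intervals(total_ms, target_burden,
                                   min_dur_s * 1000.0, max_dur_s * 1000.0, rng)
    segments = []
    cursor = 0.0
    for start, dur in intervals:
        if start > cursor:
            segments.append((base_profile, cursor, start - cursor))
        segments.append((episode_profile, start, dur))
        cursor = start + dur
    if cursor < total_ms:
        segments.append((base_profile, cursor, total_ms - cursor))
    times_all, labels_all = [], []
    t_end = 0.0
    for prof, start, dur in segments:
        seg = simulate_rr(prof, dur / 1000.0, rng, t0_ms=max(start, t_end))
        if len(seg) == 0:
            continue
        times_all.append(seg.beat_times)
        labels_all.append(seg.beat_labels)
        t_end = seg.beat_times[-1]
    times = np.concatenate(times_all)
    labels = np.concatenate(labels_all)
    order = np.argsort(times)
    return BeatSequence(times[order], labels[order], record_id)


def inject_unknown_spans(beats: BeatSequence, fraction: float,
                         rng: np.random.Generator,
                         span_s: float = 30.0) -> BeatSequence:
    """Relabel contiguous spans as UNKNOWN to exercise the exclusion rules."""
    if fraction <= 0:
        return beats
    total_ms = beats.beat_times[-1] - beats.beat_times[0]
    labels = beats.beat_labels.copy()
    goal = fraction * total_ms
    covered = 0.0
    for _ in range(1000):
        if covered >= goal:
            break
        start = rng.uniform(beats.beat_times[0], beats.beat_times[-1] - span_s * 1000)
        m = (beats.beat_times >= start) & (beats.beat_times < start + span_s * 1000)
        labels[m] = "UNKNOWN"
        covered += span_s * 1000
    return BeatSequence(beats.beat_times, labels, beats.record_id)


@dataclass
class CohortSpec:
    """Study conditions for a simulated Holter cohort.

    The default burden mixture (40% non-AF_l, 20% each mild / moderate /
    severe) populates all four severity strata, and half of the patients
    additionally carry AT episodes (~5% of record time) so the negative
    class contains fast-but-regular rhythm.
    """

    n_patients: int = 40
    duration_h: float = 2.0
    seed: int = 0
    episode_rhythm: str = "AF"
    burden_by_stratum: dict = field(default_factory=lambda: {
        "NON_AFL": 0.0, "AF_MILD": 0.02, "AF_MOD": 0.45, "AF_SEV": 0.90})
    stratum_fractions: dict = field(default_factory=lambda: {
        "NON_AFL": 0.4, "AF_MILD": 0.2, "AF_MOD": 0.2, "AF_SEV": 0.2})
    min_episode_s: float = 60.0
    max_episode_s: float = 900.0
    at_fraction_of_patients: float = 0.5
    at_burden: float = 0.05
    unknown_fraction: float = 0.0
    snr_db: Optional[float] = 20.0

    def __post_init__(self):
        for b in self.burden_by_stratum.values():
            if not 0.0 <= b <= 1.0:
                raise ValueError("burdens must lie in [0, 1]")


def make_cohort(spec: CohortSpec) -> tuple:
    """Simulate a cohort; returns (list of BeatSequence, ground-truth table).

    The ground-truth table contains, per patient: planted target burden,
    the realized label-derived AF_l burden and total AF_l time (computed
    from the generated labels with the same windowing arithmetic the
    pipeline uses, so truth and pipeline agree exactly), severity level,
    the 30-s episode-rule binary label, and strata columns (sex, age bin)
    for report testing.
    """
    from .windowing import segment_windows  # local import to avoid a cycle
    from .metrics import classify_severity

    rng = np.random.Generator(np.random.PCG64(spec.seed))
    strata = list(spec.stratum_fractions)
    counts = {s: int(round(spec.stratum_fractions[s] * spec.n_patients)) for s in strata}
    while sum(counts.values()) < spec.n_patients:
        counts[strata[0]] += 1
    while sum(counts.values()) > spec.n_patients:
        counts[max(counts, key=counts.get)] -= 1
    assignments = [s for s in strata for _ in range(counts[s])]

    episode_profile = PROFILES[spec.episode_rhythm]
    recordings, rows = [], []
    for i, stratum in enumerate(assignments):
        rid = f"synth{i:03d}"
        target = spec.burden_by_stratum[stratum]
        beats = plant_episodes(spec.duration_h * 3600.0, episode_profile, target,
                               rng, min_dur_s=spec.min_episode_s,
                               max_dur_s=spec.max_episode_s, record_id=rid)
        if spec.at_fraction_of_patients > 0 and rng.uniform() < spec.at_fraction_of_patients:
            beats = _overlay_at_episodes(beats, spec, rng)
        if spec.unknown_fraction > 0:
            beats = inject_unknown_spans(beats, spec.unknown_fraction, rng)
        rec = segment_windows(beats)
        t = np.array([w.t_ms for w in rec.windows])
        y = np.array([w.y for w in rec.windows], dtype=float)
        if t.size:
            af_time = float(np.sum(t * y))
            afb = af_time / float(t.sum())
        else:
            af_time, afb = 0.0, 0.0
        # 30-s episode rule on the planted labels (contiguous positive spans)
        longest = _longest_positive_run_ms(beats)
        rows.append({
            "record_id": rid,
            "target_burden": target,
            "true_afb": afb,
            "true_af_time_ms": af_time,
            "severity": classify_severity(af_time, afb),
            "label_30s": int(longest >= 30_000.0),
            "sex": "F" if i % 2 == 0 else "M",
            "age_bin": ("le60", "61to75", "gt75")[i % 3],
            "n_windows": int(t.size),
        })
        recordings.append(beats)
    return recordings, pd.DataFrame(rows)


def _overlay_at_episodes(beats: BeatSequence, spec: CohortSpec,
                         rng: np.random.Generator) -> BeatSequence:
    """Replace negative-rhythm spans with AT episodes (~spec.at_burden)."""
    total_ms = beats.beat_times[-1]
    at = PROFILES["AT"]
    goal = spec.at_burden * total_ms
    covered = 0.0
    times, labels = beats.beat_times, beats.beat_labels
    for _ in range(200):
        if covered >= goal:
            break
        dur = rng.uniform(spec.min_episode_s, min(spec.max_episode_s, 300.0)) * 1000.0
        start = rng.uniform(0.0, total_ms - dur)
        m = (times >= start) & (times < start + dur)
        if m.sum() == 0 or np.isin(labels[m], ("AF", "AFL")).any():
            continue
        seg = simulate_rr(at, dur / 1000.0, rng, t0_ms=start)
        times = np.concatenate([times[~m], seg.beat_times])
        labels = np.concatenate([labels[~m], seg.beat_labels])
        order = np.argsort(times)
        times, labels = times[order], labels[order]
        # enforce strict monotonicity at the seams
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, labels = times[keep], labels[keep]
        covered += dur
    return BeatSequence(times, labels, beats.record_id)


def _longest_positive_run_ms(beats: BeatSequence) -> float:
    """Longest contiguous AF_l span (summed RR of consecutive AF/AFL beats)."""
    pos = np.isin(beats.beat_labels, ("AF", "AFL"))
    if len(beats) < 2 or not pos.any():
        return 0.0
    rr = np.diff(beats.beat_times)
    run, best = 0.0, 0.0
    for i in range(1, len(beats)):
        if pos[i]:
            run += rr[i - 1]
            best = max(best, run)
        else:
            run = 0.0
    return best


def _ricker(fs: float, width_s: float = 0.08) -> np.ndarray:
    """Mexican-hat QRS template of roughly ``width_s`` total width."""
    sigma = width_s / 5.0
    t = np.arange(-2.5 * sigma, 2.5 * sigma + 1.0 / fs, 1.0 / fs)
    x = (1.0 - (t / sigma) ** 2) * np.exp(-(t ** 2) / (2 * sigma ** 2))
    return x


def simulate_ecg(beats: BeatSequence, fs: float = 200.0,
                 snr_db: Optional[float] = None,
                 seed: int = 0) -> EcgRecord:
    """Toy ECG: one QRS-like Mexican-hat pulse per beat plus white noise.

    ``snr_db=None`` disables noise.  Supports detector and signal-quality
    testing only; no P/F-wave morphology is synthesized.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    rng = np.random.Generator(np.random.PCG64(seed))
    template = _ricker(fs)
    half = len(template) // 2
    if len(beats):
        n = int(np.ceil(beats.beat_times[-1] / 1000.0 * fs)) + half + 1
    else:
        n = int(fs)  # 1 s of pure noise
    x = np.zeros(n + 2 * half)
    for t_ms in beats.beat_times:
        idx = int(round(t_ms / 1000.0 * fs)) + half
        x[idx - half:idx - half + len(template)] += template
    x = x[half:half + n]
    if snr_db is not None and len(beats):
        p_signal = float(np.mean(x ** 2))
        noise_sd = np.sqrt(p_signal / (10.0 ** (snr_db / 10.0)))
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    elif snr_db is not None:
        x = rng.normal(0.0, 0.05, size=len(x))
    return EcgRecord(x, fs=fs, lead_name="synthetic")
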