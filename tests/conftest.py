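import numpy as np
import pytest

from arnet2.datatypes import BeatSequence
from arnet2.synthetic import PROFILES, simulate_ecg, simulate_rr


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def nsr_beats(rng):
    """10 minutes of normal sinus rhythm."""
    return simulate_rr(PROFILES["NSR"], 600.0, rng)


def make_beats(rr_ms, labels=None, record_id="r0"):
    """Beat sequence from explicit RR intervals (first beat at t=0)."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(rr_ms)])
    if labels is None:
        labels = ["OTHER"] * len(times)
    return BeatSequence(times, np.asarray(labels, dtype="U9"), record_id)


@pytest.fixture
def clean_pulse_record():
    """60 identical QRS-like pulses at a regular 800 ms spacing, noise-free."""
    times = 1000.0 + np.arange(60) * 800.0
    beats = BeatSequence(times, np.full(60, "OTHER", dtype="U9"), "pulses")
    return simulate_ecg(beats, fs=200.0, snr_db=None), beats
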