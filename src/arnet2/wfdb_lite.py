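"""Compact WFDB-compatible record and annotation IO.

Covers the subset of the WFDB conventions this pipeline needs: single-
segment headers (.hea), format-16 signal files (.dat, little-endian
int16), and MIT-format annotation files carrying beat annotations whose
aux strings hold rhythm-change markers ("(AFIB", "(AFL", "(AT", ...).
A rhythm marker applies forward until the next marker; sample indices are
0-based and converted to milliseconds on read.

Written and read files round-trip bit-exactly for the supported subset.
"""
from __future__ import annotations

import os
import struct
from typing import Optional

import numpy as np

from .datatypes import BeatSequence, EcgRecord

# MIT annotation type codes used here
_CODE_NORMAL = 1
_CODE_RHYTHM = 28
# pseudo-annotation codes
_PSEUDO_SKIP = 59
_PSEUDO_NUM = 60
_PSEUDO_SUB = 61
_PSEUDO_CHN = 62
_PSEUDO_AUX = 63

#: rhythm aux string <-> beat label vocabulary
AUX_TO_LABEL = {
    "(AFIB": "AF", "(AFL": "AFL", "(AT": "AT",
    "(SVT": "OTHER_SVT", "(N": "OTHER", "(NOISE": "UNKNOWN",
}
LABEL_TO_AUX = {v: k for k, v in AUX_TO_LABEL.items()}


# ------------------------------------------------------------------ records

def write_record(path_base: str, record: EcgRecord, adc_gain: float = 200.0,
                 units: str = "mV") -> None:
    """Write ``<base>.hea`` + format-16 ``<base>.dat`` for one signal."""
    name = os.path.basename(path_base)
    digital = np.clip(np.round(record.samples * adc_gain), -32768, 32767).astype("<i2")
    with open(path_base + ".dat", "wb") as f:
        f.write(digital.tobytes())
    fs = record.fs
    fs_str = f"{fs:g}"
    with open(path_base + ".hea", "w") as f:
        f.write(f"{name} 1 {fs_str} {len(digital)}\n")
        f.write(f"{name}.dat 16 {adc_gain:g}({0})/{units} 16 0 "
                f"{int(digital[0]) if len(digital) else 0} 0 0 {record.lead_name}\n")


def read_record(path_base: str) -> EcgRecord:
    """Read a single-signal format-16 WFDB record back into physical units."""
    with open(path_base + ".hea") as f:
        lines = [ln.strip() for ln in f if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    if n_sig != 1:
        raise ValueError(f"only single-signal records supported, got {n_sig}")
    fs = float(head[2]) if len(head) > 2 else 250.0
    sig = lines[1].split()
    fname, fmt = sig[0], sig[1]
    if fmt.split("x")[0] != "16":
        raise ValueError(f"only format 16 supported, got {fmt}")
    gain_field = sig[2] if len(sig) > 2 else "200"
    gain = float(gain_field.split("(")[0].split("/")[0]) or 200.0
    lead = sig[-1] if len(sig) >= 9 else "ECG"
    data = np.fromfile(os.path.join(os.path.dirname(path_base) or ".", fname),
                       dtype="<i2")
    return EcgRecord(data.astype(float) / gain, fs=fs, lead_name=lead)


# -------------------------------------------------------------- annotations

def _encode_entry(code: int, delta: int) -> bytes:
    return struct.pack("<H", ((code & 0x3F) << 10) | (delta & 0x3FF))


def _encode_time(code: int, delta: int, out: bytearray) -> None:
    if delta > 1023 or delta < 0:
        out += _encode_entry(_PSEUDO_SKIP, 0)
        out += struct.pack("<i", delta)
        out += _encode_entry(code, 0)
    else:
        out += _encode_entry(code, delta)


def write_annotations(path: str, beats: BeatSequence, fs: float) -> None:
    """Write beats as MIT-format annotations with rhythm aux markers.

    Emits a NORMAL annotation per beat; whenever the rhythm label changes
    (or at the first beat) the annotation carries the rhythm aux string.
    """
    out = bytearray()
    prev_sample = 0
    prev_label: Optional[str] = None
    for t_ms, label in zip(beats.beat_times, beats.beat_labels):
        sample = int(round(t_ms / 1000.0 * fs))
        delta = sample - prev_sample
        _encode_time(_CODE_NORMAL, delta, out)
        prev_sample = sample
        if label != prev_label:
            aux = LABEL_TO_AUX.get(str(label), "(N").encode()
            n = len(aux)
            out += _encode_entry(_PSEUDO_AUX, n)
            out += aux
            if n % 2:
                out += b"\x00"
            prev_label = str(label)
    out += _encode_entry(0, 0)  # EOF
    with open(path, "wb") as f:
        f.write(bytes(out))


def read_annotations(path: str, fs: float, record_id: str = "") -> BeatSequence:
    """Read MIT-format annotations into a labeled beat sequence.

    Rhythm aux strings apply forward until the next rhythm marker; beats
    before the first marker are labeled UNKNOWN.
    """
    with open(path, "rb") as f:
        raw = f.read()
    times, labels = [], []
    sample = 0
    current = "UNKNOWN"
    i = 0
    pending_beat = False
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code = word >> 10
        field = word & 0x3FF
        if code == 0 and field == 0:
            break
        if code == _PSEUDO_SKIP:
            skip = struct.unpack_from("<i", raw, i)[0]
            i += 4
            sample += skip
        elif code == _PSEUDO_AUX:
            aux = raw[i:i + field].decode(errors="replace")
            i += field + (field % 2)
            label = AUX_TO_LABEL.get(aux.rstrip("\x00"))
            if label is not None:
                current = label
                if pending_beat and labels:
                    labels[-1] = current  # marker attached to this beat
        elif code in (_PSEUDO_NUM, _PSEUDO_SUB, _PSEUDO_CHN):
            continue
        else:
            sample += field
            times.append(sample / fs * 1000.0)
            labels.append(current)
            pending_beat = True
    return BeatSequence(np.asarray(times, dtype=float),
                        np.asarray(labels, dtype="U9"), record_id)


def write_wfdb(path_base: str, record: EcgRecord, beats: BeatSequence) -> None:
    write_record(path_base, record)
    write_annotations(path_base + ".atr", beats, record.fs)


def read_wfdb(path_base: str) -> tuple:
    record = read_record(path_base)
    beats = read_annotations(path_base + ".atr", record.fs,
                             record_id=os.path.basename(path_base))
    return record, beats
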