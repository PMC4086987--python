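"""Minimal reader/writer for the MIT dialect of the WFDB format.

Covers exactly what two-lead Holter records like the MIT-BIH Arrhythmia
Database use: a ``.hea`` text header, a single multiplexed ``.dat`` signal
file in format 212 (two 12-bit samples packed into 3 bytes) or format 16
(16-bit little-endian), and a ``.atr`` annotation file in the standard
MIT annotation encoding.  Writing is provided so synthetic records can
exercise the same code path as real ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

# Standard WFDB annotation code <-> mnemonic table (beat codes 1..41).
ANNOTATION_CODES: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_CODES: dict[str, int] = {v: k for k, v in ANNOTATION_CODES.items()}

# Pseudo-annotation codes carrying bookkeeping, not beats.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_MAX_INC = 1023  # largest time increment storable in a plain annotation word


@dataclass
class SignalInfo:
    file_name: str
    fmt: int
    gain: float = 200.0
    baseline: int = 0
    units: str = "mV"
    description: str = ""


@dataclass
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalInfo] = field(default_factory=list)


def _parse_fmt(token: str) -> int:
    # format token may carry xN samples-per-frame, :skew, +offset suffixes
    for sep in ("x", ":", "+"):
        token = token.split(sep)[0]
    return int(token)


def _parse_gain(token: str) -> tuple[float, int | None, str]:
    units = "mV"
    if "/" in token:
        token, units = token.split("/", 1)
    baseline = None
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(token) if token else 0.0
    if gain == 0.0:
        gain = 200.0  # WFDB convention: 0 means "assume 200 adu/mV"
    return gain, baseline, units


def read_header(path: str) -> Header:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = _parse_fmt(tok[1])
        gain, baseline, units = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, None, "mV")
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else ""
        signals.append(SignalInfo(tok[0], fmt, gain, baseline, units, description))
    return Header(name, n_sig, fs, n_samples, signals)


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_trip = len(b) // 3
    b = b[: n_trip * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_trip * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out = out[:n_values]
    out = np.where(out > 2047, out - 4096, out)
    return out


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if np.any((v < -2048) | (v > 2047)):
        raise ValueError("format 212 requires samples in [-2048, 2047]")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).reshape(-1, 2)
    out = np.empty((v.shape[0], 3), dtype=np.uint8)
    out[:, 0] = v[:, 0] & 0xFF
    out[:, 1] = ((v[:, 0] >> 8) & 0x0F) | (((v[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = v[:, 1] & 0xFF
    return out.tobytes()


def read_record(path_prefix: str) -> tuple[Header, np.ndarray]:
    """Read ``<path_prefix>.hea`` + its signal file.

    Returns the header and an ``(n_samples, n_sig)`` float array in physical
    units, i.e. ``(adu - baseline) / gain`` per channel.
    """
    header = read_header(path_prefix + ".hea")
    if not header.signals:
        raise ValueError(f"record {header.record_name}: header lists no signals")
    fnames = {s.file_name for s in header.signals}
    if len(fnames) != 1:
        raise ValueError("only single (multiplexed) signal files are supported")
    fmts = {s.fmt for s in header.signals}
    if len(fmts) != 1:
        raise ValueError("mixed signal formats are not supported")
    fmt = fmts.pop()
    dat_path = os.path.join(os.path.dirname(path_prefix), header.signals[0].file_name)
    n_values = header.n_samples * header.n_sig
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    if fmt == 212:
        flat = _decode_212(raw, n_values)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")[:n_values].astype(np.int32)
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    if flat.size < n_values:
        raise ValueError(
            f"record {header.record_name}: signal file holds {flat.size} values, "
            f"header promises {n_values}")
    digital = flat.reshape(header.n_samples, header.n_sig)
    physical = np.empty(digital.shape, dtype=float)
    for j, sig in enumerate(header.signals):
        physical[:, j] = (digital[:, j] - sig.baseline) / sig.gain
    return header, physical


def write_record(directory: str, record_name: str, signals: np.ndarray,
                 fs: float, lead_names: list[str] | tuple[str, ...],
                 fmt: int = 16, gain: float = 200.0) -> str:
    """Write ``signals`` (n_samples, n_sig), physical units, as an MIT record."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be 2-D (n_samples, n_sig)")
    n_samples, n_sig = signals.shape
    if len(lead_names) != n_sig:
        raise ValueError("one lead name per channel required")
    digital = np.rint(signals * gain).astype(np.int32)
    dat_name = record_name + ".dat"
    flat = digital.reshape(-1)  # row-major => channel-multiplexed
    if fmt == 212:
        raw = _encode_212(flat)
    elif fmt == 16:
        raw = flat.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, dat_name), "wb") as fh:
        fh.write(raw)
    lines = [f"{record_name} {n_sig} {fs:g} {n_samples}"]
    for name in lead_names:
        lines.append(f"{dat_name} {fmt} {gain:g}(0)/mV 12 0 0 0 0 {name}")
    with open(os.path.join(directory, record_name + ".hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return os.path.join(directory, record_name)


def read_annotations(path: str) -> list[tuple[int, str]]:
    """Return ``[(sample_index, symbol), ...]`` in file order."""
    data = np.fromfile(path, dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < len(data):
        word = int(data[i])
        if word == 0:  # EOF marker
            break
        code = word >> 10
        inc = word & 0x3FF
        if code == _SKIP:
            # long interval: next two words hold a 32-bit offset, high word first
            interval = (int(data[i + 1]) << 16) | int(data[i + 2])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (inc + 1) // 2
            continue
        t += inc
        out.append((t, ANNOTATION_CODES.get(code, "?")))
        i += 1
    return out


def write_annotations(path: str, samples, symbols) -> None:
    samples = list(samples)
    symbols = list(symbols)
    if len(samples) != len(symbols):
        raise ValueError("samples and symbols must have equal length")
    words: list[int] = []
    prev = 0
    for t, sym in zip(samples, symbols):
        code = SYMBOL_CODES.get(sym)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {sym!r}")
        inc = int(t) - prev
        if inc < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if inc > _MAX_INC:
            words.append(_SKIP << 10)
            words.append((inc >> 16) & 0xFFFF)
            words.append(inc & 0xFFFF)
            inc = 0
        words.append((code << 10) | inc)
        prev = int(t)
    words.append(0)
    np.asarray(words, dtype="<u2").tofile(path)
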