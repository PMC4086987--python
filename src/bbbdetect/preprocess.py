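"""Beat segmentation, per-lead z-normalization and RR intervals.

Each beat is cut symmetrically around the annotated R peak — 0.278 s on
either side, which is 100 samples per side at 360 Hz, 200 samples total —
and each lead is normalized to zero mean and unit (population) standard
deviation.  No filtering or denoising is ever applied: the raw morphology
is the feature.  The RR interval attached to a beat is the time since the
preceding studied beat's R peak, in seconds; the first beat of a record
copies the interval that follows it so every beat carries an RR value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import BeatAnnotation, NORM, LBBB, RBBB, OTHER, STUDIED_LABELS

log = logging.getLogger(__name__)

#: samples kept before / after the R peak (0.278 s at 360 Hz each side)
PRE_SAMPLES = 100
POST_SAMPLES = 100
BEAT_LENGTH = PRE_SAMPLES + POST_SAMPLES


class ZeroVarianceError(ValueError):
    """A flatline segment cannot be normalized to unit variance."""


class SegmentBoundsError(ValueError):
    """The beat window crosses the record boundary under the 'skip' policy."""


@dataclass
class Beat:
    lead_a: np.ndarray
    lead_b: np.ndarray
    rr_s: float
    label: str
    record_id: str = ""
    r_index: int = 0

    def __post_init__(self):
        self.lead_a = np.asarray(self.lead_a, dtype=float)
        self.lead_b = np.asarray(self.lead_b, dtype=float)
        if self.lead_a.shape != (BEAT_LENGTH,) or self.lead_b.shape != (BEAT_LENGTH,):
            raise ValueError(f"each lead must hold {BEAT_LENGTH} samples")
        if not self.rr_s > 0:
            raise ValueError("rr_s must be positive")
        if self.label not in STUDIED_LABELS:
            raise ValueError(f"label must be one of {STUDIED_LABELS}")

    def lead(self, which: str) -> np.ndarray:
        if which == "A":
            return self.lead_a
        if which == "B":
            return self.lead_b
        raise ValueError("lead must be 'A' or 'B'")


def segment(signal: np.ndarray, r_index: int,
            pre: int = PRE_SAMPLES, post: int = POST_SAMPLES,
            edge: str = "pad") -> np.ndarray:
    """Samples ``[r_index - pre, r_index + post)`` of ``signal``.

    Windows crossing the record boundary are edge-replicated (``edge='pad'``,
    keeps the beat stream aligned with the annotation stream) or rejected
    (``edge='skip'`` raises :class:`SegmentBoundsError`).
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    lo, hi = r_index - pre, r_index + post
    if lo >= 0 and hi <= n:
        return signal[lo:hi].copy()
    if edge == "skip":
        raise SegmentBoundsError(
            f"window [{lo}, {hi}) crosses record boundary [0, {n})")
    if edge != "pad":
        raise ValueError(f"unknown edge policy {edge!r}")
    if hi <= 0 or lo >= n or n == 0:
        raise SegmentBoundsError(
            f"window [{lo}, {hi}) lies entirely outside record [0, {n})")
    core = signal[max(lo, 0):min(hi, n)]
    return np.pad(core, (max(0, -lo), max(0, hi - n)), mode="edge")


def znormalize(seg: np.ndarray) -> np.ndarray:
    """Subtract the mean, divide by the population standard deviation."""
    seg = np.asarray(seg, dtype=float)
    if seg.size == 0:
        raise ValueError("cannot normalize an empty segment")
    sd = seg.std()  # population (divide-by-N) definition
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("flatline segment: zero variance")
    return (seg - seg.mean()) / sd


def compute_rr(r_indices, fs: float) -> np.ndarray:
    """RR interval preceding each R peak, in seconds.

    ``rr[k] = (r[k] - r[k-1]) / fs`` for k >= 1; the first beat copies the
    following interval so the output has one entry per input R peak.
    """
    r = np.asarray(r_indices, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if r.size < 2:
        raise ValueError("RR intervals undefined with fewer than 2 beats")
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_indices must be strictly ascending")
    rr = np.empty(r.size)
    rr[1:] = np.diff(r) / fs
    rr[0] = rr[1]
    return rr


def make_beats(lead_a: np.ndarray, lead_b: np.ndarray,
               annotations: list[BeatAnnotation], fs: float,
               record_id: str = "", edge: str = "pad",
               ) -> tuple[list[Beat], list[tuple[int, str]]]:
    """Build normalized two-lead beats from one annotated record.

    OTHER-labelled annotations are dropped; RR intervals are computed from
    the studied-beat R peaks only (the stream actually classified).  Returns
    the beats plus a ``(r_index, reason)`` list of skipped beats.
    """
    studied = [a for a in annotations if a.label != OTHER]
    n_other = len(annotations) - len(studied)
    skipped: list[tuple[int, str]] = []
    if len(studied) < 2:
        for a in studied:
            skipped.append((a.r_index, "fewer than 2 studied beats: RR undefined"))
        if skipped:
            log.warning("record %s: %d beat(s) skipped (no RR context)",
                        record_id, len(skipped))
        return [], skipped
    rr = compute_rr([a.r_index for a in studied], fs)
    beats: list[Beat] = []
    for a, rr_s in zip(studied, rr):
        try:
            seg_a = znormalize(segment(lead_a, a.r_index, edge=edge))
            seg_b = znormalize(segment(lead_b, a.r_index, edge=edge))
        except (SegmentBoundsError, ZeroVarianceError) as exc:
            skipped.append((a.r_index, str(exc)))
            continue
        beats.append(Beat(seg_a, seg_b, float(rr_s), a.label, record_id, a.r_index))
    if skipped:
        log.info("record %s: skipped %d beat(s): %s", record_id, len(skipped),
                 "; ".join(f"@{i}: {r}" for i, r in skipped[:5]))
    assert len(beats) + len(skipped) + n_other == len(annotations)
    return beats, skipped


# -- CSV interchange ---------------------------------------------------------
# layout: record_id, r_index, label, rr_s, a000..a199, b000..b199

def beats_to_frame(beats: list[Beat]) -> pd.DataFrame:
    a_cols = [f"a{i:03d}" for i in range(BEAT_LENGTH)]
    b_cols = [f"b{i:03d}" for i in range(BEAT_LENGTH)]
    rows = []
    for b in beats:
        row = {"record_id": b.record_id, "r_index": b.r_index,
               "label": b.label, "rr_s": b.rr_s}
        row.update(zip(a_cols, b.lead_a))
        row.update(zip(b_cols, b.lead_b))
        rows.append(row)
    return pd.DataFrame(rows, columns=["record_id", "r_index", "label", "rr_s",
                                       *a_cols, *b_cols])


def beats_to_csv(beats: list[Beat], path: str) -> None:
    beats_to_frame(beats).to_csv(path, index=False)


def beats_from_csv(path: str) -> list[Beat]:
    df = pd.read_csv(path)
    a_cols = [f"a{i:03d}" for i in range(BEAT_LENGTH)]
    b_cols = [f"b{i:03d}" for i in range(BEAT_LENGTH)]
    return [Beat(row[a_cols].to_numpy(float), row[b_cols].to_numpy(float),
                 float(row["rr_s"]), str(row["label"]),
                 str(row["record_id"]), int(row["r_index"]))
            for _, row in df.iterrows()]
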