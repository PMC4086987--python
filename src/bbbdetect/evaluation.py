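"""Confusion matrices and the Se/PP/Sp/NP/Acc metric suite.

Confusion matrices are oriented rows = reference label, columns = algorithm
label.  For each class, sensitivity Se = diag/row-total and positive
predictive value PP = diag/column-total; for the NORM class these are
conventionally reported as specificity (Sp) and negative predictive value
(NP).  Accuracy is trace/total.  A zero denominator yields an *undefined*
metric (NaN internally, rendered "-"), never 0 or 100.  Report tables round
half-up to one decimal in percent; raw fractions are always retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NORM = "NORM"
DEFAULT_LABELS = ("NORM", "LBBB", "RBBB")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero-half-up (the convention of printed
    clinical tables), not banker's rounding."""
    if not np.isfinite(x):
        return x
    f = 10.0 ** decimals
    return math.floor(x * f + 0.5) / f


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) int, rows = reference

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square, one row per label")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion(y_true, y_pred, labels=DEFAULT_LABELS) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        try:
            counts[index[t], index[p]] += 1
        except KeyError as exc:
            raise ValueError(f"unknown label {exc}") from exc
    return ConfusionMatrix(tuple(labels), counts)


@dataclass
class Metrics:
    """Per-class Se/PP (reported as Sp/NP for NORM) plus overall accuracy.

    ``per_class[label] = {"se": ..., "pp": ...}`` as fractions in [0, 1];
    NaN marks an undefined value (empty reference row / prediction column).
    """
    per_class: dict = field(default_factory=dict)
    acc: float = float("nan")

    def se(self, label: str) -> float:
        return self.per_class[label]["se"]

    def pp(self, label: str) -> float:
        return self.per_class[label]["pp"]

    # NORM's Se/PP go by their conventional names
    @property
    def sp(self) -> float:
        return self.se(NORM)

    @property
    def np_(self) -> float:
        return self.pp(NORM)

    def as_percent(self, decimals: int = 1) -> dict:
        out = {}
        for lab, m in self.per_class.items():
            out[lab] = {k: round_half_up(100 * v, decimals) for k, v in m.items()}
        out["acc"] = round_half_up(100 * self.acc, decimals)
        return out


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    counts = cm.counts
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    per_class = {}
    for i, lab in enumerate(cm.labels):
        se = counts[i, i] / row[i] if row[i] else float("nan")
        pp = counts[i, i] / col[i] if col[i] else float("nan")
        if row[i] == 0 or col[i] == 0:
            log.info("metrics: %s has an empty %s; value undefined", lab,
                     "reference row" if row[i] == 0 else "prediction column")
        per_class[lab] = {"se": se, "pp": pp}
    total = counts.sum()
    acc = counts.trace() / total if total else float("nan")
    return Metrics(per_class, float(acc))


def _metric_row(m: Metrics, labels) -> dict:
    row = {}
    for lab in labels:
        prefix = lab.lower()
        se_name = "sp" if lab == NORM else "se"
        pp_name = "np" if lab == NORM else "pp"
        row[f"{prefix}_{se_name}"] = m.se(lab)
        row[f"{prefix}_{pp_name}"] = m.pp(lab)
    row["acc"] = m.acc
    return row


def per_record_metrics(predictions: pd.DataFrame,
                       labels=DEFAULT_LABELS) -> pd.DataFrame:
    """One metrics row per record from a prediction audit table
    (columns ``record_id``, ``true``, ``final``).  Fractions, NaN where a
    class is absent from the record."""
    rows = {}
    for rid, grp in predictions.groupby("record_id", sort=True):
        cm = confusion(grp["true"], grp["final"], labels)
        rows[rid] = _metric_row(metrics_from_confusion(cm), labels)
        for lab in labels:
            rows[rid][f"n_{lab.lower()}"] = int((grp["true"] == lab).sum())
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_lead_configs(runs: dict[str, Metrics],
                         labels=DEFAULT_LABELS,
                         expected=("A", "B", "AB")) -> pd.DataFrame:
    """Side-by-side metric table over lead configurations."""
    for cfg in expected:
        if cfg not in runs:
            log.warning("lead configuration %s missing; omitted", cfg)
    rows = {cfg: _metric_row(m, labels) for cfg, m in runs.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def format_percent_table(df: pd.DataFrame, decimals: int = 1) -> str:
    """Render a fraction-valued table as percentages, "-" for undefined."""
    def fmt(v):
        if isinstance(v, float):
            if not np.isfinite(v):
                return "-"
            return f"{round_half_up(100 * v, decimals):.{decimals}f}"
        return str(v)
    shown = df[[c for c in df.columns if not c.startswith("n_")]]
    return shown.map(fmt).to_string()
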