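"""Cross-validated parameter selection on the training set.

Ten-fold, class-stratified cross-validation; the ten held-out confusion
matrices are *summed* before computing metrics (summing, rather than
averaging per-fold metrics, keeps imbalanced folds from distorting the
rates).  Two selection rules are implemented:

* WLDA (NORM vs RBBB): grid of 30 weight pairs — w1 (NORM) in 0.01..0.10
  step 0.01, w2 (RBBB) in {0.4, 0.5, 0.6} — maximizing RBBB sensitivity,
  ties broken by RBBB positive predictive value;
* linear SVM (LBBB vs RBBB): penalty C in {0.001, 0.01, 0.1, 1, 10, 100}
  maximizing the mean of the two class sensitivities, ties broken toward
  the smallest C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers
from .evaluation import ConfusionMatrix, metrics_from_confusion

log = logging.getLogger(__name__)

W1_GRID = tuple(round(0.01 * i, 2) for i in range(1, 11))  # 0.01 .. 0.10
W2_GRID = (0.4, 0.5, 0.6)
C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class CVResult:
    parameter_values: dict
    summed_confusion: ConfusionMatrix
    criterion_metrics: dict = field(default_factory=dict)


def kfold_partition(y, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: within each class, samples are shuffled
    (seeded) and dealt round-robin, so per-class fold sizes differ by at
    most one.  A class smaller than k leaves some folds without it (warned).
    """
    y = np.asarray(y)
    n = y.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for lab in np.unique(y):
        idx = np.flatnonzero(y == lab)
        if idx.size < k:
            log.warning("stratum %r has %d < k=%d samples; some folds will "
                        "lack it", str(lab), idx.size, k)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def cv_summed_confusion(X, y, fit, predict, folds, labels,
                        params: dict | None = None) -> CVResult:
    """Fit on k-1 folds, predict the held-out fold, sum the k confusion
    matrices, and derive metrics from the summed matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = np.asarray(folds)
    labels = tuple(labels)
    total = ConfusionMatrix(labels, np.zeros((len(labels),) * 2, dtype=int))
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        try:
            model = fit(X[train], y[train])
        except Exception as exc:
            raise RuntimeError(f"fold {f}: fit failed: {exc}") from exc
        pred = predict(model, X[test])
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels),) * 2, dtype=int)
        for t, p in zip(y[test], pred):
            counts[idx[t], idx[p]] += 1
        total = total + ConfusionMatrix(labels, counts)
    m = metrics_from_confusion(total)
    crit = {}
    for lab in labels:
        crit[f"se_{lab}"] = m.se(lab)
        crit[f"pp_{lab}"] = m.pp(lab)
    crit["acc"] = m.acc
    return CVResult(dict(params or {}), total, crit)


def _key(*vals) -> tuple:
    # NaN-safe lexicographic comparison key (undefined sorts below everything)
    return tuple(-np.inf if not np.isfinite(v) else v for v in vals)


def select_wlda_params(X, y, seed: int = 0, k: int = 10,
                       labels=("NORM", "RBBB"),
                       w1_grid=W1_GRID, w2_grid=W2_GRID,
                       folds=None) -> tuple[float, float, pd.DataFrame]:
    """Grid-search the WLDA weights by summed-confusion CV.

    Maximizes RBBB sensitivity; if sensitivities tie, the pair with the
    larger RBBB positive predictive value wins (first hit in grid order on
    a full tie).  Class scatters are computed once per fold and re-weighted
    across the grid, which is exact — the scatter is linear in the weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = tuple(labels)
    minority = labels[1]
    folds = kfold_partition(y, k, seed) if folds is None else np.asarray(folds)
    per_fold = []
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        means, scatters = classifiers.class_scatter(X[train], y[train], labels)
        per_fold.append((means, scatters, X[test], y[test]))
    rows = []
    best = None
    idx = {lab: i for i, lab in enumerate(labels)}
    for w1 in w1_grid:
        for w2 in w2_grid:
            counts = np.zeros((2, 2), dtype=int)
            for means, scatters, Xte, yte in per_fold:
                model = classifiers.wlda_from_scatter(means, scatters,
                                                      (w1, w2), labels)
                pred = classifiers.predict_wlda(model, Xte)
                for t, p in zip(yte, pred):
                    counts[idx[t], idx[p]] += 1
            m = metrics_from_confusion(ConfusionMatrix(labels, counts))
            row = {"w1": w1, "w2": w2,
                   f"se_{minority}": m.se(minority),
                   f"pp_{minority}": m.pp(minority),
                   f"sp_{labels[0]}": m.se(labels[0]),
                   f"np_{labels[0]}": m.pp(labels[0]),
                   "tn": counts[0, 0], "fp": counts[0, 1],
                   "fn": counts[1, 0], "tp": counts[1, 1]}
            rows.append(row)
            score = _key(m.se(minority), m.pp(minority))
            if best is None or score > best[0]:
                best = (score, w1, w2)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def select_svm_C(X, y, seed: int = 0, k: int = 10,
                 labels=("LBBB", "RBBB"), c_grid=C_GRID,
                 class_weights=(1.0, 1.0), folds=None,
                 ) -> tuple[float, pd.DataFrame]:
    """Grid-search the SVM penalty by summed-confusion CV, maximizing the
    mean of the two class sensitivities; exact ties keep the smallest C."""
    y = np.asarray(y)
    labels = tuple(labels)
    folds = kfold_partition(y, k, seed) if folds is None else np.asarray(folds)
    rows = []
    best = None
    for C in sorted(c_grid):
        res = cv_summed_confusion(
            X, y,
            fit=lambda Xt, yt, C=C: classifiers.fit_linear_svm(
                Xt, yt, C=C, class_weights=class_weights, labels=labels),
            predict=classifiers.predict_svm,
            folds=folds, labels=labels, params={"C": C})
        se0 = res.criterion_metrics[f"se_{labels[0]}"]
        se1 = res.criterion_metrics[f"se_{labels[1]}"]
        mean_se = (se0 + se1) / 2
        rows.append({"C": C, f"se_{labels[0]}": se0, f"se_{labels[1]}": se1,
                     "mean_se": mean_se,
                     f"pp_{labels[0]}": res.criterion_metrics[f"pp_{labels[0]}"],
                     f"pp_{labels[1]}": res.criterion_metrics[f"pp_{labels[1]}"]})
        score = _key(mean_se)
        if best is None or score > best[0]:  # strict: ties keep smaller C
            best = (score, C)
    return best[1], pd.DataFrame(rows)
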