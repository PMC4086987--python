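"""End-to-end training and evaluation of the three-classifier ensemble.

Wires the modules into the published protocol: select the designated
basis beats from the training set, fit one ICA basis per lead, choose the
WLDA weights and the SVM penalty by 10-fold summed-confusion CV on the
relevant class pairs, fit the three classifiers, then classify a test set
and report the confusion matrix and metric suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers, features, model_selection
from .ensemble import EnsembleModels, classify_beats
from .evaluation import ConfusionMatrix, Metrics, confusion, metrics_from_confusion
from .preprocess import Beat

log = logging.getLogger(__name__)

NORM, LBBB, RBBB = "NORM", "LBBB", "RBBB"


@dataclass
class TrainedPipeline:
    models: EnsembleModels
    w1: float
    w2: float
    C: float
    cv_wlda_table: pd.DataFrame
    cv_svm_table: pd.DataFrame
    lead_config: str = "AB"
    seed: int = 0


def _select(beats: list[Beat], *labels) -> list[Beat]:
    want = set(labels)
    return [b for b in beats if b.label in want]


def train_ensemble(train_beats: list[Beat], *, lead_config: str = "AB",
                   n_components: int = 100, basis_plan: dict | None = None,
                   seed: int = 0, k: int = 10,
                   w1_grid=model_selection.W1_GRID,
                   w2_grid=model_selection.W2_GRID,
                   c_grid=model_selection.C_GRID) -> TrainedPipeline:
    """Full training protocol on an inter-patient training set."""
    # ICA bases from the designated per-record beat selection
    basis_beats = features.select_basis_beats(train_beats, basis_plan)
    log.info("basis selection: %d beats", len(basis_beats))
    basis_a = basis_b = None
    if "A" in lead_config:
        basis_a = features.fit_ica_basis(basis_beats, "A", n_components, seed=seed)
    if "B" in lead_config:
        basis_b = features.fit_ica_basis(basis_beats, "B", n_components, seed=seed + 1)

    # centroid classifier: NORM vs LBBB on morphology features
    nl = _select(train_beats, NORM, LBBB)
    centroid = classifiers.fit_centroid(
        features.morph_matrix(nl, lead_config), features.labels_of(nl),
        labels=(NORM, LBBB))

    # WLDA: NORM vs RBBB on ICA features, weights by CV
    nr = _select(train_beats, NORM, RBBB)
    X_nr = features.ica_matrix(nr, basis_a, basis_b, lead_config)
    y_nr = features.labels_of(nr)
    w1, w2, cv_wlda = model_selection.select_wlda_params(
        X_nr, y_nr, seed=seed + 2, k=k, labels=(NORM, RBBB),
        w1_grid=w1_grid, w2_grid=w2_grid)
    wlda = classifiers.fit_wlda(X_nr, y_nr, (w1, w2), labels=(NORM, RBBB))
    log.info("selected WLDA weights: w1=%g w2=%g", w1, w2)

    # linear SVM: LBBB vs RBBB on ICA features, penalty by CV
    lr = _select(train_beats, LBBB, RBBB)
    X_lr = features.ica_matrix(lr, basis_a, basis_b, lead_config)
    y_lr = features.labels_of(lr)
    C, cv_svm = model_selection.select_svm_C(
        X_lr, y_lr, seed=seed + 3, k=k, labels=(LBBB, RBBB), c_grid=c_grid)
    svm = classifiers.fit_linear_svm(X_lr, y_lr, C=C, labels=(LBBB, RBBB))
    log.info("selected SVM penalty: C=%g", C)

    models = EnsembleModels(centroid, wlda, svm, basis_a, basis_b, lead_config)
    return TrainedPipeline(models, w1, w2, C, cv_wlda, cv_svm, lead_config, seed)


@dataclass
class EvaluationResult:
    predictions: pd.DataFrame
    confusion: ConfusionMatrix
    metrics: Metrics


def evaluate_ensemble(trained: TrainedPipeline,
                      test_beats: list[Beat]) -> EvaluationResult:
    preds = classify_beats(test_beats, trained.models)
    cm = confusion(preds["true"], preds["final"], (NORM, LBBB, RBBB))
    return EvaluationResult(preds, cm, metrics_from_confusion(cm))
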