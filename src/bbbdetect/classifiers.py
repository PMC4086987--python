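"""The three pairwise classifiers: centroid, weighted LDA, linear SVM.

Each classifier separates one pair of beat classes:

* a minimum-distance (nearest-centroid) classifier for NORM vs LBBB on
  morphology features — robust to the heavy overlap between those classes;
* a weighted linear discriminant (WLDA) for NORM vs RBBB on ICA features —
  class means m_i with a class-weighted pooled scatter matrix

      Sigma = sum_i w_i sum_k (x_ik - m_i)(x_ik - m_i)^T

  (no division by class size: the weights absorb scale), softmax posteriors
  over the linear discriminants

      g_i(x) = m_i^T Sigma^{-1} x - (1/2) m_i^T Sigma^{-1} m_i + log P(w_i)

  with equal priors P = 0.5, assigning the class of maximum posterior;
* an L2-regularized hinge-loss linear SVM (liblinear) for LBBB vs RBBB,
  optionally with per-class penalty weights for imbalanced pairs.

All exact ties resolve to NORM when NORM is one of the pair's labels (the
dominant class in the corpus), else to the first label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

log = logging.getLogger(__name__)

NORM = "NORM"


def _tie_label(labels) -> str:
    return NORM if NORM in labels else labels[0]


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _check_binary(y: np.ndarray, labels) -> tuple[str, str]:
    if labels is None:
        labels = tuple(sorted(set(y)))
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    for lab in labels:
        if not np.any(y == lab):
            raise ValueError(f"class {lab!r} absent from training data")
    return tuple(labels)


# -- minimum-distance classifier --------------------------------------------

@dataclass
class CentroidModel:
    class_labels: tuple[str, str]
    centroids: np.ndarray  # (2, d)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != 2 or not np.all(np.isfinite(self.centroids)):
            raise ValueError("need two finite centroids of equal dimension")


def fit_centroid(X: np.ndarray, y, labels=None) -> CentroidModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = _check_binary(y, labels)
    cents = np.stack([X[y == lab].mean(axis=0) for lab in labels])
    return CentroidModel(labels, cents)


def predict_centroid(model: CentroidModel, x: np.ndarray):
    """Label of the nearer centroid (Euclidean); exact ties -> NORM."""
    X, single = _as_2d(x)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension does not match centroids")
    d0 = np.linalg.norm(X - model.centroids[0], axis=1)
    d1 = np.linalg.norm(X - model.centroids[1], axis=1)
    tie = _tie_label(model.class_labels)
    out = np.where(d0 < d1, model.class_labels[0],
                   np.where(d1 < d0, model.class_labels[1], tie))
    return out[0] if single else out


# -- weighted linear discriminant -------------------------------------------

@dataclass
class WLDAModel:
    class_labels: tuple[str, str]
    means: np.ndarray      # (2, d)
    sigma: np.ndarray      # (d, d) weighted pooled scatter
    sigma_inv: np.ndarray
    weights: tuple[float, float]
    priors: tuple[float, float] = (0.5, 0.5)
    ridge_eps: float = 0.0

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.sigma_inv = np.asarray(self.sigma_inv, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


def class_scatter(X: np.ndarray, y, labels) -> tuple[np.ndarray, list[np.ndarray]]:
    """Class means and unweighted within-class scatter matrices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    means, scatters = [], []
    for lab in labels:
        Xi = X[y == lab]
        m = Xi.mean(axis=0)
        D = Xi - m
        means.append(m)
        scatters.append(D.T @ D)
    return np.stack(means), scatters


def wlda_from_scatter(means: np.ndarray, scatters, w, labels,
                      priors=(0.5, 0.5), ridge: bool = True) -> WLDAModel:
    """Assemble a WLDA model from precomputed class scatters (the weighted
    grid search reuses the scatters and only re-weights here)."""
    if not all(wi > 0 for wi in w):
        raise ValueError("weights must be positive")
    sigma = w[0] * scatters[0] + w[1] * scatters[1]
    sigma = (sigma + sigma.T) / 2
    d = sigma.shape[0]
    eps = 0.0
    if d == 1:
        singular = sigma[0, 0] == 0
    else:
        singular = not np.isfinite(np.linalg.cond(sigma)) or \
            np.linalg.cond(sigma) > 1e12
    if singular:
        if not ridge:
            raise np.linalg.LinAlgError("singular scatter matrix, ridge disabled")
        scale = np.trace(sigma) / d
        eps = 1e-6 * scale if scale > 1e-12 else 1e-6
        log.warning("WLDA: singular scatter, adding ridge eps=%.3g", eps)
        sigma = sigma + eps * np.eye(d)
    sigma_inv = np.linalg.inv(sigma)
    return WLDAModel(tuple(labels), means, sigma, sigma_inv,
                     tuple(float(wi) for wi in w), tuple(priors), eps)


def fit_wlda(X: np.ndarray, y, w, priors=(0.5, 0.5), labels=None,
             ridge: bool = True) -> WLDAModel:
    """Fit the weighted linear discriminant (weighted pooled scatter,
    class means, equal priors by default)."""
    y = np.asarray(y)
    labels = _check_binary(y, labels)
    means, scatters = class_scatter(X, y, labels)
    return wlda_from_scatter(means, scatters, w, labels, priors, ridge)


def wlda_discriminants(model: WLDAModel, X: np.ndarray) -> np.ndarray:
    M = model.means
    A = model.sigma_inv @ M.T                      # (d, 2)
    lin = X @ A                                    # (n, 2)
    const = -0.5 * np.einsum("id,di->i", M, A) + np.log(model.priors)
    return lin + const


def wlda_posterior(model: WLDAModel, x: np.ndarray):
    """Softmax posteriors over the two discriminants (max-subtracted)."""
    X, single = _as_2d(x)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature vector")
    g = wlda_discriminants(model, X)
    g = g - g.max(axis=1, keepdims=True)
    e = np.exp(g)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


def predict_wlda(model: WLDAModel, x: np.ndarray):
    X, single = _as_2d(x)
    p = wlda_posterior(model, X)
    tie = _tie_label(model.class_labels)
    out = np.where(p[:, 0] > p[:, 1], model.class_labels[0],
                   np.where(p[:, 1] > p[:, 0], model.class_labels[1], tie))
    return out[0] if single else out


# -- linear SVM ---------------------------------------------------------------

@dataclass
class LinearSVMModel:
    class_labels: tuple[str, str]   # (negative side, positive side)
    weight_vector: np.ndarray
    bias: float
    penalty_C: float
    class_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        if not np.all(np.isfinite(self.weight_vector)):
            raise ValueError("weight vector must be finite")
        if not self.penalty_C > 0:
            raise ValueError("penalty C must be positive")


def fit_linear_svm(X: np.ndarray, y, C: float = 1.0,
                   class_weights=(1.0, 1.0), labels=None,
                   max_iter: int = 20000, seed: int = 0,
                   strict: bool = False) -> LinearSVMModel:
    """L2-regularized hinge-loss linear classifier with per-class penalty
    ``C * class_weights[i]`` (the liblinear formulation).  Deterministic for
    fixed inputs and seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = _check_binary(y, labels)
    # sklearn orders classes lexicographically; keep our label order aligned
    order = tuple(sorted(labels))
    cw = dict(zip(labels, class_weights))
    svc = LinearSVC(C=C, class_weight=cw, max_iter=max_iter,
                    random_state=seed, dual="auto")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        svc.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        msg = (f"linear SVM (C={C}) did not converge within {max_iter} "
               f"iterations (n_iter={getattr(svc, 'n_iter_', '?')})")
        if strict:
            raise RuntimeError(msg)
        log.warning(msg)
    neg, pos = svc.classes_  # decision > 0 -> classes_[1]
    return LinearSVMModel((str(neg), str(pos)), svc.coef_.ravel(),
                          float(svc.intercept_[0]), C,
                          (float(cw[str(neg)]), float(cw[str(pos)])))


def svm_decision(model: LinearSVMModel, x: np.ndarray):
    X, single = _as_2d(x)
    if X.shape[1] != model.weight_vector.shape[0]:
        raise ValueError("feature dimension does not match hyperplane")
    d = X @ model.weight_vector + model.bias
    return d[0] if single else d


def predict_svm(model: LinearSVMModel, x: np.ndarray):
    """Sign of the decision function; a decision of exactly 0 -> NORM if
    NORM is one of the labels, else the first label."""
    X, single = _as_2d(x)
    d = svm_decision(model, X)
    tie = _tie_label(model.class_labels)
    out = np.where(d > 0, model.class_labels[1],
                   np.where(d < 0, model.class_labels[0], tie))
    return out[0] if single else out


# -- serialization -----------------------------------------------------------

def save_model(model, path: str) -> None:
    """JSON round-trip serialization for any of the three model types."""
    if isinstance(model, CentroidModel):
        payload = {"type": "centroid", "class_labels": list(model.class_labels),
                   "centroids": model.centroids.tolist()}
    elif isinstance(model, WLDAModel):
        payload = {"type": "wlda", "class_labels": list(model.class_labels),
                   "means": model.means.tolist(), "sigma": model.sigma.tolist(),
                   "sigma_inv": model.sigma_inv.tolist(),
                   "weights": list(model.weights), "priors": list(model.priors),
                   "ridge_eps": model.ridge_eps}
    elif isinstance(model, LinearSVMModel):
        payload = {"type": "svm", "class_labels": list(model.class_labels),
                   "weight_vector": model.weight_vector.tolist(),
                   "bias": model.bias, "penalty_C": model.penalty_C,
                   "class_weights": list(model.class_weights)}
    else:
        raise TypeError(f"unknown model type {type(model)}")
    payload["version"] = 1
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str):
    with open(path) as fh:
        p = json.load(fh)
    t = p["type"]
    labels = tuple(p["class_labels"])
    if t == "centroid":
        return CentroidModel(labels, np.asarray(p["centroids"]))
    if t == "wlda":
        return WLDAModel(labels, np.asarray(p["means"]), np.asarray(p["sigma"]),
                         np.asarray(p["sigma_inv"]), tuple(p["weights"]),
                         tuple(p["priors"]), p["ridge_eps"])
    if t == "svm":
        return LinearSVMModel(labels, np.asarray(p["weight_vector"]), p["bias"],
                              p["penalty_C"], tuple(p["class_weights"]))
    raise ValueError(f"unknown serialized model type {t!r}")
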