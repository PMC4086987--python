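"""Feature construction: raw morphology vectors and ICA-basis projections.

Two representations feed the three classifiers.  The morphology vector
concatenates the normalized 200-sample waveforms of the selected leads with
the RR interval (401-dim for two leads).  The ICA representation projects
each lead onto a basis of independent component waveforms learned once, per
lead, from a designated subset of training beats: with the study corpus,
10 normal beats from each of the 18 training records containing them, 100
LBBB beats from each of 2 records and 80 RBBB beats from each of 3 records
— 620 beats in all — from which 100 components are extracted by FastICA.
A beat's features are its least-squares coordinates in that basis, i.e. the
beat row-vector times the Moore–Penrose pseudo-inverse of the component
matrix, giving a 201-dim vector for two leads (2 x 100 + RR).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import Beat, BEAT_LENGTH

log = logging.getLogger(__name__)

MORPH = "MORPH"
ICA = "ICA"

#: per-record beat quota used to pick the basis-fitting subset
DEFAULT_BASIS_PLAN = {"NORM": 10, "LBBB": 100, "RBBB": 80}


@dataclass
class ICABasis:
    """Per-lead independent component basis (rows are component waveforms)."""
    lead: str
    components: np.ndarray          # (n_components, BEAT_LENGTH)
    pinv_components: np.ndarray     # (BEAT_LENGTH, n_components), cached
    fit_seed: int
    n_train_beats: int
    n_iter: int = 0

    def __post_init__(self):
        if self.lead not in ("A", "B"):
            raise ValueError("lead must be 'A' or 'B'")
        self.components = np.asarray(self.components, dtype=float)
        self.pinv_components = np.asarray(self.pinv_components, dtype=float)
        if not np.all(np.isfinite(self.components)):
            raise ValueError("components must be finite")
        resid = self.components @ self.pinv_components @ self.components - self.components
        if np.linalg.norm(resid) > 1e-6 * np.linalg.norm(self.components):
            raise ValueError("pinv_components is not a pseudo-inverse of components")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str) -> None:
        payload = {"version": 1, "lead": self.lead, "fit_seed": self.fit_seed,
                   "n_train_beats": self.n_train_beats, "n_iter": self.n_iter,
                   "components": self.components.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "ICABasis":
        with open(path) as fh:
            p = json.load(fh)
        comps = np.asarray(p["components"], dtype=float)
        return cls(p["lead"], comps, np.linalg.pinv(comps),
                   p["fit_seed"], p["n_train_beats"], p.get("n_iter", 0))


@dataclass
class FeatureVector:
    kind: str                       # MORPH or ICA
    values: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in (MORPH, ICA):
            raise ValueError(f"unknown feature kind {self.kind!r}")


def select_basis_beats(beats: list[Beat],
                       plan: dict[str, int] | None = None) -> list[Beat]:
    """Pick the basis-fitting subset: for each class, the first ``plan[label]``
    beats (in temporal order) from every record containing that class.

    With the study training set and the default 10/100/80 plan this yields
    the designated 620 beats (180 NORM + 200 LBBB + 240 RBBB).
    """
    plan = DEFAULT_BASIS_PLAN if plan is None else plan
    by_record: dict[str, dict[str, list[Beat]]] = {}
    for b in sorted(beats, key=lambda b: (b.record_id, b.r_index)):
        by_record.setdefault(b.record_id, {}).setdefault(b.label, []).append(b)
    selected: list[Beat] = []
    for rid in sorted(by_record):
        for label, quota in plan.items():
            pool = by_record[rid].get(label, [])
            if not pool:
                continue
            if len(pool) < quota:
                raise ValueError(
                    f"record {rid} has only {len(pool)} {label} beats; "
                    f"{quota} required (shortfall {quota - len(pool)})")
            selected.extend(pool[:quota])
    return selected


def fit_ica_basis(beats: list[Beat], lead: str, n_components: int = 100,
                  seed: int = 0, max_iter: int = 1000, tol: float = 1e-4,
                  strict: bool = False) -> ICABasis:
    """Learn an independent component basis from one lead of the given beats.

    FastICA with deflation (one-by-one) extraction and the tanh/log-cosh
    contrast, after PCA whitening to ``n_components`` dimensions.  The basis
    rows are the component waveforms (the mixing directions), so projection
    through their pseudo-inverse recovers the per-beat source activations.
    Reproducible for a fixed seed.  Components that have not converged after
    ``max_iter`` iterations raise if ``strict`` else are logged and kept.
    """
    X = np.stack([b.lead(lead) for b in beats])
    if X.shape[0] < n_components:
        raise ValueError(f"need >= {n_components} beats, got {X.shape[0]}")
    ica = FastICA(n_components=n_components, algorithm="deflation",
                  fun="logcosh", whiten="unit-variance",
                  max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X)
    n_iter = int(np.max(ica.n_iter_)) if np.ndim(ica.n_iter_) else int(ica.n_iter_)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        msg = (f"FastICA (lead {lead}): some components did not converge "
               f"within {max_iter} iterations (last n_iter={n_iter}, tol={tol})")
        if strict:
            raise RuntimeError(msg)
        log.warning(msg)
    components = ica.mixing_.T  # rows = component waveforms, (n_comp, 200)
    return ICABasis(lead, components, np.linalg.pinv(components),
                    seed, X.shape[0], n_iter)


def ica_project(seg: np.ndarray, basis: ICABasis) -> np.ndarray:
    """Least-squares coordinates of a 200-sample segment in the basis rows."""
    seg = np.asarray(seg, dtype=float)
    if seg.shape[-1] != basis.pinv_components.shape[0]:
        raise ValueError(
            f"segment length {seg.shape[-1]} does not match basis "
            f"({basis.pinv_components.shape[0]})")
    return seg @ basis.pinv_components


def assemble_morph(beat: Beat, lead_config: str = "AB") -> FeatureVector:
    """Morphology + RR vector: 401-dim for two leads, 201-dim for one."""
    parts = [beat.lead(lead) for lead in lead_config]
    parts.append([beat.rr_s])
    return FeatureVector(MORPH, np.concatenate(parts), beat.label)


def assemble_ica(beat: Beat, basis_a: ICABasis | None = None,
                 basis_b: ICABasis | None = None,
                 lead_config: str = "AB") -> FeatureVector:
    """ICA-projection + RR vector: 201-dim for two leads, 101-dim for one."""
    bases = {"A": basis_a, "B": basis_b}
    parts = []
    for lead in lead_config:
        basis = bases[lead]
        if basis is None:
            raise ValueError(f"no basis supplied for lead {lead}")
        if basis.lead != lead:
            raise ValueError(f"basis fitted on lead {basis.lead}, need {lead}")
        parts.append(ica_project(beat.lead(lead), basis))
    parts.append([beat.rr_s])
    return FeatureVector(ICA, np.concatenate(parts), beat.label)


# -- bulk helpers (same math as the per-beat ops, batched) -------------------

def morph_matrix(beats: list[Beat], lead_config: str = "AB") -> np.ndarray:
    cols = [np.stack([b.lead(lead) for b in beats]) for lead in lead_config]
    cols.append(np.array([[b.rr_s] for b in beats]))
    return np.hstack(cols)


def ica_matrix(beats: list[Beat], basis_a: ICABasis | None = None,
               basis_b: ICABasis | None = None,
               lead_config: str = "AB") -> np.ndarray:
    bases = {"A": basis_a, "B": basis_b}
    cols = []
    for lead in lead_config:
        basis = bases[lead]
        if basis is None or basis.lead != lead:
            raise ValueError(f"missing or mismatched basis for lead {lead}")
        cols.append(np.stack([b.lead(lead) for b in beats]) @ basis.pinv_components)
    cols.append(np.array([[b.rr_s] for b in beats]))
    return np.hstack(cols)


def labels_of(beats: list[Beat]) -> np.ndarray:
    return np.array([b.label for b in beats])
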