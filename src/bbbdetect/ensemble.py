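"""Majority-vote fusion of the three one-vs-one decisions.

Each test beat receives three votes — centroid (NORM vs LBBB, morphology
features), weighted LDA (NORM vs RBBB, ICA features) and linear SVM
(LBBB vs RBBB, ICA features).  Any label with at least two votes wins;
when the three votes are pairwise distinct the beat defaults to NORM,
the overwhelmingly most frequent class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classifiers, features
from .preprocess import Beat

NORM, LBBB, RBBB = "NORM", "LBBB", "RBBB"


@dataclass
class VoteTriple:
    v1: str  # centroid, NORM vs LBBB
    v2: str  # WLDA, NORM vs RBBB
    v3: str  # SVM, LBBB vs RBBB

    def __post_init__(self):
        if self.v1 not in (NORM, LBBB):
            raise ValueError(f"v1 must be NORM or LBBB, got {self.v1!r}")
        if self.v2 not in (NORM, RBBB):
            raise ValueError(f"v2 must be NORM or RBBB, got {self.v2!r}")
        if self.v3 not in (LBBB, RBBB):
            raise ValueError(f"v3 must be LBBB or RBBB, got {self.v3!r}")


def majority(votes, tie_break: str) -> str:
    """Label with >= 2 votes; all pairwise distinct -> ``tie_break``."""
    votes = tuple(votes)
    for lab in votes:
        if votes.count(lab) >= 2:
            return lab
    return tie_break


def vote(t: VoteTriple, tie_break: str = NORM) -> str:
    """Majority label of the triple; three distinct labels -> ``tie_break``."""
    return majority((t.v1, t.v2, t.v3), tie_break)


@dataclass
class EnsembleModels:
    centroid: classifiers.CentroidModel
    wlda: classifiers.WLDAModel
    svm: classifiers.LinearSVMModel
    basis_a: features.ICABasis | None = None
    basis_b: features.ICABasis | None = None
    lead_config: str = "AB"

    def __post_init__(self):
        for lead in self.lead_config:
            basis = self.basis_a if lead == "A" else self.basis_b
            if basis is None or basis.lead != lead:
                raise ValueError(f"lead config {self.lead_config!r} requires "
                                 f"a fitted basis for lead {lead}")


def classify_beat(beat: Beat, models: EnsembleModels) -> tuple[str, VoteTriple]:
    """Assemble both feature vectors, query the three classifiers, vote."""
    morph = features.assemble_morph(beat, models.lead_config).values
    ica = features.assemble_ica(beat, models.basis_a, models.basis_b,
                                models.lead_config).values
    t = VoteTriple(classifiers.predict_centroid(models.centroid, morph),
                   classifiers.predict_wlda(models.wlda, ica),
                   classifiers.predict_svm(models.svm, ica))
    return vote(t), t


def classify_beats(beats: list[Beat], models: EnsembleModels) -> pd.DataFrame:
    """Batched classification; one audit row per beat with the raw votes."""
    if not beats:
        return pd.DataFrame(columns=["record_id", "r_index", "true",
                                     "v1", "v2", "v3", "final"])
    morph = features.morph_matrix(beats, models.lead_config)
    ica = features.ica_matrix(beats, models.basis_a, models.basis_b,
                              models.lead_config)
    v1 = classifiers.predict_centroid(models.centroid, morph)
    v2 = classifiers.predict_wlda(models.wlda, ica)
    v3 = classifiers.predict_svm(models.svm, ica)
    final = [vote(VoteTriple(a, b, c)) for a, b, c in zip(v1, v2, v3)]
    return pd.DataFrame({
        "record_id": [b.record_id for b in beats],
        "r_index": [b.r_index for b in beats],
        "true": [b.label for b in beats],
        "v1": v1, "v2": v2, "v3": v3, "final": final,
    })
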