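"""Synthetic two-lead heartbeat generator with class-dependent morphology.

Generates labeled 200-sample two-lead beats so the whole pipeline is
testable without any ECG download.  Templates are sums of Gaussian bumps
sketching the qualitative class morphologies: a normal beat has a narrow
central QRS with P and T waves; an LBBB beat a widened, notched QRS with a
discordant T; an RBBB beat an rSR'-like late secondary deflection in lead A
and a wide slurred S in lead B.  These are controllable class geometries,
not physiological simulations.

Inter-individual variation — the dominant difficulty of inter-patient
classification — is emulated by "virtual patients": every patient carries a
fixed random perturbation of the bump amplitudes and centers, shared by all
of that patient's beats; training and test subsets use disjoint patients.
Beats add white Gaussian noise and a per-beat amplitude jitter before the
standard per-lead z-normalization; RR intervals are drawn per class from a
truncated normal.

Defaults mirror the study conditions at roughly one-twelfth scale: each of
the train and test subsets holds 3000/300/300 NORM/LBBB/RBBB beats (the
corpus' ~10:1:1 imbalance) over 18/2/3 virtual patients, matching the
record structure that the 10/100/80-per-record basis-selection plan expects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import _mitdb
from .preprocess import Beat, BEAT_LENGTH, znormalize

NORM, LBBB, RBBB = "NORM", "LBBB", "RBBB"
LABELS = (NORM, LBBB, RBBB)
_SYMBOL = {NORM: "N", LBBB: "L", RBBB: "R"}


@dataclass(frozen=True)
class Bump:
    center: float   # sample index within the 200-sample window
    width: float    # Gaussian sigma, samples
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bump width must be positive")


def default_templates() -> dict[str, dict[str, tuple[Bump, ...]]]:
    """Per-class, per-lead bump sets (R peak sits at sample 100)."""
    return {
        NORM: {
            "A": (Bump(55, 6, 0.15), Bump(95, 2.5, -0.20), Bump(100, 3, 1.00),
                  Bump(106, 2.5, -0.25), Bump(150, 12, 0.30)),
            "B": (Bump(55, 6, 0.10), Bump(100, 3, 0.60), Bump(107, 3, -0.35),
                  Bump(150, 12, 0.25)),
        },
        LBBB: {  # widened, notched complex; discordant T
            "A": (Bump(55, 6, 0.12), Bump(95, 7, 0.70), Bump(110, 7, 0.80),
                  Bump(160, 12, -0.30)),
            "B": (Bump(55, 6, 0.10), Bump(100, 9, -0.90), Bump(113, 7, -0.40),
                  Bump(160, 12, 0.30)),
        },
        RBBB: {  # rSR' in lead A, wide slurred S in lead B
            "A": (Bump(55, 6, 0.15), Bump(94, 3, 0.40), Bump(101, 3, -0.50),
                  Bump(112, 4, 0.90), Bump(155, 10, -0.25)),
            "B": (Bump(55, 6, 0.12), Bump(98, 3, 0.80), Bump(112, 8, -0.50),
                  Bump(150, 12, 0.25)),
        },
    }


#: per-class RR interval distribution (mean, sd) in seconds
DEFAULT_RR = {NORM: (0.80, 0.05), LBBB: (0.85, 0.06), RBBB: (0.75, 0.05)}


@dataclass
class GeneratorConfig:
    n_train: tuple[int, int, int] = (3000, 300, 300)   # NORM, LBBB, RBBB
    n_test: tuple[int, int, int] = (3000, 300, 300)
    n_patients_train: tuple[int, int, int] = (18, 2, 3)
    n_patients_test: tuple[int, int, int] = (18, 2, 3)
    templates: dict = field(default_factory=default_templates)
    rr: dict = field(default_factory=lambda: dict(DEFAULT_RR))
    noise_sd: float = 0.15
    amplitude_jitter_sd: float = 0.10
    patient_amp_sd: float = 0.10
    patient_shift_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("noise/jitter standard deviations must be >= 0")
        for lab, (mu, sd) in self.rr.items():
            if not mu > 3 * sd:
                raise ValueError(f"{lab}: rr mean must exceed 3x rr sd")

    @classmethod
    def from_proportions(cls, n_total: int, proportions=(10 / 12, 1 / 12, 1 / 12),
                         **kwargs) -> "GeneratorConfig":
        if abs(sum(proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        n = tuple(int(round(n_total * p)) for p in proportions)
        return cls(n_train=n, n_test=n, **kwargs)


def render_template(bumps) -> np.ndarray:
    t = np.arange(BEAT_LENGTH, dtype=float)
    out = np.zeros(BEAT_LENGTH)
    for b in bumps:
        out += b.amplitude * np.exp(-0.5 * ((t - b.center) / b.width) ** 2)
    return out


def _patient_effect(bumps, config: GeneratorConfig, rng) -> tuple[Bump, ...]:
    """A patient's fixed template perturbation: per-bump amplitude scaling
    and center shift, drawn once and reused for all of that patient's beats."""
    return tuple(
        replace(b,
                amplitude=b.amplitude * (1 + config.patient_amp_sd * rng.standard_normal()),
                center=b.center + config.patient_shift_sd * rng.standard_normal())
        for b in bumps)


def _draw_rr(label: str, config: GeneratorConfig, rng) -> float:
    mu, sd = config.rr[label]
    while True:
        rr = mu + sd * rng.standard_normal()
        if rr > 0:
            return rr


def sample_beat(label: str, config: GeneratorConfig, rng,
                patient_bumps: dict[str, tuple[Bump, ...]] | None = None,
                record_id: str = "", r_index: int = 0) -> Beat:
    """One beat: (possibly patient-perturbed) template + amplitude jitter +
    white noise, z-normalized per lead; RR drawn from the class distribution."""
    bumps = patient_bumps if patient_bumps is not None else config.templates[label]
    leads = []
    for lead in ("A", "B"):
        wave = render_template(bumps[lead])
        wave = wave * (1 + config.amplitude_jitter_sd * rng.standard_normal())
        wave = wave + config.noise_sd * rng.standard_normal(BEAT_LENGTH)
        leads.append(znormalize(wave))
    return Beat(leads[0], leads[1], _draw_rr(label, config, rng),
                label, record_id, r_index)


def _subset(config: GeneratorConfig, n_by_class, n_patients_by_class,
            prefix: str, rng) -> list[Beat]:
    beats: list[Beat] = []
    for label, n, n_pat in zip(LABELS, n_by_class, n_patients_by_class):
        if n == 0:
            continue
        if n_pat <= 0:
            raise ValueError(f"{label}: need at least one patient")
        base = n // n_pat
        sizes = [base + (1 if i < n % n_pat else 0) for i in range(n_pat)]
        for i, size in enumerate(sizes):
            rid = f"{prefix}{label[0].lower()}{i + 1:02d}"
            patient_bumps = {
                lead: _patient_effect(config.templates[label][lead], config, rng)
                for lead in ("A", "B")}
            r_index = 180
            for _ in range(size):
                b = sample_beat(label, config, rng, patient_bumps, rid, r_index)
                beats.append(b)
                r_index += int(round(b.rr_s * 360))
    return beats


def generate_dataset(config: GeneratorConfig) -> tuple[list[Beat], list[Beat]]:
    """Labeled (train, test) beat lists over disjoint virtual patients.

    Deterministic for a fixed config seed; the train and test subsets draw
    independent patient effects, so the split is inter-patient-like.
    """
    rng = np.random.default_rng(config.seed)
    train = _subset(config, config.n_train, config.n_patients_train, "tr-", rng)
    test = _subset(config, config.n_test, config.n_patients_test, "te-", rng)
    return train, test


def write_wfdb_record(directory: str, record_id: str, labels: list[str],
                      config: GeneratorConfig, rng, fs: float = 360.0,
                      extra_symbols: dict[int, str] | None = None) -> str:
    """Render one virtual patient as a continuous two-lead record in the MIT
    on-disk format (header + format-16 signal + annotations), so the loader
    and segmentation run the same path as on real data.

    ``extra_symbols`` optionally injects non-beat annotations at given beat
    positions (symbol overrides, e.g. 'V'), to exercise OTHER handling.
    """
    patient_bumps = {
        lab: {lead: _patient_effect(config.templates[lab][lead], config, rng)
              for lead in ("A", "B")}
        for lab in set(labels)}
    r_positions = []
    r = 180
    for lab in labels:
        r_positions.append(r)
        r += int(round(_draw_rr(lab, config, rng) * fs))
    n_samples = r_positions[-1] + BEAT_LENGTH
    sig = config.noise_sd * rng.standard_normal((n_samples, 2))
    for lab, pos in zip(labels, r_positions):
        for j, lead in enumerate(("A", "B")):
            wave = render_template(patient_bumps[lab][lead])
            wave = wave * (1 + config.amplitude_jitter_sd * rng.standard_normal())
            sig[pos - 100:pos + 100, j] += wave
    prefix = _mitdb.write_record(directory, record_id, sig, fs, ("LeadA", "LeadB"))
    symbols = [_SYMBOL[lab] for lab in labels]
    if extra_symbols:
        for i, sym in extra_symbols.items():
            symbols[i] = sym
    _mitdb.write_annotations(os.path.join(directory, record_id + ".atr"),
                             r_positions, symbols)
    return prefix


def write_wfdb_dataset(directory: str, config: GeneratorConfig,
                       fs: float = 360.0) -> tuple[list[str], list[str]]:
    """Materialize the default train/test subsets as on-disk records, one
    per virtual patient; returns the (train, test) record id lists."""
    rng = np.random.default_rng(config.seed)
    ids: dict[str, list[str]] = {"train": [], "test": []}
    for subset, n_by_class, n_pat_by_class, prefix in (
            ("train", config.n_train, config.n_patients_train, "tr-"),
            ("test", config.n_test, config.n_patients_test, "te-")):
        for label, n, n_pat in zip(LABELS, n_by_class, n_pat_by_class):
            if n == 0:
                continue
            base = n // n_pat
            sizes = [base + (1 if i < n % n_pat else 0) for i in range(n_pat)]
            for i, size in enumerate(sizes):
                rid = f"{prefix}{label[0].lower()}{i + 1:02d}"
                write_wfdb_record(directory, rid, [label] * size, config, rng, fs)
                ids[subset].append(rid)
    return ids["train"], ids["test"]
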