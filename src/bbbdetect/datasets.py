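"""Record loading, label mapping and the inter-patient record division.

The study corpus is two-lead Holter data with reference beat annotations
(the MIT-BIH Arrhythmia Database in the original work).  Three beat classes
are studied — normal sinus beats (NORM) and left/right bundle branch block
beats (LBBB/RBBB); every other annotation symbol is retained as OTHER at
load time and filtered later, so RR context stays available if wanted.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _mitdb

NORM, LBBB, RBBB, OTHER = "NORM", "LBBB", "RBBB", "OTHER"
STUDIED_LABELS = (NORM, LBBB, RBBB)

#: default annotation-symbol -> class mapping (MIT-BIH mnemonics)
DEFAULT_SYMBOL_MAP = {"N": NORM, "L": LBBB, "R": RBBB}


@dataclass
class RecordSpec:
    record_id: str
    lead_names: tuple[str, str] = ("", "")  # empty = first two channels
    sampling_rate_hz: float = 360.0

    def __post_init__(self):
        if len(self.lead_names) != 2:
            raise ValueError("exactly two leads required")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


@dataclass
class BeatAnnotation:
    r_index: int
    symbol: str
    label: str

    def __post_init__(self):
        if self.r_index < 0:
            raise ValueError("r_index must be non-negative")


@dataclass
class DatasetSplit:
    ds1_records: list[str]
    ds2_records: list[str]
    excluded_records: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.ds1_records) & set(self.ds2_records):
            raise ValueError("DS1 and DS2 must be disjoint")
        all_ids = self.ds1_records + self.ds2_records + self.excluded_records
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("a record appears in more than one list")


def map_beat_label(symbol: str, symbol_map: dict[str, str] | None = None) -> str:
    """Total, deterministic mapping of an annotation symbol to a class."""
    table = DEFAULT_SYMBOL_MAP if symbol_map is None else symbol_map
    return table.get(symbol, OTHER)


def _load_config(config_path: str | None = None) -> dict:
    if config_path is None:
        ref = importlib.resources.files("bbbdetect") / "data" / "mitdb_split.yaml"
        text = ref.read_text()
    else:
        with open(config_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def default_split(config_path: str | None = None) -> DatasetSplit:
    """The canonical 22/22 training/test record division with 4 paced
    records excluded, read from the shipped (or a user-supplied) config."""
    cfg = _load_config(config_path)
    return DatasetSplit([str(r) for r in cfg["ds1"]],
                        [str(r) for r in cfg["ds2"]],
                        [str(r) for r in cfg.get("excluded", [])])


def load_record(path: str, spec: RecordSpec | None = None,
                symbol_map: dict[str, str] | None = None,
                ) -> tuple[np.ndarray, np.ndarray, list[BeatAnnotation]]:
    """Read one record (``path`` is the prefix of .hea/.dat/.atr files).

    Returns (lead_a, lead_b, annotations): two equal-length physical-unit
    signals and the beat annotations sorted by R index.
    """
    rec_id = spec.record_id if spec else os.path.basename(path)
    if not os.path.exists(path + ".hea"):
        raise FileNotFoundError(f"record {rec_id}: missing header {path}.hea")
    header, physical = _mitdb.read_record(path)
    if header.n_sig < 2:
        raise ValueError(f"record {rec_id}: needs >=2 channels, found {header.n_sig}")
    ch_a, ch_b = 0, 1
    if spec and spec.lead_names[0]:
        names = [s.description for s in header.signals]
        try:
            ch_a = names.index(spec.lead_names[0])
            ch_b = names.index(spec.lead_names[1])
        except ValueError as exc:
            raise ValueError(f"record {rec_id}: lead {exc} not in {names}") from exc
    raw = _mitdb.read_annotations(path + ".atr")
    anns = sorted(
        (BeatAnnotation(t, sym, map_beat_label(sym, symbol_map)) for t, sym in raw),
        key=lambda a: a.r_index)
    n = header.n_samples
    for a in anns:
        if a.r_index >= n:
            raise ValueError(
                f"record {rec_id}: annotation at sample {a.r_index} beyond "
                f"signal end ({n})")
    return physical[:, ch_a], physical[:, ch_b], anns


def count_beats_by_type(data_dir: str, record_ids: list[str],
                        symbol_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-record counts of the three studied beat classes (OTHER excluded).

    Rows are records, columns NORM/LBBB/RBBB plus a ``total``; sum rows to
    reproduce per-dataset distributions.
    """
    rows = {}
    for rid in record_ids:
        _, _, anns = load_record(os.path.join(data_dir, rid),
                                 symbol_map=symbol_map)
        counts = {lab: 0 for lab in STUDIED_LABELS}
        for a in anns:
            if a.label in counts:
                counts[a.label] += 1
        rows[rid] = counts
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(STUDIED_LABELS)).fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=list(STUDIED_LABELS), dtype=int)
    df["total"] = df.sum(axis=1) if len(df) else 0
    return df
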