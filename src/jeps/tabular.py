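"""Fold-safe encoding of clinical records into fixed-length vectors.

Numeric fields are min-max scaled with ranges derived from the training
rows only; categorical fields are one-hot encoded over the training
vocabulary, so a category first seen at test time encodes as an all-zero
block.  Out-of-range test numerics pass through the affine map without
clamping.  Fitting on training rows only is the leakage contract every
cross-validation fold relies on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ClinicalSchema:
    """Ordered field list with per-field kind ('numeric' or 'categorical')."""

    fields: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for name, kind in self.fields:
            if kind not in ("numeric", "categorical"):
                raise ValueError(f"field {name!r}: unknown kind {kind!r}")

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "ClinicalSchema":
        return cls(tuple(mapping.items()))

    def names(self):
        return [n for n, _ in self.fields]


@dataclass
class ClinicalEncoder:
    """Fitted fold-local encoder: numeric ranges + categorical vocabularies."""

    schema: ClinicalSchema
    numeric_range: dict[str, tuple[float, float]]
    categories: dict[str, list[str]]

    @property
    def width(self) -> int:
        w = 0
        for name, kind in self.schema.fields:
            w += 1 if kind == "numeric" else len(self.categories[name])
        return w

    def column_names(self) -> list[str]:
        cols = []
        for name, kind in self.schema.fields:
            if kind == "numeric":
                cols.append(name)
            else:
                cols.extend(f"{name}={c}" for c in self.categories[name])
        return cols

    def to_json(self) -> str:
        return json.dumps({
            "schema": list(self.schema.fields),
            "numeric_range": {k: list(v) for k, v in self.numeric_range.items()},
            "categories": self.categories,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClinicalEncoder":
        d = json.loads(text)
        return cls(ClinicalSchema(tuple((n, k) for n, k in d["schema"])),
                   {k: tuple(v) for k, v in d["numeric_range"].items()},
                   {k: list(v) for k, v in d["categories"].items()})


def fit_clinical_encoder(train_records: list[dict], schema: ClinicalSchema) -> ClinicalEncoder:
    """Derive numeric ranges and category vocabularies from training rows only."""
    if len(train_records) < 2:
        raise ValueError("need at least 2 training rows to fit an encoder")
    numeric_range, categories = {}, {}
    for name, kind in schema.fields:
        try:
            col = [r[name] for r in train_records]
        except KeyError:
            raise ValueError(f"field {name!r} missing from training records") from None
        if any(v is None or v == "" for v in col):
            raise ValueError(f"field {name!r} has missing values; "
                             "data-incomplete records must be excluded")
        if kind == "numeric":
            vals = np.asarray([float(v) for v in col])
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                warnings.warn(f"numeric field {name!r} is constant in training "
                              "data; it will encode as 0")
            numeric_range[name] = (lo, hi)
        else:
            categories[name] = sorted({str(v) for v in col})
    return ClinicalEncoder(schema, numeric_range, categories)


def encode_clinical(records: list[dict], encoder: ClinicalEncoder) -> np.ndarray:
    """Encode records to a (rows, width) float matrix under a fitted encoder."""
    out = np.zeros((len(records), encoder.width), dtype=np.float64)
    for i, rec in enumerate(records):
        j = 0
        for name, kind in encoder.schema.fields:
            if kind == "numeric":
                try:
                    x = float(rec[name])
                except (TypeError, ValueError):
                    rid = rec.get("patient_id", f"row {i}")
                    raise ValueError(
                        f"non-numeric value {rec[name]!r} in numeric field "
                        f"{name!r} ({rid})") from None
                lo, hi = encoder.numeric_range[name]
                out[i, j] = 0.0 if hi == lo else (x - lo) / (hi - lo)
                j += 1
            else:
                vocab = encoder.categories[name]
                v = str(rec[name])
                if v in vocab:
                    out[i, j + vocab.index(v)] = 1.0
                j += len(vocab)
    return out
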