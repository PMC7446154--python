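"""Feature-encoding contract: fit on training annotations, apply anywhere.

Each categorical feature keeps its (up to) five most frequent training
levels and expands to one indicator per retained level plus explicit
``other`` and ``missing`` indicators; numerical features are imputed with
a fixed per-feature value (externally recommended values may be supplied
as overrides, otherwise the training median); population allele frequency
is appended as an extra feature, 0 for variants absent from the lookup.
The fitted schema is serializable so train- and test-time encodings are
guaranteed column-identical.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (
    DEFAULT_MANIFEST,
    AnnotationRecord,
    ClassifiedVariant,
    FeatureManifest,
    SchemaMismatchError,
    VariantKey,
)

logger = logging.getLogger(__name__)

OTHER = "__other__"
MISSING = "__missing__"
DEFAULT_AF_FEATURE = "population_af"


@dataclass
class FeatureSchema:
    """Fitted encoding contract (retained levels, imputation values,
    total column order)."""

    categorical_levels: dict[str, list[str]]
    imputation_values: dict[str, float]
    feature_order: list[str]
    af_feature_name: str = DEFAULT_AF_FEATURE
    include_af: bool = True
    max_levels: int = 5
    version: str = "1"

    @property
    def categorical_names(self) -> list[str]:
        return list(self.categorical_levels)

    @property
    def numerical_names(self) -> list[str]:
        return list(self.imputation_values)

    def expected_n_columns(self) -> int:
        n_cat = sum(len(levels) + 2 for levels in self.categorical_levels.values())
        return n_cat + len(self.imputation_values) + (1 if self.include_af else 0)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "categorical_levels": self.categorical_levels,
            "imputation_values": self.imputation_values,
            "feature_order": self.feature_order,
            "af_feature_name": self.af_feature_name,
            "include_af": self.include_af,
            "max_levels": self.max_levels,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)


@dataclass
class FeatureMatrix:
    """Dense encoded matrix aligned with its variant keys; optional labels
    (1 = pathogenic) and per-row sample weights."""

    keys: list[VariantKey]
    columns: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.keys), len(self.columns)):
            raise ValueError("matrix shape does not match keys/columns")
        if np.isnan(self.values).any():
            raise ValueError("encoded matrix must not contain absent values")

    @property
    def n_rows(self) -> int:
        return len(self.keys)


def fit_feature_schema(
    training_annotations: Sequence[AnnotationRecord],
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    imputation_overrides: Mapping[str, float] | None = None,
    max_levels: int = 5,
    include_af: bool = True,
    af_feature_name: str = DEFAULT_AF_FEATURE,
) -> FeatureSchema:
    """Fit the encoding contract on training annotations.

    Retains the ``max_levels`` most frequent levels per categorical feature
    (ties broken lexicographically); numerical imputation values come from
    the override table when given, else the training median.
    """
    if not training_annotations:
        raise ValueError("cannot fit a feature schema on an empty training set")
    overrides = dict(imputation_overrides or {})

    categorical_levels: dict[str, list[str]] = {}
    for name in manifest.categorical_names:
        counts = Counter(
            rec.categorical[name]
            for rec in training_annotations
            if name in rec.categorical
        )
        if not counts:
            logger.warning("categorical feature %r never observed in training", name)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        categorical_levels[name] = [lvl for lvl, _ in ranked[:max_levels]]

    imputation_values: dict[str, float] = {}
    for name in manifest.numerical_names:
        if name in overrides:
            imputation_values[name] = float(overrides[name])
            continue
        vals = [rec.numerical[name] for rec in training_annotations if name in rec.numerical]
        if vals:
            imputation_values[name] = float(np.median(vals))
        else:
            logger.warning("numerical feature %r never observed; imputing 0.0", name)
            imputation_values[name] = 0.0

    feature_order: list[str] = []
    for name in manifest.categorical_names:
        feature_order.extend(f"{name}={lvl}" for lvl in categorical_levels[name])
        feature_order.append(f"{name}={OTHER}")
        feature_order.append(f"{name}={MISSING}")
    feature_order.extend(manifest.numerical_names)
    if include_af:
        feature_order.append(af_feature_name)

    return FeatureSchema(
        categorical_levels=categorical_levels,
        imputation_values=imputation_values,
        feature_order=feature_order,
        af_feature_name=af_feature_name,
        include_af=include_af,
        max_levels=max_levels,
    )


def encode_features(
    annotations: Sequence[AnnotationRecord],
    af_lookup: Mapping[VariantKey, float],
    schema: FeatureSchema,
) -> FeatureMatrix:
    """Encode annotation records into the schema's dense column layout.

    Categorical: one indicator per retained level, an ``other`` indicator
    for observed-but-unretained levels and a ``missing`` indicator for
    absent values. Numerical: pass-through with fixed imputation. AF:
    lookup value, 0 when the variant is absent from the lookup.
    """
    declared = set(schema.categorical_levels) | set(schema.imputation_values)
    col_index = {c: j for j, c in enumerate(schema.feature_order)}
    n, m = len(annotations), len(schema.feature_order)
    values = np.zeros((n, m), dtype=float)

    for i, rec in enumerate(annotations):
        unknown = (set(rec.categorical) | set(rec.numerical)) - declared
        if unknown:
            raise SchemaMismatchError(
                f"annotation features not in schema: {sorted(unknown)}"
            )
        for name, levels in schema.categorical_levels.items():
            if name in rec.categorical:
                level = rec.categorical[name]
                col = f"{name}={level}" if level in levels else f"{name}={OTHER}"
            else:
                col = f"{name}={MISSING}"
            values[i, col_index[col]] = 1.0
        for name, impute in schema.imputation_values.items():
            values[i, col_index[name]] = rec.numerical.get(name, impute)
        if schema.include_af:
            values[i, col_index[schema.af_feature_name]] = af_lookup.get(rec.key, 0.0)

    return FeatureMatrix(
        keys=[rec.key for rec in annotations],
        columns=list(schema.feature_order),
        values=values,
    )


def attach_labels(
    matrix: FeatureMatrix, variants: Sequence[ClassifiedVariant]
) -> FeatureMatrix:
    """Attach labels (1 = pathogenic) and sample weights from classified
    variants, aligned by variant key."""
    by_key = {v.key: v for v in variants}
    missing = [k for k in matrix.keys if k not in by_key]
    if missing:
        raise KeyError(f"{len(missing)} matrix keys have no classified variant")
    labels = np.array(
        [1 if by_key[k].label == "pathogenic" else 0 for k in matrix.keys], dtype=int
    )
    weights = np.array([by_key[k].sample_weight for k in matrix.keys], dtype=float)
    return FeatureMatrix(matrix.keys, matrix.columns, matrix.values, labels, weights)


_KEY_COLS = ["chrom", "pos", "ref", "alt"]


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.columns)
    for j, col in enumerate(_KEY_COLS):
        df.insert(j, col, [getattr(k, col) for k in matrix.keys])
    offset = len(_KEY_COLS)
    if matrix.labels is not None:
        df.insert(offset, "label", matrix.labels)
        offset += 1
    if matrix.weights is not None:
        df.insert(offset, "sample_weight", matrix.weights)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    keys = [
        VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df[_KEY_COLS].itertuples()
    ]
    labels = df.pop("label").to_numpy(dtype=int) if "label" in df.columns else None
    weights = (
        df.pop("sample_weight").to_numpy(dtype=float)
        if "sample_weight" in df.columns
        else None
    )
    feat = df.drop(columns=_KEY_COLS)
    return FeatureMatrix(keys, list(feat.columns), feat.to_numpy(dtype=float), labels, weights)
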