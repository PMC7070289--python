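"""Cleaning and autoscaling of feature tables.

Scaling statistics are always learned from the fitting rows only and then
applied unchanged to any other table — the leakage-free contract Monte
Carlo cross-validation depends on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .feature_io import FeatureTable


class PreprocessError(ValueError):
    pass


@dataclass
class ScalerParams:
    """Per-feature training mean and sample SD (denominator n - 1)."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped_features: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.feature_names) == len(self.means) == len(self.sds)):
            raise PreprocessError("feature_names, means, sds length mismatch")
        if np.any(self.sds <= 0):
            bad = [n for n, s in zip(self.feature_names, self.sds) if s <= 0]
            raise PreprocessError(f"non-positive sd for features {bad}")

    def to_json(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "dropped_features": [list(d) for d in self.dropped_features],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ScalerParams":
        return cls(
            feature_names=list(obj["feature_names"]),
            means=np.asarray(obj["means"]),
            sds=np.asarray(obj["sds"]),
            dropped_features=[tuple(d) for d in obj.get("dropped_features", [])],
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "ScalerParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def clean_features(table: FeatureTable) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Drop unusable features; impute sporadic non-finite cells.

    Features that are entirely non-finite or have zero variance (over
    finite cells) are dropped with a reason; remaining non-finite cells
    are replaced by the feature median.  The output is fully finite.
    """
    if table.n_objects == 0:
        raise PreprocessError("empty table")
    X = table.values.copy()
    X[~np.isfinite(X)] = np.nan
    report: list[tuple[str, str]] = []
    keep: list[int] = []
    for j, name in enumerate(table.feature_names):
        col = X[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            report.append((name, "all non-finite"))
            continue
        if np.nanstd(col) == 0:
            report.append((name, "zero variance"))
            continue
        if np.isnan(col).any():
            col[np.isnan(col)] = np.median(finite)
        keep.append(j)
    if not keep:
        raise PreprocessError("all features dropped during cleaning")
    cleaned = FeatureTable(
        object_ids=table.object_ids,
        group=table.group,
        compound_id=table.compound_id,
        feature_names=[table.feature_names[j] for j in keep],
        values=X[:, keep],
        extra_metadata=table.extra_metadata,
    )
    return cleaned, report


def fit_scaler(table: FeatureTable) -> ScalerParams:
    """Per-feature mean and sample SD over the given rows only."""
    if table.n_objects < 2:
        raise PreprocessError("need at least 2 rows to fit a scaler")
    if not table.is_finite():
        raise PreprocessError("table must be cleaned before scaling")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        bad = [table.feature_names[j] for j in zero]
        raise PreprocessError(f"zero standard deviation for features {bad}")
    return ScalerParams(list(table.feature_names), means, sds)


def apply_scaler(params: ScalerParams, table: FeatureTable) -> FeatureTable:
    """Restrict to the scaler's features and apply (x - mean) / sd.

    Never refits: test-set columns keep whatever moments they have under
    the training statistics.  Extra unseen features are excluded;
    missing ones are an error.
    """
    pos = {name: j for j, name in enumerate(table.feature_names)}
    missing = [n for n in params.feature_names if n not in pos]
    if missing:
        raise PreprocessError(f"table is missing features {missing}")
    idx = [pos[n] for n in params.feature_names]
    values = (table.values[:, idx] - params.means) / params.sds
    return FeatureTable(
        object_ids=table.object_ids,
        group=table.group,
        compound_id=table.compound_id,
        feature_names=list(params.feature_names),
        values=values,
        extra_metadata=table.extra_metadata,
    )
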