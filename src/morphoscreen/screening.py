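"""Compound scoring: collapse each treated cell population into a single
protection score against the trained classifier.

Each object in a compound-treated population receives the posterior
naive-probability from the fitted PLS-LDA model; the population median of
those per-object scores is the compound's protection score, and a median
above 0.5 (strictly) flags the compound as protective.  Median profiles
of the standardized features feed the screen heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, subset_by_compound, subset_by_group
from .pls_lda import PLSLDAModel, posterior, posterior_from_discriminant
from .preprocess import apply_scaler


class ScreeningError(ValueError):
    pass


@dataclass
class CompoundScore:
    compound_id: str
    n_objects: int
    object_scores: np.ndarray  # per-object posterior in [0, 1]
    median_score: float
    protective: bool  # median_score > 0.5, strict
    median_profile: np.ndarray  # per-feature median of standardized values


def score_compound(
    model: PLSLDAModel,
    table: FeatureTable,
    compound_id: str,
    score_median_profile: bool = False,
) -> CompoundScore:
    """Score one treated population.

    By default each object is scored and the median of the per-object
    posteriors is reported.  With ``score_median_profile`` the per-feature
    median profile is scored instead (the alternative reading of a
    median-aggregated readout); the per-object scores are reported either
    way.
    """
    if table.n_objects == 0:
        raise ScreeningError("empty population")
    if not all(c == compound_id for c in table.compound_id):
        raise ScreeningError(f"rows do not all carry compound_id {compound_id!r}")
    scores = posterior(model, table)
    profile = np.median(apply_scaler(model.scaler, table).values, axis=0)
    if score_median_profile:
        t = model.pls.transform(profile[None, :])
        d = t @ model.lda_direction + model.lda_offset
        median_score = float(posterior_from_discriminant(model, d)[0])
    else:
        median_score = float(np.median(scores))
    return CompoundScore(
        compound_id=compound_id,
        n_objects=table.n_objects,
        object_scores=scores,
        median_score=median_score,
        protective=bool(median_score > 0.5),
        median_profile=profile,
    )


def rank_compounds(
    model: PLSLDAModel,
    screen: FeatureTable,
    score_median_profile: bool = False,
) -> list[CompoundScore]:
    """One CompoundScore per compound among the treated rows, sorted by
    descending median score; exact ties broken lexicographically."""
    treated = subset_by_group(screen, {"treated"})
    if treated.n_objects == 0:
        raise ScreeningError("no treated rows in screen")
    compound_ids = sorted(set(treated.compound_id))
    scores = [
        score_compound(
            model, subset_by_compound(treated, cid), cid, score_median_profile
        )
        for cid in compound_ids
    ]
    scores.sort(key=lambda s: (-s.median_score, s.compound_id))
    return scores


def heatmap_matrix(
    scores: list[CompoundScore],
    naive_table: FeatureTable,
    model_table: FeatureTable,
    model: PLSLDAModel,
) -> pd.DataFrame:
    """Median standardized profiles: rows naive, model, then compounds by
    descending median score; columns the model's retained features."""
    if not scores:
        raise ScreeningError("no compound scores")
    rows = {
        "naive": np.median(apply_scaler(model.scaler, naive_table).values, axis=0),
        "model": np.median(apply_scaler(model.scaler, model_table).values, axis=0),
    }
    ordered = sorted(scores, key=lambda s: (-s.median_score, s.compound_id))
    p = len(model.scaler.feature_names)
    for s in ordered:
        if s.median_profile.shape != (p,):
            raise ScreeningError(f"feature mismatch for compound {s.compound_id!r}")
        rows[s.compound_id] = s.median_profile
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=model.scaler.feature_names
    )
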