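"""Variable importance in projection (VIP) from a fitted PLS model.

For feature ``j`` over ``A`` components,

    VIP_j = sqrt( p * sum_a [ SS_a * (w_aj / ||w_a||)^2 ] / sum_a SS_a )

with ``SS_a = q_a^2 (t_a' t_a)`` the y-sum-of-squares captured by
component ``a`` and ``p`` the number of features.  This is the
weights-based variant, under which ``sum_j VIP_j^2 = p`` exactly (NIPALS
weights have unit norm), so VIP > 1 marks a feature contributing more
than an average share of the explained class separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls_lda import PLSModel


class VIPError(ValueError):
    pass


@dataclass
class VIPResult:
    feature_names: list[str]  # model's canonical feature order
    vip: np.ndarray
    above_one: list[str]  # vip > 1 (strict), sorted descending by vip
    ties: list[str]  # features involved in exact VIP ties, if any


def compute_vip(model: PLSModel, feature_names: list[str] | None = None) -> VIPResult:
    """VIP score per feature; satisfies ``sum VIP^2 = n_features``."""
    p = model.n_features
    names = list(feature_names) if feature_names is not None else [
        f"feature_{j}" for j in range(p)
    ]
    if len(names) != p:
        raise VIPError("feature_names length does not match model")
    ss = np.asarray(model.explained_y_ss, dtype=float)
    total = ss.sum()
    if total <= 0:
        raise VIPError("no y-variance captured (all SS_a = 0)")
    W = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    vip = np.sqrt(p * (W**2 @ ss) / total)
    order = _vip_order(vip)
    above = [names[j] for j in order if vip[j] > 1.0]
    vals, counts = np.unique(vip, return_counts=True)
    tied_vals = set(vals[counts > 1])
    ties = [names[j] for j in range(p) if vip[j] in tied_vals]
    return VIPResult(feature_names=names, vip=vip, above_one=above, ties=ties)


def _vip_order(vip: np.ndarray) -> np.ndarray:
    """Indices by descending VIP; exact ties keep canonical feature order."""
    return np.lexsort((np.arange(vip.size), -vip))


def top_features(result: VIPResult, k: int) -> list[str]:
    """The ``k`` highest-VIP feature names (ties broken canonically)."""
    p = len(result.feature_names)
    if not 1 <= k <= p:
        raise VIPError(f"k={k} outside [1, {p}]")
    order = _vip_order(result.vip)
    return [result.feature_names[j] for j in order[:k]]
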