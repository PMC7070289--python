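"""PLS-LDA: partial least squares against class membership, then a linear
discriminant in latent-score space.

The classifier is the two-stage construction standard in chemometrics:

1. NIPALS PLS1 extracts ``A`` latent variables from the standardized
   feature matrix ``X`` against the class code ``y`` (+1 naive, -1
   injured "model" cells).  For each component ``a``: the weight
   ``w_a`` is proportional to ``X' y`` (unit norm), the score is
   ``t_a = X w_a``, the x-loading ``p_a = X' t_a / (t_a' t_a)``, the
   y-loading ``q_a = y' t_a / (t_a' t_a)``, and ``X`` is deflated by
   ``t_a p_a'`` (``y`` is not deflated).  Score columns are mutually
   orthogonal.
2. Fisher LDA (equal-covariance Gaussian, equal priors) on the
   ``A``-dimensional training scores yields a signed discriminant
   ``d(x)``: positive for naive-like objects, negative for injured-like,
   with the decision boundary exactly at 0.

The posterior score in [0, 1] is the logistic map implied by the
two-Gaussian model: ``p(naive | x) = 1 / (1 + exp(-d(x) * delta /
sigma^2))`` where ``delta`` is the between-class discriminant mean gap
and ``sigma^2`` the pooled within-class discriminant variance; ``d = 0``
maps to exactly 0.5, so the 0-threshold on the discriminant and the
0.5-threshold on the compound score coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .feature_io import FeatureTable, subset_by_group
from .preprocess import ScalerParams, apply_scaler, fit_scaler

#: Condition-number cap for the (P'W) solve.
_MAX_COND = 1e12


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """NIPALS PLS1 decomposition.

    ``explained_y_ss[a] = q_a^2 * (t_a' t_a)`` is the y-sum-of-squares
    captured by component ``a`` (not necessarily monotone in ``a``).
    """

    A: int
    W: np.ndarray  # (p, A) unit-norm weight columns
    P: np.ndarray  # (p, A) x-loadings
    q: np.ndarray  # (A,) y-loadings
    T: np.ndarray  # (n, A) training scores
    explained_y_ss: np.ndarray  # (A,)

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def rotation(self) -> np.ndarray:
        """R = W (P'W)^{-1}, such that scores(X) = X R."""
        PtW = self.P.T @ self.W
        if np.linalg.cond(PtW) > _MAX_COND:
            raise PLSError("P'W is numerically singular (condition > 1e12)")
        return np.linalg.solve(PtW.T, self.W.T).T

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project standardized rows into latent-score space."""
        return np.asarray(X, dtype=float) @ self.rotation()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """PLS regression prediction of y (used by equivalence oracles)."""
        return self.transform(X) @ self.q


def fit_pls(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS1 with X-deflation only.

    ``X`` must be cleaned and standardized; ``y`` coded +1 / -1 (any
    two-valued centering works, but the +1/-1 convention is assumed
    upstream).
    """
    X = np.array(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise PLSError("degenerate y: one class only")
    if not 1 <= A <= min(n - 1, p):
        raise PLSError(f"A={A} outside admissible range [1, {min(n - 1, p)}]")

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))
    ss = np.empty(A)
    for a in range(A):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise PLSError(f"zero weight vector at component {a + 1}: rank exhausted")
        w /= norm
        t = X @ w
        tt = t @ t
        if tt <= 0:
            raise PLSError(f"degenerate score at component {a + 1}")
        pvec = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, pvec)
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        ss[a] = qa * qa * tt
    return PLSModel(A=A, W=W, P=P, q=q, T=T, explained_y_ss=ss)


@dataclass
class PLSLDAModel:
    """Fitted PLS-LDA pipeline: scaler + PLS + discriminant + posterior map.

    Orientation convention: the mean discriminant of training naive
    objects is positive and of training model objects negative
    ("score below 0 = injured").
    """

    scaler: ScalerParams
    pls: PLSModel
    lda_direction: np.ndarray  # (A,)
    lda_offset: float
    #: (naive mean, model mean, pooled variance) of the training discriminant
    score_moments: tuple[float, float, float]

    def decision_function(self, table: FeatureTable) -> np.ndarray:
        return discriminant(self, table)

    def to_json(self) -> dict:
        return {
            "kind": "plslda",
            "scaler": self.scaler.to_json(),
            "pls": {
                "A": self.pls.A,
                "W": self.pls.W.tolist(),
                "P": self.pls.P.tolist(),
                "q": self.pls.q.tolist(),
                "T": self.pls.T.tolist(),
                "explained_y_ss": self.pls.explained_y_ss.tolist(),
            },
            "lda_direction": self.lda_direction.tolist(),
            "lda_offset": self.lda_offset,
            "score_moments": list(self.score_moments),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PLSLDAModel":
        p = obj["pls"]
        return cls(
            scaler=ScalerParams.from_json(obj["scaler"]),
            pls=PLSModel(
                A=int(p["A"]),
                W=np.asarray(p["W"]),
                P=np.asarray(p["P"]),
                q=np.asarray(p["q"]),
                T=np.asarray(p["T"]),
                explained_y_ss=np.asarray(p["explained_y_ss"]),
            ),
            lda_direction=np.asarray(obj["lda_direction"]),
            lda_offset=float(obj["lda_offset"]),
            score_moments=tuple(obj["score_moments"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path) -> "PLSLDAModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def class_codes(table: FeatureTable) -> np.ndarray:
    """+1 for naive, -1 for model; raises if any other group is present."""
    y = np.where(table.group == "naive", 1.0, -1.0)
    other = set(table.group) - {"naive", "model"}
    if other:
        raise PLSError(f"unexpected groups for supervised fit: {sorted(other)}")
    return y


def fit_plslda(table: FeatureTable, A: int) -> PLSLDAModel:
    """Fit scaler, PLS and the score-space discriminant on labeled rows.

    ``table`` must be cleaned (finite) and contain at least 2 naive and
    2 model objects.
    """
    labeled = subset_by_group(table, {"naive", "model"})
    for g in ("naive", "model"):
        if int((labeled.group == g).sum()) < 2:
            raise PLSError(f"fewer than 2 objects in class {g!r}")
    scaler = fit_scaler(labeled)
    scaled = apply_scaler(scaler, labeled)
    y = class_codes(scaled)
    pls = fit_pls(scaled.values, y, A)

    T = pls.T
    pos, neg = y > 0, y < 0
    mu_pos, mu_neg = T[pos].mean(axis=0), T[neg].mean(axis=0)
    centered = np.vstack([T[pos] - mu_pos, T[neg] - mu_neg])
    S = centered.T @ centered / (len(T) - 2)
    # shrink toward the diagonal if the pooled covariance is ill-conditioned
    if np.linalg.cond(S) > _MAX_COND:
        S = S + 1e-8 * np.trace(S) / max(S.shape[0], 1) * np.eye(S.shape[0])
    direction = np.linalg.solve(S, mu_pos - mu_neg)
    offset = -float(direction @ (mu_pos + mu_neg)) / 2.0

    d = T @ direction + offset
    m_pos, m_neg = float(d[pos].mean()), float(d[neg].mean())
    if not m_pos > 0 > m_neg:  # fix naive-positive orientation
        direction, offset = -direction, -offset
        d = -d
        m_pos, m_neg = float(d[pos].mean()), float(d[neg].mean())
    resid = np.concatenate([d[pos] - m_pos, d[neg] - m_neg])
    sigma2 = float(resid @ resid / max(len(d) - 2, 1))
    if sigma2 == 0:
        sigma2 = np.finfo(float).tiny
    return PLSLDAModel(
        scaler=scaler,
        pls=pls,
        lda_direction=direction,
        lda_offset=offset,
        score_moments=(m_pos, m_neg, sigma2),
    )


def discriminant(model: PLSLDAModel, table: FeatureTable) -> np.ndarray:
    """Signed per-object score: > 0 naive-like, < 0 injured-like."""
    scaled = apply_scaler(model.scaler, table)
    t = model.pls.transform(scaled.values)
    return t @ model.lda_direction + model.lda_offset


def posterior(model: PLSLDAModel, table: FeatureTable) -> np.ndarray:
    """P(naive | x) in [0, 1]; exactly 0.5 at the decision boundary."""
    return posterior_from_discriminant(model, discriminant(model, table))


def posterior_from_discriminant(model: PLSLDAModel, d: np.ndarray) -> np.ndarray:
    m_pos, m_neg, sigma2 = model.score_moments
    slope = (m_pos - m_neg) / sigma2
    return expit(np.asarray(d) * slope)
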