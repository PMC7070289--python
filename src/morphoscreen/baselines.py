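"""Reference classifiers for the algorithm comparison: logistic
regression (IRLS) and least-squares SVM.

Both expose the same fit / ``decision_function`` contract as the PLS-LDA
model — a real-valued score per object, higher meaning more naive-like —
so Monte Carlo cross-validation can run any of the three interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .feature_io import FeatureTable, subset_by_group
from .pls_lda import class_codes
from .preprocess import ScalerParams, apply_scaler, fit_scaler


class BaselineError(ValueError):
    pass


@dataclass
class BaselineModel:
    """Fitted baseline classifier sharing the naive-positive orientation."""

    kind: Literal["logreg", "lssvm"]
    scaler: ScalerParams
    coef: np.ndarray  # logreg coefficients or LS-SVM support coefficients
    intercept: float
    kernel: str = "linear"
    kernel_width: float = 1.0
    support_vectors: np.ndarray | None = None
    separation_flag: bool = False
    n_iter: int = 0

    def decision_function(self, table: FeatureTable) -> np.ndarray:
        X = apply_scaler(self.scaler, table).values
        if self.kind == "logreg":
            return X @ self.coef + self.intercept
        K = _kernel(X, self.support_vectors, self.kernel, self.kernel_width)
        return K @ self.coef + self.intercept


def _kernel(A: np.ndarray, B: np.ndarray, kernel: str, width: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * width**2))
    raise BaselineError(f"unknown kernel {kernel!r}")


# margin at which every training object is called "certain": probabilities
# within ~1e-5 of 0/1, the practical signature of complete separation
_SEPARATION_MARGIN = 12.0


def fit_logreg(
    table: FeatureTable,
    l2: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> BaselineModel:
    """Logistic regression by iteratively reweighted least squares.

    Default is the plain unpenalized maximum-likelihood fit (``l2 = 0``);
    a ridge penalty on the coefficients (not the intercept) is available.
    Stops at gradient norm < ``tol`` or ``max_iter`` iterations.  Complete
    separation — every training object pushed to a certain probability —
    is detected, the coefficients are capped at the separation margin, and
    ``separation_flag`` is set.
    """
    labeled = subset_by_group(table, {"naive", "model"})
    y01 = (class_codes(labeled) > 0).astype(float)
    if np.unique(y01).size < 2:
        raise BaselineError("one-class input")
    scaler = fit_scaler(labeled)
    X = apply_scaler(scaler, labeled).values
    n, p = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    beta = np.zeros(p + 1)
    penalty = np.full(p + 1, l2)
    penalty[-1] = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xb @ beta
        mu = expit(eta)
        grad = Xb.T @ (y01 - mu) - penalty * beta
        if np.linalg.norm(grad) < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Xb * w[:, None]).T @ Xb + np.diag(penalty)
        # lstsq handles the singular Hessian of the p >> n regime
        step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
    # complete separation: the likelihood has no maximizer and IRLS runs
    # to the iteration cap with every training object pushed certain;
    # report it and cap the fit at the separation margin
    eta = Xb @ beta
    margins = np.where(y01 > 0, eta, -eta)
    separated = bool(np.all(margins > _SEPARATION_MARGIN))
    if separated:
        beta = beta * (_SEPARATION_MARGIN / np.abs(eta).max())
    return BaselineModel(
        kind="logreg",
        scaler=scaler,
        coef=beta[:-1],
        intercept=float(beta[-1]),
        separation_flag=separated,
        n_iter=it,
    )


def fit_lssvm(
    table: FeatureTable,
    gamma: float = 1.0,
    kernel: str = "linear",
    kernel_width: float = 1.0,
) -> BaselineModel:
    """Least-squares SVM: one linear system instead of a QP.

    Solves ``[[0, 1'], [1, K + I/gamma]] [b; alpha] = [0; y]`` with
    ``y`` in {+1, -1}; the score of a new object is
    ``sum_i alpha_i K(x_i, x) + b``.
    """
    if gamma <= 0:
        raise BaselineError("gamma must be positive")
    labeled = subset_by_group(table, {"naive", "model"})
    y = class_codes(labeled)
    if np.unique(y).size < 2:
        raise BaselineError("one-class input")
    scaler = fit_scaler(labeled)
    X = apply_scaler(scaler, labeled).values
    n = len(y)
    K = _kernel(X, X, kernel, kernel_width)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise BaselineError(f"singular LS-SVM system: {exc}") from exc
    return BaselineModel(
        kind="lssvm",
        scaler=scaler,
        coef=sol[1:],
        intercept=float(sol[0]),
        kernel=kernel,
        kernel_width=kernel_width,
        support_vectors=X,
    )
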