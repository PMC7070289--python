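"""Monte Carlo cross-validation, ROC/AUC/accuracy, and latent-dimension
selection.

The validation protocol mirrors the screening study design: repeated
random 80/20 train/test partitions (stratified by class by default), the
full pipeline — cleaning, autoscaling, classifier — refit from the
training rows of every repetition, and held-out AUC/accuracy summarized
over repetitions.  A pooled ROC over all held-out (score, label) pairs is
kept for plotting alongside the per-repetition metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import baselines, pls_lda
from .feature_io import FeatureTable, subset_by_group
from .preprocess import clean_features


class ValidationError(ValueError):
    pass


@dataclass
class CVConfig:
    """Monte Carlo cross-validation settings (default 80/20, stratified)."""

    train_fraction: float = 0.8
    n_reps: int = 1000
    stratified: bool = True
    seed: int = 0
    model_spec: dict = field(default_factory=lambda: {"model": "plslda", "A": 2})

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass
class CVResult:
    per_rep_auc: np.ndarray
    per_rep_accuracy: np.ndarray
    mean_auc: float
    mean_accuracy: float
    pooled_roc: np.ndarray  # (k, 2) columns fpr, tpr
    pooled_auc: float
    pooled_scores: np.ndarray  # concatenated held-out decision scores
    pooled_labels: np.ndarray  # matching labels, True = naive
    n_missing: int = 0  # reps with a one-class test set (unstratified runs)


def fit_model(table: FeatureTable, model_spec: dict):
    """Fit the classifier named by ``model_spec['model']`` on labeled rows.

    All three classifiers share the ``decision_function`` contract
    (higher = more naive-like, threshold at 0).
    """
    spec = dict(model_spec)
    kind = spec.pop("model", "plslda")
    if kind == "plslda":
        return pls_lda.fit_plslda(table, A=spec.get("A", 2))
    if kind == "logreg":
        return baselines.fit_logreg(table, l2=spec.get("l2", 0.0))
    if kind == "lssvm":
        return baselines.fit_lssvm(
            table,
            gamma=spec.get("gamma", 1.0),
            kernel=spec.get("kernel", "linear"),
            kernel_width=spec.get("kernel_width", 1.0),
        )
    raise ValidationError(f"unknown model kind {kind!r}")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("auc needs both classes")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(fpr, tpr) points, thresholds swept over unique scores descending.

    Tied scores collapse into a single step; the trapezoid area of the
    output equals :func:`auc` to machine precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_curve needs both classes")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(lab)[distinct]
    fp = np.cumsum(~lab)[distinct]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    return np.column_stack([fpr, tpr])


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValidationError("length mismatch")
    return float(np.mean(predictions == labels))


def _split(
    rng: np.random.Generator, y: np.ndarray, train_fraction: float, stratified: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test indices; per-class floor(n * fraction) under stratification."""
    n = y.size
    if stratified:
        train_idx = []
        for cls in (True, False):
            idx = np.flatnonzero(y == cls)
            perm = rng.permutation(idx)
            train_idx.append(perm[: int(np.floor(idx.size * train_fraction))])
        train = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[: int(np.floor(n * train_fraction))])
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def mccv(table: FeatureTable, config: CVConfig) -> CVResult:
    """Monte Carlo cross-validation of the full pipeline.

    Every repetition cleans, scales and fits the classifier from its
    training rows only, then scores the held-out rows.  The RNG is fully
    determined by ``config.seed``.  Repetitions whose test set contains a
    single class, or whose training set lacks two objects of either
    class (possible only unstratified), are recorded as missing, never
    silently skipped.
    """
    labeled = subset_by_group(table, {"naive", "model"})
    y = labeled.group == "naive"
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise ValidationError("need >= 2 objects of each class")
    rng = np.random.default_rng(config.seed)
    aucs, accs = [], []
    pooled_scores, pooled_labels = [], []
    n_missing = 0
    for _ in range(config.n_reps):
        train, test = _split(rng, y, config.train_fraction, config.stratified)
        trainable = y[train].sum() >= 2 and (~y[train]).sum() >= 2
        if not trainable or np.unique(y[test]).size < 2:
            n_missing += 1
            aucs.append(np.nan)
            accs.append(np.nan)
            continue
        train_table, _ = clean_features(labeled.take(train))
        model = fit_model(train_table, config.model_spec)
        d = model.decision_function(labeled.take(test))
        aucs.append(auc(d, y[test]))
        accs.append(accuracy(d > 0, y[test]))
        pooled_scores.append(d)
        pooled_labels.append(y[test])
    aucs = np.asarray(aucs)
    accs = np.asarray(accs)
    scores = np.concatenate(pooled_scores) if pooled_scores else np.array([])
    labs = np.concatenate(pooled_labels) if pooled_labels else np.array([], bool)
    roc = roc_curve(scores, labs) if scores.size else np.zeros((0, 2))
    return CVResult(
        per_rep_auc=aucs,
        per_rep_accuracy=accs,
        mean_auc=float(np.nanmean(aucs)) if pooled_scores else float("nan"),
        mean_accuracy=float(np.nanmean(accs)) if pooled_scores else float("nan"),
        pooled_roc=roc,
        pooled_auc=auc(scores, labs) if scores.size else float("nan"),
        pooled_scores=scores,
        pooled_labels=labs,
        n_missing=n_missing,
    )


def select_components(
    table: FeatureTable, A_max: int, config: CVConfig, n_reps: int = 100
) -> int:
    """Smallest latent dimension whose MC-CV mean AUC is within 0.001 of
    the best over ``A = 1..A_max`` (reduced repetition count)."""
    if A_max < 1:
        raise ValidationError("A_max must be >= 1")
    means = []
    for A in range(1, A_max + 1):
        spec = dict(config.model_spec)
        spec.update(model="plslda", A=A)
        sub = CVConfig(
            train_fraction=config.train_fraction,
            n_reps=min(config.n_reps, n_reps),
            stratified=config.stratified,
            seed=config.seed,
            model_spec=spec,
        )
        means.append(mccv(table, sub).mean_auc)
    best = max(means)
    for A, m in enumerate(means, start=1):
        if m >= best - 1e-3:
            return A
    return A_max  # unreachable
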