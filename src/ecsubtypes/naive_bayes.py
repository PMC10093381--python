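"""Gaussian naive Bayes for CN-cluster-4 membership, with stratified CV.

The classifier is written from scratch (log-space class-conditional normal
densities, frequency priors, variance flooring) in the scikit-learn estimator
idiom so it composes with pipelines and model selection. Cross-validation
re-runs the top-gene selection of :mod:`ecsubtypes.cn_features` inside every
training fold, since the gene list is itself a fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_X_y

from .cn_features import CNFeatureExtractor, CNFeatureSpec
from .io import CNProfile, GeneModel


class GaussianNaiveBayes(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes with variance flooring.

    The class-conditional density of each feature is a normal with the
    per-class sample mean and (biased) sample variance; every variance is
    floored at ``var_smoothing`` times the largest overall feature variance so
    constant features contribute a proper density. Posteriors are computed in
    log space and normalized with log-sum-exp.

    Attributes (after ``fit``): ``classes_``, ``class_prior_``, ``theta_``
    (means), ``var_`` (floored variances), ``epsilon_`` (the floor).
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("fit requires at least two classes")
        n, p = X.shape
        self.epsilon_ = self.var_smoothing * max(X.var(axis=0).max(), np.finfo(float).tiny)
        self.theta_ = np.empty((len(self.classes_), p))
        self.var_ = np.empty((len(self.classes_), p))
        self.class_count_ = np.empty(len(self.classes_))
        for k in range(len(self.classes_)):
            Xk = X[y_idx == k]
            self.class_count_[k] = len(Xk)
            self.theta_[k] = Xk.mean(axis=0)
            self.var_[k] = np.maximum(Xk.var(axis=0), self.epsilon_)
        self.class_prior_ = self.class_count_ / n
        self.n_features_in_ = p
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            log_det = np.sum(np.log(2.0 * np.pi * self.var_[k]))
            maha = np.sum((X - self.theta_[k]) ** 2 / self.var_[k], axis=1)
            jll[:, k] = np.log(self.class_prior_[k]) - 0.5 * (log_det + maha)
        return jll

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def predict_posterior(model: GaussianNaiveBayes, x) -> float:
    """Posterior probability of the positive (last) class for one feature vector."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return float(model.predict_proba(x)[0, -1])


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    stratified: bool = True
    seed: int = 13

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def stratified_folds(labels, config: CVConfig | None = None) -> np.ndarray:
    """Fold id per sample. Within each class fold sizes differ by at most one;
    the assignment is reproducible from the config seed."""
    config = config or CVConfig()
    y = np.asarray(labels)
    if config.n_folds > len(y):
        raise ValueError("more folds than samples")
    _, counts = np.unique(y, return_counts=True)
    if config.stratified and counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{config.n_folds} folds"
        )
    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(np.zeros(len(y)), y)
    else:
        from sklearn.model_selection import KFold

        splits = KFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        ).split(np.zeros(len(y)))
    folds = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(splits):
        folds[test_idx] = fold_id
    return folds


_METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc")


@dataclass(frozen=True)
class CVReport:
    """Per-fold, fold-averaged and pooled CV metrics with out-of-fold posteriors."""

    per_fold: dict[str, tuple[float, ...]]
    averaged: dict[str, float]
    pooled: dict[str, float]
    fold_assignment: np.ndarray
    oof_posterior: np.ndarray
    threshold: float = 0.5


def _binary_metrics(y_true, posterior, threshold) -> dict[str, float]:
    y_pred = (np.asarray(posterior) >= threshold).astype(int)
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    out["roc_auc"] = (
        roc_auc_score(y_true, posterior) if len(np.unique(y_true)) == 2 else np.nan
    )
    return out


def cross_validate(
    profiles: list[CNProfile],
    genes: GeneModel,
    labels,
    feature_spec: CNFeatureSpec | None = None,
    config: CVConfig | None = None,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold CV of the CN-cluster-4 Gaussian NB.

    Top-gene selection and NB fitting both happen inside each training fold;
    held-out samples contribute only their feature rows and metric outcomes.
    Averaged metrics are unweighted means over folds; pooled metrics are
    computed once from all out-of-fold posteriors.
    """
    feature_spec = feature_spec or CNFeatureSpec()
    config = config or CVConfig()
    y = np.asarray(labels, dtype=int)
    if len(profiles) != len(y):
        raise ValueError("profiles and labels length mismatch")
    folds = stratified_folds(y, config)
    oof = np.full(len(y), np.nan)
    per_fold: dict[str, list[float]] = {m: [] for m in _METRICS}
    for fold_id in range(config.n_folds):
        test = folds == fold_id
        train = ~test
        extractor = CNFeatureExtractor(
            gene_model=genes,
            gain_margin=feature_spec.gain_margin,
            loss_margin=feature_spec.loss_margin,
            top_k_genes=feature_spec.top_k_genes,
            genome_length_mb=feature_spec.genome_length_mb,
        )
        train_profiles = [p for p, t in zip(profiles, train) if t]
        test_profiles = [p for p, t in zip(profiles, test) if t]
        X_train = extractor.fit_transform(train_profiles)
        X_test = extractor.transform(test_profiles)
        model = GaussianNaiveBayes().fit(X_train, y[train])
        pos_col = int(np.where(model.classes_ == 1)[0][0])
        post = model.predict_proba(X_test)[:, pos_col]
        oof[test] = post
        for m, v in _binary_metrics(y[test], post, threshold).items():
            per_fold[m].append(v)
    averaged = {m: float(np.nanmean(v)) for m, v in per_fold.items()}
    pooled = {
        m: float(v) for m, v in _binary_metrics(y, oof, threshold).items()
    }
    return CVReport(
        per_fold={m: tuple(v) for m, v in per_fold.items()},
        averaged=averaged,
        pooled=pooled,
        fold_assignment=folds,
        oof_posterior=oof,
        threshold=threshold,
    )
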