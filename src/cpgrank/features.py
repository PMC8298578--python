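"""Consensus feature selection across the four base learners.

Each learner ranks features on the training data — |coefficient| for
regularized logistic regression and the linear SVM, Gini impurity
importance for the random forest, gain for the gradient-boosted trees.
Features are then voted by how many learners keep them in their top
list, with ties broken by the two-sided Wilcoxon rank-sum p comparing
feature values between positive and negative CpGs, and residual ties by
feature name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from ._rng import child_seed
from .datamodel import FeatureMatrix

__all__ = ["LEARNER_KINDS", "FeatureRanking", "ConsensusSet", "rank_features", "consensus_select"]

LEARNER_KINDS = ("rlr", "svm", "rf", "gbdt")


@dataclass
class FeatureRanking:
    learner_kind: str
    features: list[str]          # best first
    importances: np.ndarray      # non-increasing, aligned with features


@dataclass
class ConsensusSet:
    features: list[str]          # full consensus order
    votes: dict[str, int]
    wilcoxon_p: dict[str, float]
    selected: list[str]          # top-K


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _ranking_estimator(kind: str, seed: int):
    # fixed, untuned defaults: feature selection precedes hyperparameter tuning
    if kind == "rlr":
        # L2-penalized (ridge) logistic regression, sklearn's default penalty
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
    if kind == "svm":
        return LinearSVC(C=1.0, dual=False)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if kind == "gbdt":
        return XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown learner kind {kind!r}")


def rank_features(
    learner_kind: str, X: FeatureMatrix, y: np.ndarray, top_k: int = 100, seed: int = 0
) -> FeatureRanking:
    """Top-``top_k`` features for one base learner (capped at n_features)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking needs both classes present")
    values = X.values
    if np.isnan(values).any():
        raise ValueError("FeatureMatrix must be imputed before ranking")
    names = np.array(X.feature_names)
    est = _ranking_estimator(learner_kind, child_seed(seed, f"rank-{learner_kind}"))
    if learner_kind in ("rlr", "svm"):
        # z-scored inputs make |weight| comparable across features
        est.fit(_standardize(values), y)
        importances = np.abs(np.ravel(est.coef_))
    elif learner_kind == "rf":
        est.fit(values, y)
        importances = est.feature_importances_
    else:  # gbdt: gain
        est.fit(values, y)
        gain = est.get_booster().get_score(importance_type="gain")
        importances = np.array([gain.get(f"f{i}", 0.0) for i in range(values.shape[1])])
    k = min(top_k, len(names))
    # stable order: importance descending, then feature name
    order = sorted(range(len(names)), key=lambda i: (-importances[i], names[i]))[:k]
    return FeatureRanking(learner_kind, [str(names[i]) for i in order], importances[order])


def wilcoxon_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free groups,
    normal approximation with continuity correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    try:
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # ties defeat the exact path
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def consensus_select(
    rankings: list[FeatureRanking], X: FeatureMatrix, y: np.ndarray, top_k: int = 60
) -> ConsensusSet:
    """Vote features across the four rankings and keep the top ``top_k``.

    Primary key: descending vote count (how many learners kept the
    feature). Secondary: ascending two-sided Wilcoxon rank-sum p of the
    feature between positive and negative CpGs. Residual: feature name.
    """
    if len(rankings) != len(LEARNER_KINDS):
        raise ValueError(f"expected {len(LEARNER_KINDS)} rankings, got {len(rankings)}")
    kinds = sorted(r.learner_kind for r in rankings)
    if kinds != sorted(LEARNER_KINDS):
        raise ValueError(f"need one ranking per learner kind, got {kinds}")
    names = X.feature_names
    if top_k > len(names):
        raise ValueError(f"top_k={top_k} exceeds the {len(names)} available features")
    votes = {f: 0 for f in names}
    for r in rankings:
        for f in r.features:
            votes[f] += 1
    values = X.values
    y = np.asarray(y)
    pos, neg = values[y == 1], values[y == 0]
    wp = {
        f: wilcoxon_rank_sum_p(pos[:, j], neg[:, j]) for j, f in enumerate(names)
    }
    order = sorted(names, key=lambda f: (-votes[f], wp[f], f))
    return ConsensusSet(features=order, votes=votes, wilcoxon_p=wp, selected=order[:top_k])
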