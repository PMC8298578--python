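"""Nested cross-validation and the soft-voting ensemble.

Layout: a 10-fold outer loop splits training CpGs nine-to-one; within
each outer training part, a budgeted, seeded random search over each
base learner's hyperparameter space is scored by mean F1 across an
inner 3-fold CV. Positives are uniformly up-sampled to match the
negatives inside every fitted fold, but evaluation always happens on
untouched test folds at the natural 1:10 imbalance. Out-of-fold member
probabilities are averaged (unweighted soft vote) and all non-empty
member subsets are compared by F1 to pick the ensemble.

`TraitEnsemble` / `TraitEnsembleResults` present this as a model object
fitted to data, with `summary()`, `predict()` and plotting on the
results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._rng import child_seed, stream
from .datamodel import FeatureMatrix, Metrics, f1_score_from
from .features import LEARNER_KINDS

log = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "CVResult",
    "EnsembleModel",
    "TraitEnsemble",
    "TraitEnsembleResults",
    "upsample_positives",
    "tune_learner",
    "nested_cv",
    "build_ensemble",
    "compute_metrics",
]

DEFAULT_MEMBERS = ("rlr", "gbdt")


# --------------------------------------------------------------------------
# hyperparameter spaces (modest on purpose: desk-scale runs finish in minutes)

def sample_params(kind: str, rng: np.random.Generator) -> dict:
    if kind == "rlr":
        return {"C": float(10 ** rng.uniform(-3, 2))}
    if kind == "svm":
        kernel = str(rng.choice(["linear", "rbf"]))
        params = {"kernel": kernel, "C": float(10 ** rng.uniform(-2, 2))}
        if kernel == "rbf":
            params["gamma"] = float(10 ** rng.uniform(-4, 0))
        return params
    if kind == "rf":
        return {
            "n_estimators": int(rng.integers(100, 401)),
            "max_depth": int(rng.integers(3, 16)),
        }
    if kind == "gbdt":
        return {
            "n_estimators": int(rng.integers(50, 301)),
            "max_depth": int(rng.integers(2, 9)),
            "learning_rate": float(10 ** rng.uniform(-2, np.log10(0.3))),
        }
    raise ValueError(f"unknown learner kind {kind!r}")


def make_estimator(kind: str, params: dict, seed: int):
    if kind == "rlr":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                # L2 (ridge) penalty is sklearn's default
                ("clf", LogisticRegression(solver="lbfgs", max_iter=2000, **params)),
            ]
        )
    if kind == "svm":
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(probability=False, **params))])
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "gbdt":
        return XGBClassifier(
            tree_method="hist", random_state=seed, n_jobs=1, verbosity=0, **params
        )
    raise ValueError(f"unknown learner kind {kind!r}")


def member_probability(kind: str, estimator, X: np.ndarray) -> np.ndarray:
    """Probability-like score in [0,1] for one member.

    The SVM exposes no native probability (calibration is out of scope);
    its decision function is squashed through a logistic so 0.5 falls on
    the decision boundary and rank order is preserved.
    """
    if kind == "svm":
        return expit(estimator.decision_function(X))
    return estimator.predict_proba(X)[:, 1]


# --------------------------------------------------------------------------

def upsample_positives(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index array that duplicates positives (uniformly, with replacement)
    until the classes balance; negatives are untouched."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to upsample")
    if pos.size >= neg.size:
        return np.arange(y.size)
    extra = rng.choice(pos, size=neg.size - pos.size, replace=True)
    return np.concatenate([np.arange(y.size), extra])


def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> Metrics:
    """AUC (rank statistic), AUPRC (precision-recall step integration),
    and precision/recall/F1 at ``threshold``."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0,1]")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return Metrics(
        auc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        precision=precision,
        recall=recall,
    )


def tune_learner(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    budget: int = 50,
    seed: int = 0,
    inner_folds: int = 3,
) -> tuple[dict, float]:
    """Budgeted random search maximizing mean inner-CV F1.

    Returns (best params, its mean F1). The search is seeded and the
    tie-break is deterministic: the first-evaluated configuration among
    those sharing the best score wins.
    """
    if budget < 5:
        raise ValueError("tuning budget below 5 is not a search")
    rng = stream(seed, f"tune-{kind}")
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=child_seed(seed, f"inner-{kind}"))
    splits = list(skf.split(X, y))
    best_params, best_f1 = None, -np.inf
    for trial in range(budget):
        params = sample_params(kind, rng)
        f1s = []
        for tr, va in splits:
            up = upsample_positives(y[tr], stream(seed, f"up-{kind}-{trial}"))
            est = make_estimator(kind, params, child_seed(seed, f"est-{kind}-{trial}"))
            est.fit(X[tr][up], y[tr][up])
            prob = member_probability(kind, est, X[va])
            pred = prob >= 0.5
            tp = np.sum(pred & (y[va] == 1))
            fp = np.sum(pred & (y[va] == 0))
            fn = np.sum(~pred & (y[va] == 1))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(f1_score_from(prec, rec))
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1:  # strict: first max wins
            best_f1, best_params = mean_f1, params
    return best_params, best_f1


# --------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Nested cross-validation layout: 10 outer folds (nine-to-one
    splits), 3 inner folds for hyperparameter search, label-stratified."""

    outer_folds: int = 10
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class CVResult:
    site_ids: list[str]
    labels: np.ndarray
    oof: dict[str, np.ndarray]                 # learner kind -> out-of-fold scores
    fold_of: np.ndarray                        # outer-fold index per site
    metrics: dict[str, Metrics]                # per learner, pooled OOF
    chosen_params: dict[str, list[tuple[dict, float]]]  # per learner, per fold
    threshold: float = 0.5

    def best_params(self, kind: str) -> dict:
        """Per-fold tuned configs collapsed to one: highest inner F1 wins."""
        configs = self.chosen_params[kind]
        return max(enumerate(configs), key=lambda kv: kv[1][1])[1][0]


def nested_cv(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    learner_kinds: tuple[str, ...] = LEARNER_KINDS,
    plan: CVPlan | None = None,
    budget: int = 50,
    site_ids: list[str] | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Out-of-fold member probabilities for every training site.

    Each outer fold is the test set exactly once, so the pooled
    out-of-fold scores cover the whole dataset; metrics are evaluated at
    the natural class imbalance.
    """
    plan = plan or CVPlan()
    if isinstance(X, FeatureMatrix):
        site_ids = site_ids or X.site_ids
        X = X.values
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("impute features before nested_cv")
    if X.shape[0] < 30:
        raise ValueError("nested_cv needs at least 30 sites")
    site_ids = site_ids or [str(i) for i in range(X.shape[0])]
    unknown = set(learner_kinds) - set(LEARNER_KINDS)
    if unknown:
        raise ValueError(f"unknown learner kinds {sorted(unknown)}")

    skf = StratifiedKFold(
        n_splits=plan.outer_folds, shuffle=True, random_state=child_seed(plan.seed, "outer")
    )
    oof = {k: np.full(X.shape[0], np.nan) for k in learner_kinds}
    fold_of = np.full(X.shape[0], -1)
    chosen: dict[str, list[tuple[dict, float]]] = {k: [] for k in learner_kinds}
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"outer fold {fold} lost a class under stratification")
        fold_of[te] = fold
        for kind in learner_kinds:
            params, inner_f1 = tune_learner(
                kind, X[tr], y[tr],
                budget=budget,
                seed=child_seed(plan.seed, f"fold{fold}-{kind}"),
                inner_folds=plan.inner_folds,
            )
            chosen[kind].append((params, inner_f1))
            up = upsample_positives(y[tr], stream(plan.seed, f"fit-up-{fold}-{kind}"))
            est = make_estimator(kind, params, child_seed(plan.seed, f"fit-{fold}-{kind}"))
            est.fit(X[tr][up], y[tr][up])
            oof[kind][te] = member_probability(kind, est, X[te])
    metrics = {k: compute_metrics(oof[k], y, threshold) for k in learner_kinds}
    return CVResult(
        site_ids=list(site_ids),
        labels=y,
        oof=oof,
        fold_of=fold_of,
        metrics=metrics,
        chosen_params=chosen,
        threshold=threshold,
    )


# --------------------------------------------------------------------------

class EnsembleModel:
    """Deployable soft-voting ensemble.

    Carries the fitted member estimators, the selected feature names,
    the training-set imputation medians (scaling lives inside member
    pipelines), and the voting rule: unweighted mean of member
    probabilities.
    """

    def __init__(
        self,
        members: dict[str, object],
        feature_names: list[str],
        impute_medians: pd.Series,
        params: dict[str, dict],
        seed: int,
        threshold: float = 0.5,
    ):
        self.members = members
        self.feature_names = list(feature_names)
        self.impute_medians = impute_medians
        self.params = params
        self.seed = seed
        self.threshold = threshold

    @property
    def member_kinds(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def predict_proba(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.df.reindex(columns=self.feature_names)
            X = X.fillna(self.impute_medians).to_numpy(float)
        X = np.asarray(X, float)
        probs = [member_probability(k, self.members[k], X) for k in self.member_kinds]
        return np.mean(probs, axis=0)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "member_kinds": list(self.member_kinds),
            "feature_names": self.feature_names,
            "impute_medians": {k: float(v) for k, v in self.impute_medians.items()},
            "params": self.params,
            "seed": self.seed,
            "threshold": self.threshold,
            "voting": "unweighted mean of member probabilities",
            "evaluation": "pooled out-of-fold scores at natural imbalance",
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for kind, est in self.members.items():
            joblib.dump(est, out_dir / f"member_{kind}.joblib")

    @classmethod
    def load(cls, out_dir) -> "EnsembleModel":
        out_dir = Path(out_dir)
        manifest = json.loads((out_dir / "manifest.json").read_text())
        members = {
            kind: joblib.load(out_dir / f"member_{kind}.joblib")
            for kind in manifest["member_kinds"]
        }
        return cls(
            members=members,
            feature_names=manifest["feature_names"],
            impute_medians=pd.Series(manifest["impute_medians"]),
            params=manifest["params"],
            seed=manifest["seed"],
            threshold=manifest.get("threshold", 0.5),
        )


def build_ensemble(
    cv_result: CVResult,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    combination_search: bool = True,
    metric: str = "f1",
    seed: int = 0,
    impute_medians: pd.Series | None = None,
    feature_names: list[str] | None = None,
) -> tuple[EnsembleModel, dict[tuple[str, ...], Metrics], tuple[str, ...]]:
    """Pick the member subset with the best soft-voted OOF metric and
    refit it on the full training set for deployment.

    With ``combination_search`` all 2^k - 1 non-empty subsets of the
    learners present in ``cv_result`` are compared; otherwise the
    default members (RLR + GBDT) are used directly.
    """
    if isinstance(X, FeatureMatrix):
        feature_names = feature_names or X.feature_names
        X = X.values
    X = np.asarray(X, float)
    y = np.asarray(y)
    kinds = sorted(cv_result.oof)
    combo_metrics: dict[tuple[str, ...], Metrics] = {}
    for r in range(1, len(kinds) + 1):
        for combo in combinations(kinds, r):
            vote = np.mean([cv_result.oof[k] for k in combo], axis=0)
            combo_metrics[combo] = compute_metrics(vote, y, cv_result.threshold)

    if combination_search:
        key = (lambda m: m.f1) if metric == "f1" else (lambda m: m.auprc)
        best_combo = max(sorted(combo_metrics), key=lambda c: key(combo_metrics[c]))
    else:
        best_combo = tuple(k for k in kinds if k in DEFAULT_MEMBERS) or tuple(kinds)
        best_combo = tuple(sorted(best_combo))

    members = {}
    params = {}
    for kind in best_combo:
        p = cv_result.best_params(kind)
        params[kind] = p
        up = upsample_positives(y, stream(seed, f"final-up-{kind}"))
        est = make_estimator(kind, p, child_seed(seed, f"final-{kind}"))
        est.fit(X[up], y[up])
        members[kind] = est
    model = EnsembleModel(
        members=members,
        feature_names=feature_names or [f"f{i}" for i in range(X.shape[1])],
        impute_medians=impute_medians if impute_medians is not None else pd.Series(np.zeros(X.shape[1]), index=feature_names or range(X.shape[1])),
        params=params,
        seed=seed,
        threshold=cv_result.threshold,
    )
    return model, combo_metrics, best_combo


# --------------------------------------------------------------------------
# model / results objects

class TraitEnsemble:
    """Trait-association classifier over a training set of CpGs.

    Built from an (already consensus-selected) feature matrix and 0/1
    labels; ``fit`` runs the nested CV and ensemble construction and
    returns a results object.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        labels: np.ndarray,
        learner_kinds: tuple[str, ...] = LEARNER_KINDS,
        plan: CVPlan | None = None,
    ):
        imputed, medians = features.median_impute()
        self.features = imputed
        self.impute_medians = medians
        self.labels = np.asarray(labels)
        self.learner_kinds = tuple(learner_kinds)
        self.plan = plan or CVPlan()

    @classmethod
    def from_training_set(cls, training_set, features: FeatureMatrix, **kwargs) -> "TraitEnsemble":
        sub = features.subset(training_set.site_ids)
        return cls(sub, training_set.labels, **kwargs)

    def fit(
        self,
        budget: int = 50,
        combination_search: bool = True,
        threshold: float = 0.5,
        seed: int | None = None,
    ) -> "TraitEnsembleResults":
        seed = self.plan.seed if seed is None else seed
        cv = nested_cv(
            self.features,
            self.labels,
            learner_kinds=self.learner_kinds,
            plan=self.plan,
            budget=budget,
            threshold=threshold,
        )
        model, combo_metrics, best_combo = build_ensemble(
            cv,
            self.features,
            self.labels,
            combination_search=combination_search,
            seed=seed,
            impute_medians=self.impute_medians,
        )
        return TraitEnsembleResults(self, cv, model, combo_metrics, best_combo)


class TraitEnsembleResults:
    """Fit results: out-of-fold scores, per-learner and per-combination
    metrics, the chosen ensemble, and the deployable model."""

    def __init__(self, model_spec, cv_result, ensemble, combo_metrics, best_combination):
        self.model_spec = model_spec
        self.cv_result = cv_result
        self.ensemble = ensemble
        self.combo_metrics = combo_metrics
        self.best_combination = best_combination

    @property
    def oof_ensemble_scores(self) -> np.ndarray:
        return np.mean([self.cv_result.oof[k] for k in self.best_combination], axis=0)

    @property
    def metrics(self) -> Metrics:
        return self.combo_metrics[self.best_combination]

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        return self.ensemble.predict_proba(features)

    def summary(self) -> str:
        lines = [
            "Trait-association ensemble (nested CV, soft voting)",
            f"  sites: {len(self.cv_result.site_ids)}"
            f"  positives: {int(self.cv_result.labels.sum())}"
            f"  folds: {self.model_spec.plan.outer_folds}x{self.model_spec.plan.inner_folds}",
            f"  ensemble members: {' + '.join(self.best_combination).upper()}",
            "",
            f"  {'learner':<12}{'AUC':>8}{'AUPR':>8}{'F1':>8}{'Prec':>8}{'Recall':>8}",
        ]
        for kind, m in sorted(self.cv_result.metrics.items()):
            lines.append(
                f"  {kind:<12}{m.auc:>8.3f}{m.auprc:>8.3f}{m.f1:>8.3f}{m.precision:>8.3f}{m.recall:>8.3f}"
            )
        m = self.metrics
        lines.append(
            f"  {'ensemble':<12}{m.auc:>8.3f}{m.auprc:>8.3f}{m.f1:>8.3f}{m.precision:>8.3f}{m.recall:>8.3f}"
        )
        return "\n".join(lines)

    def metrics_frame(self) -> pd.DataFrame:
        rows = {kind: m.as_dict() for kind, m in self.cv_result.metrics.items()}
        rows["ensemble(" + "+".join(self.best_combination) + ")"] = self.metrics.as_dict()
        return pd.DataFrame(rows).T

    def plot_curves(self, ax_pair=None):
        """ROC and precision-recall curves of the pooled OOF ensemble scores."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import precision_recall_curve, roc_curve

        if ax_pair is None:
            _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
        y = self.cv_result.labels
        s = self.oof_ensemble_scores
        fpr, tpr, _ = roc_curve(y, s)
        ax_pair[0].plot(fpr, tpr)
        ax_pair[0].plot([0, 1], [0, 1], ls="--", c="grey")
        ax_pair[0].set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUC={self.metrics.auc:.3f})")
        prec, rec, _ = precision_recall_curve(y, s)
        ax_pair[1].plot(rec, prec)
        ax_pair[1].set(xlabel="Recall", ylabel="Precision", title=f"PRC (AUPR={self.metrics.auprc:.3f})")
        return ax_pair
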