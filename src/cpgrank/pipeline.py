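"""End-to-end orchestration: simulate -> EWAS -> training set ->
consensus features -> nested-CV ensemble -> genome-wide ranks.

This is the programmatic counterpart of running the CLI stages in
sequence, used for validation runs on synthetic studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .datamodel import BinnedFeatureStore, CpGSite, FeatureMatrix
from .ensemble import CVPlan, TraitEnsemble, TraitEnsembleResults
from .ewas import run_ewas
from .features import LEARNER_KINDS, consensus_select, rank_features
from .scorer import assemble_records, score_genome
from .simulate import SimulationSpec, SyntheticTruth, simulate_study
from .trainset import TrainingSet, build_training_set

__all__ = ["PipelineResult", "run_pipeline", "select_consensus_features"]


@dataclass
class PipelineResult:
    spec: SimulationSpec
    config: RunConfig
    sites: list[CpGSite]
    stats_by_trait: dict[str, list]
    training_set: TrainingSet
    consensus: object
    fit: TraitEnsembleResults
    truth: SyntheticTruth
    store: BinnedFeatureStore
    records: list | None = None


def select_consensus_features(
    features: FeatureMatrix, labels: np.ndarray, config: RunConfig, seed: int
):
    imputed, _ = features.median_impute()
    rankings = [
        rank_features(kind, imputed, labels, top_k=config.top_k_rank, seed=seed)
        for kind in LEARNER_KINDS
    ]
    return consensus_select(rankings, imputed, labels, top_k=config.top_k_consensus)


def run_pipeline(
    spec: SimulationSpec,
    trait_name: str = "pathology",
    config: RunConfig | None = None,
    learner_kinds: tuple[str, ...] = ("rlr", "gbdt"),
    combination_search: bool = False,
    score_whole_genome: bool = False,
    permute_labels: bool = False,
) -> PipelineResult:
    """One full synthetic study for one trait.

    ``learner_kinds`` defaults to the RLR+GBDT pair used for deployment;
    pass all four kinds plus ``combination_search=True`` for the full
    subset search. ``permute_labels`` shuffles training labels (a null
    calibration run).
    """
    config = (config or RunConfig()).validate()
    seed = spec.seed

    _, sites, beta, covariates, traits, features, store, truth = simulate_study(spec)

    stats_by_trait = {
        t.name: run_ewas(beta, t, traits[t.name], covariates) for t in spec.traits
    }
    training_set = build_training_set(
        stats_by_trait,
        trait_name,
        p_pos=config.p_pos,
        p_neg=config.p_neg,
        ratio=config.neg_pos_ratio,
        max_beta_diff=config.max_beta_diff,
    )
    train_features = features.subset(training_set.site_ids)
    labels = training_set.labels
    consensus = select_consensus_features(train_features, labels, config, seed)
    selected = FeatureMatrix(train_features.df[consensus.selected])
    if permute_labels:
        # null-calibration mode for the CV/ensemble stage: labels are
        # shuffled after feature selection, so the check isolates the
        # cross-validation machinery (consensus selection is a pre-CV
        # stage by design; see the methods note on its optimism)
        labels = np.random.default_rng(seed).permutation(labels)

    model = TraitEnsemble(
        selected,
        labels,
        learner_kinds=learner_kinds,
        plan=CVPlan(config.outer_folds, config.inner_folds, seed=seed),
    )
    fit = model.fit(
        budget=config.tuning_budget,
        combination_search=combination_search,
        threshold=config.threshold,
        seed=seed,
    )

    records = None
    if score_whole_genome:
        scores = score_genome(fit.ensemble, sites, store)
        records = assemble_records(
            sites, {trait_name: scores}, composite=config.composite
        )

    return PipelineResult(
        spec=spec,
        config=config,
        sites=sites,
        stats_by_trait=stats_by_trait,
        training_set=training_set,
        consensus=consensus,
        fit=fit,
        truth=truth,
        store=store,
        records=records,
    )
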