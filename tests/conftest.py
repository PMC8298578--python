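import warnings

import pytest

from cpgrank import SimulationSpec
from cpgrank.config import RunConfig
from cpgrank.pipeline import run_pipeline
from cpgrank.simulate import simulate_study

# silence sklearn/xgboost chatter so real warnings stay visible
warnings.filterwarnings("ignore", category=FutureWarning)

# a reduced study: one 400-kb chromosome, 300 samples, ~30 positive CpGs
SMALL_STUDY_KW = dict(
    n_samples=300,
    n_chroms=1,
    chrom_length_bp=400_000,
    n_causal_cpgs=60,
    array_fraction=0.6,
)

# the full planted-signal design the package defaults to
FULL_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(seed=7, **SMALL_STUDY_KW)


@pytest.fixture(scope="session")
def small_study(small_spec):
    """(sequences, sites, beta, covariates, traits, features, store, truth)."""
    return simulate_study(small_spec)


@pytest.fixture(scope="session")
def small_fit(small_spec):
    """Full pipeline on the reduced study, including genome-wide scores."""
    return run_pipeline(
        small_spec,
        "pathology",
        RunConfig(tuning_budget=5),
        score_whole_genome=True,
    )


@pytest.fixture(scope="session")
def planted_runs():
    """Five independent full-scale planted-signal studies (d=1.5).

    Shared by the end-to-end recovery checks; each run is a complete
    simulate -> EWAS -> training set -> consensus -> nested CV ->
    genome-wide scoring pass.
    """
    cfg = RunConfig(tuning_budget=5)
    return {
        seed: run_pipeline(SimulationSpec(seed=seed), "pathology", cfg, score_whole_genome=True)
        for seed in FULL_SEEDS
    }
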