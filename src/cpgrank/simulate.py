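"""Synthetic study generator.

Emits a complete, statistically structured stand-in for an array EWAS
study: a CpG-bearing genome, a cohort methylation matrix with covariate
confounding, continuous and binary traits driven by a shared latent
pathology burden, and binned epigenomic feature tracks in which a small
informative subset is shifted at trait-associated CpG bins. Ground truth
(causal sites, informative features) is recorded for recovery tests.

The generative model, briefly: each CpG j has a bimodal baseline
methylation level m_j (a hypo/hyper mixture of Beta draws); per-sample
methylation is formed on the logit scale as

    logit(beta_ij) = logit(m_j) + covariate effects + effect * latent_i * [j causal] + noise

so that confounders act additively and the model stays invertible. The
binary trait thresholds the latent at its median; the continuous trait
is the latent itself. All randomness flows from one integer seed through
named per-stage generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import stream
from .datamodel import BIN_BP, BinnedFeatureStore, CpGSite, FeatureMatrix, TraitSpec
from .io import write_fasta

__all__ = [
    "SimulationSpec",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_cohort",
    "simulate_features",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _default_traits() -> list[TraitSpec]:
    return [TraitSpec("pathology", "continuous"), TraitSpec("diagnosis", "binary")]


@dataclass
class SimulationSpec:
    """Parameters of a synthetic study.

    Defaults emulate a well-powered cohort at desk scale: 500 samples
    (the source cohorts range 113-717), CpG density 10/kb (the human
    genome averages ~9/kb), 350 causal CpGs per latent trait with a
    logit-scale effect of 0.25 per SD of the latent (essentially full
    power at p <= 1e-5 with n=500), 200 feature tracks of which 10 are
    informative with a standardized shift d=1.5 at causal bins, and half
    of all CpGs flagged as on-array so that off-array recovery is
    testable.
    """

    n_samples: int = 500
    n_chroms: int = 2
    chrom_length_bp: int = 750_000
    cpg_density_per_kb: float = 10.0
    n_features: int = 200
    n_informative_features: int = 10
    feature_effect_size: float = 1.5  # standardized mean shift d at causal bins
    n_causal_cpgs: int = 350
    causal_effect: float = 0.25      # logit-beta shift per SD of the latent trait
    noise_sd: float = 0.5            # residual SD on the logit scale
    traits: list[TraitSpec] = field(default_factory=_default_traits)
    # covariate effects on logit(beta): per year of age, per unit sex/batch,
    # per unit neuron proportion
    age_effect: float = 0.02
    sex_effect: float = 0.10
    batch_effect: float = 0.15
    neuron_effect: float = 1.5
    confounding: float = 0.3         # loading of age and neuron proportion on the latent
    array_fraction: float = 0.5
    missing_feature_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.array_fraction <= 1):
            raise ValueError(f"array_fraction {self.array_fraction} outside (0,1]")
        if self.n_informative_features > self.n_features:
            raise ValueError("n_informative_features exceeds n_features")
        if self.feature_effect_size < 0:
            raise ValueError("feature_effect_size must be >= 0")
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study, for parameter-recovery tests."""

    causal_sites: dict[str, list[str]]        # trait name -> site_ids
    informative_features: list[str]

    def to_json(self) -> dict:
        return {
            "causal_sites": self.causal_sites,
            "informative_features": self.informative_features,
        }


def simulate_genome(spec: SimulationSpec, fasta_path=None) -> tuple[dict[str, str], list[CpGSite]]:
    """Random genome hitting the target CpG density.

    A uniform random sequence is CpG-rich (1/16 per position), so all CG
    dinucleotides are first broken and the target number is then planted
    at positions spaced >= 2 bp apart; the returned site list is a fresh
    CG scan of the emitted sequence.
    """
    rng = stream(spec.seed, "genome")
    L = spec.chrom_length_bp
    k = int(round(spec.cpg_density_per_kb * L / 1000))
    if k < 1 or L < 3 * k - 1:
        raise ValueError(f"CpG density {spec.cpg_density_per_kb}/kb unachievable at length {L}")
    sequences: dict[str, str] = {}
    sites: list[CpGSite] = []
    array_rng = stream(spec.seed, "array-mask")
    for c in range(spec.n_chroms):
        chrom = f"chr{c + 1}"
        seq = rng.choice(_BASES, size=L)
        # break every CG: replacing the G with A/T cannot create a new CG
        cg = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        seq[cg + 1] = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=cg.size)
        # plant k CpGs with pairwise gaps >= 2 (classic min-gap trick)
        draw = np.sort(rng.choice(L - 1 - 2 * (k - 1), size=k, replace=False))
        pos = draw + 2 * np.arange(k)
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        sequences[chrom] = seq.tobytes().decode()
        # fresh scan of what was actually emitted
        scan = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        on_array = array_rng.random(scan.size) < spec.array_fraction
        sites.extend(CpGSite(chrom, int(p), on_array=bool(a)) for p, a in zip(scan, on_array))
    if fasta_path is not None:
        write_fasta(sequences, fasta_path)
    return sequences, sites


def simulate_cohort(
    spec: SimulationSpec, sites: list[CpGSite]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Cohort methylation, covariates and traits over the on-array CpGs.

    Returns (beta, covariates, traits, truth); beta rows are samples,
    columns are on-array site_ids, values strictly inside (0,1).
    Causal sites are drawn from ALL CpGs — those off the array leave no
    trace in beta but still mark their 200-bp bins for the informative
    feature tracks, which is what makes off-array recovery testable.
    """
    if not sites:
        raise ValueError("no CpG sites supplied")
    if spec.n_samples < 10:
        raise ValueError("n_samples < 10 leaves no residual degrees of freedom downstream")
    rng = stream(spec.seed, "cohort")

    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    age = rng.normal(80.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    batch = rng.integers(0, 2, n).astype(float)
    neuron = np.clip(rng.normal(0.4, 0.08, n), 0.05, 0.95)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "batch": batch, "neuron_prop": neuron}, index=sample_ids
    )

    # latent pathology burden, confounded with age and neuron proportion
    z_age = (age - age.mean()) / age.std()
    z_neuron = (neuron - neuron.mean()) / neuron.std()
    resid = np.sqrt(max(1.0 - 2 * spec.confounding**2, 0.05))
    latent = spec.confounding * z_age + spec.confounding * z_neuron + resid * rng.normal(size=n)
    latent = (latent - latent.mean()) / latent.std()

    traits = pd.DataFrame(index=sample_ids)
    causal_sites: dict[str, list[str]] = {}
    all_ids = [s.site_id for s in sites]
    causal_idx = rng.choice(len(sites), size=min(spec.n_causal_cpgs, len(sites)), replace=False)
    causal_set = {all_ids[i] for i in causal_idx}
    for t in spec.traits:
        if t.kind == "binary":
            traits[t.name] = (latent > np.median(latent)).astype(float)
        else:
            traits[t.name] = latent
        # all traits read out the same latent, so they share causal CpGs
        causal_sites[t.name] = sorted(causal_set)

    on_array = [s for s in sites if s.on_array]
    m = len(on_array)
    # bimodal baseline: hypo / intermediate / hyper mixture
    comp = rng.choice(3, size=m, p=[0.4, 0.2, 0.4])
    a_par = np.array([2.0, 5.0, 8.0])[comp]
    b_par = np.array([8.0, 5.0, 2.0])[comp]
    baseline = rng.beta(a_par, b_par, size=m)
    mu = logit(np.clip(baseline, 1e-3, 1 - 1e-3))

    is_causal = np.array([s.site_id in causal_set for s in on_array])
    # heterogeneous effect sizes: real EWAS hits span strong to borderline,
    # which is what leaves "suggestive" CpGs just above the training threshold
    multiplier = rng.uniform(0.4, 1.6, size=m)
    eff = np.where(is_causal, spec.causal_effect * multiplier, 0.0)
    # random sign so causal CpGs are a mix of hyper- and hypo-methylated with disease
    sign = rng.choice([-1.0, 1.0], size=m)

    logit_beta = (
        mu[None, :]
        + spec.age_effect * (age - 80.0)[:, None]
        + spec.sex_effect * sex[:, None]
        + spec.batch_effect * batch[:, None]
        + spec.neuron_effect * (neuron - 0.4)[:, None]
        + (eff * sign)[None, :] * latent[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(n, m))
    )
    beta = np.clip(expit(logit_beta), 1e-4, 1 - 1e-4)
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=[s.site_id for s in on_array])

    truth = SyntheticTruth(causal_sites=causal_sites, informative_features=[])
    return beta_df, covariates, traits, truth


def simulate_features(
    spec: SimulationSpec, sites: list[CpGSite], truth: SyntheticTruth
) -> tuple[FeatureMatrix, BinnedFeatureStore]:
    """Binned feature tracks with an informative subset.

    Every track takes one N(0,1) value per 200-bp bin; the first
    n_informative tracks gain a +d shift in bins containing a truly
    trait-associated CpG (union over traits). Missingness is applied at
    the bin level so CpGs sharing a bin always share a feature vector.
    """
    rng = stream(spec.seed, "features")
    names = [f"feat_{i:03d}" for i in range(spec.n_features)]
    informative = names[: spec.n_informative_features]

    causal_union = set().union(*truth.causal_sites.values()) if truth.causal_sites else set()
    causal_bins = {
        (s.chrom, s.bin_index) for s in sites if s.site_id in causal_union
    }
    bins = sorted({(s.chrom, s.bin_index) for s in sites})
    values = rng.normal(size=(len(bins), spec.n_features))
    for i, key in enumerate(bins):
        if key in causal_bins:
            values[i, : spec.n_informative_features] += spec.feature_effect_size
    if spec.missing_feature_rate > 0:
        mask = rng.random(values.shape) < spec.missing_feature_rate
        values[mask] = np.nan
    store = BinnedFeatureStore(names, {key: values[i] for i, key in enumerate(bins)})
    truth.informative_features = informative
    fm, _ = store.matrix_for_sites(sites)
    return fm, store


def simulate_study(spec: SimulationSpec, out_dir=None):
    """Run all three generators; optionally persist the standard files.

    Returns (sequences, sites, beta, covariates, traits, features, store, truth).
    """
    import json
    from pathlib import Path

    from .io import write_cpg_bed

    fasta = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
    sequences, sites = simulate_genome(spec, fasta_path=fasta)
    beta, covariates, traits, truth = simulate_cohort(spec, sites)
    features, store = simulate_features(spec, sites, truth)
    if out_dir is not None:
        write_cpg_bed(sites, out_dir / "sites.bed")
        beta.to_csv(out_dir / "beta.tsv", sep="\t", index_label="sample_id", float_format="%.6g")
        covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index_label="sample_id")
        traits.to_csv(out_dir / "traits.tsv", sep="\t", index_label="sample_id")
        store.to_tsv(out_dir / "features.tsv")
        (out_dir / "truth.json").write_text(json.dumps(truth.to_json(), indent=1))
    return sequences, sites, beta, covariates, traits, features, store, truth
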