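"""Site-level association testing and cluster-level validation calls.

Each CpG's methylation (beta or logit-beta) is regressed on the trait
plus covariates by ordinary least squares; the reported p-value is the
two-sided t-test on the trait coefficient. Binary traits use the same
linear model (a linear probability model), mirroring common array-EWAS
practice. The fit is vectorized across CpGs: one pseudoinverse of the
shared design matrix serves every site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit as _logit

from .datamodel import CpGSite, SummaryStat, TraitSpec

log = logging.getLogger(__name__)

__all__ = ["run_ewas", "logit_beta", "cluster_sites", "call_clusters", "ClusterCall"]

LOGIT_EPS = 1e-3


def logit_beta(beta, eps: float = LOGIT_EPS):
    """log(beta/(1-beta)), clamping to [eps, 1-eps] with a warning.

    The logit transform stabilizes the variance of methylation fractions
    but is undefined at 0/1; boundary values are clamped.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("beta values must be finite and within [0,1]")
    if np.any(arr < eps) or np.any(arr > 1 - eps):
        warnings.warn(f"beta values clamped to [{eps}, {1 - eps}] before logit", stacklevel=2)
        arr = np.clip(arr, eps, 1 - eps)
    out = _logit(arr)
    return float(out) if np.isscalar(beta) else out


def run_ewas(
    beta: pd.DataFrame,
    trait: TraitSpec,
    trait_values: pd.Series,
    covariates: pd.DataFrame | None = None,
    scale: str = "beta",
) -> list[SummaryStat]:
    """Association test of every CpG against one trait.

    beta: samples x CpGs methylation fractions; trait_values / covariates
    indexed by the same sample ids. ``scale`` selects the regression
    outcome ("beta" or "logit"). Returns one SummaryStat per CpG with
    beta_mean always computed on the raw beta scale. CpGs with constant
    methylation get p=1 by convention; a rank-deficient design yields
    NA p-values with a warning rather than an error.
    """
    if scale not in ("beta", "logit"):
        raise ValueError(f"unknown scale {scale!r}")
    y_trait = trait.apply_transform(trait_values.loc[beta.index].to_numpy())
    cols = [np.ones(len(beta)), y_trait]
    if covariates is not None:
        cov = covariates.loc[beta.index]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n_samples={n} too small for {p} regression terms")

    Y = beta.to_numpy(dtype=float)
    beta_means = Y.mean(axis=0)
    if scale == "logit":
        Y = logit_beta(Y)

    rank = np.linalg.matrix_rank(X)
    deficient = rank < p
    if deficient:
        warnings.warn("rank-deficient design matrix; p-values set to NA", stacklevel=2)

    XtX_inv = np.linalg.pinv(X.T @ X)
    coef = XtX_inv @ X.T @ Y                     # p x m
    resid = Y - X @ coef
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))

    effects = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effects / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # constant methylation carries no information: p = 1 by convention
    # (max-min is exact where std picks up mean round-off)
    constant = (Y.max(axis=0) - Y.min(axis=0)) == 0
    pvals = np.where(constant, 1.0, pvals)
    effects = np.where(constant, 0.0, effects)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    if deficient:
        pvals = np.full_like(pvals, np.nan)

    return [
        SummaryStat(site_id, trait.name, float(e), float(pv), float(bm))
        for site_id, e, pv, bm in zip(beta.columns, effects, pvals, beta_means)
    ]


@dataclass
class ClusterCall:
    """Validation verdict for one CpG cluster.

    A cluster is called trait-associated when any member CpG reaches
    unadjusted p < 0.05 on any trait; per-trait flags are also kept.
    No multiplicity adjustment is applied across traits — this matches
    the validation design being reproduced and is flagged in metadata.
    """

    cluster_id: int
    site_ids: list[str]
    min_p: float
    associated: bool
    per_trait: dict[str, bool]


def cluster_sites(sites: list[CpGSite], gap_bp: int = 500) -> dict[str, int]:
    """Transitively merge CpGs within ``gap_bp`` of each other into clusters.

    Returns site_id -> cluster_id; clusters are numbered in (chrom, pos)
    order.
    """
    assignment: dict[str, int] = {}
    cid = -1
    last_chrom, last_pos = None, None
    for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        if s.chrom != last_chrom or last_pos is None or s.pos - last_pos > gap_bp:
            cid += 1
        assignment[s.site_id] = cid
        last_chrom, last_pos = s.chrom, s.pos
    return assignment


def call_clusters(
    stats_by_trait: dict[str, dict[str, float]],
    assignment: dict[str, int],
    alpha: float = 0.05,
) -> list[ClusterCall]:
    """Cluster-level association calls from per-trait per-site p-values.

    stats_by_trait: trait -> {site_id -> p}. Every site in ``assignment``
    must have a p-value in at least one trait; empty clusters are an
    error.
    """
    if not assignment:
        raise ValueError("empty cluster assignment")
    clusters: dict[int, list[str]] = {}
    for site_id, cid in assignment.items():
        clusters.setdefault(cid, []).append(site_id)
    calls = []
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        per_trait: dict[str, bool] = {}
        min_p = np.inf
        seen = False
        for trait, pmap in stats_by_trait.items():
            ps = [pmap[s] for s in members if s in pmap and not np.isnan(pmap[s])]
            if ps:
                seen = True
                per_trait[trait] = min(ps) < alpha
                min_p = min(min_p, min(ps))
            else:
                per_trait[trait] = False
        if not seen:
            raise ValueError(f"cluster {cid} has no tested members")
        calls.append(
            ClusterCall(cid, members, float(min_p), bool(min_p < alpha), per_trait)
        )
    return calls
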