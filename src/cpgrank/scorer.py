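"""Genome-wide scoring and rank-based significance.

Every forward-strand CG dinucleotide in a genome is enumerated (a CpG
is its own reverse complement, so one strand suffices), features are
attached through the 200-bp bin of each site, the trained ensemble
scores them in chunks, and scores are converted to rank-based
quantities: rank (1 = highest), the log-scale rank score
LRS = -log10(rank/total), and the empirical p-value rank/total. A
composite over traits (sum of per-trait LRS by default) drives the
spacing-constrained selection of "detached" top loci.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datamodel import BinnedFeatureStore, CpGSite, PredictionRecord

log = logging.getLogger(__name__)

__all__ = [
    "enumerate_cpgs",
    "score_genome",
    "compute_lrs",
    "assemble_records",
    "select_detached_loci",
    "LocusSelection",
]


def enumerate_cpgs(fasta_path=None, sequences: dict[str, str] | None = None) -> list[CpGSite]:
    """All forward-strand CG dinucleotides, ordered by (chrom, pos).

    Soft-masked (lowercase) bases count; N (or any non-ACGT letter)
    breaks a dinucleotide. Provide either a FASTA path or an in-memory
    chrom -> sequence mapping.
    """
    if sequences is None:
        if fasta_path is None:
            raise ValueError("provide a FASTA path or sequences")
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path), as_raw=True, rebuild=True)
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty FASTA: nothing to enumerate")
    sites: list[CpGSite] = []
    for chrom in sorted(sequences):
        seq = np.frombuffer(sequences[chrom].upper().encode(), dtype="S1")
        hits = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        sites.extend(CpGSite(chrom, int(p)) for p in hits)
    return sites


def score_genome(
    model,
    sites: list[CpGSite],
    store: BinnedFeatureStore,
    chunk_size: int = 10_000,
) -> np.ndarray:
    """Ensemble score for every site, streamed in chunks.

    Feature vectors come from each site's 200-bp bin; sites in bins the
    store does not cover are filled with the model's training medians
    and counted in a warning. Chunking cannot change the scores.
    """
    name_idx = [store.feature_names.index(f) for f in model.feature_names]
    medians = model.impute_medians.to_numpy(float)
    scores = np.empty(len(sites))
    n_uncovered = 0
    for start in range(0, len(sites), chunk_size):
        chunk = sites[start : start + chunk_size]
        X = np.empty((len(chunk), len(name_idx)))
        for i, s in enumerate(chunk):
            vec = store.vector_for(s.chrom, s.pos)
            if vec is None:
                X[i] = medians
                n_uncovered += 1
            else:
                row = vec[name_idx]
                missing = np.isnan(row)
                if missing.any():
                    row = np.where(missing, medians, row)
                X[i] = row
        scores[start : start + len(chunk)] = model.predict_proba(X)
    if n_uncovered:
        warnings.warn(f"{n_uncovered} sites fell in uncovered bins; imputed with training medians")
    return scores


def compute_lrs(scores: np.ndarray, total: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ranks, LRS and empirical p for one trait's scores.

    Rank 1 is the highest score; tied scores all receive the best
    (minimum) rank of their block, so equal scores get equal LRS.
    ``total`` defaults to the number of scores but may be overridden
    when ranking a subset against a known genome-wide total.
    """
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    total = int(total if total is not None else scores.size)
    if total < 1:
        raise ValueError("total must be >= 1")
    ranks = rankdata(-scores, method="min").astype(int)
    empirical_p = ranks / total
    lrs = -np.log10(empirical_p)
    return ranks, lrs, empirical_p


def assemble_records(
    sites: list[CpGSite],
    scores_by_trait: dict[str, np.ndarray],
    composite: str = "sum",
    total: int | None = None,
) -> list[PredictionRecord]:
    """Per-trait ranks/LRS/empirical p plus a composite per CpG.

    ``composite`` combines the per-trait LRS values: "sum" (default,
    the total LRS), "mean" or "max".
    """
    if composite not in ("sum", "mean", "max"):
        raise ValueError(f"unknown composite rule {composite!r}")
    records = [PredictionRecord(s.site_id, s.chrom, s.pos) for s in sites]
    for trait, scores in scores_by_trait.items():
        if len(scores) != len(sites):
            raise ValueError(f"trait {trait}: {len(scores)} scores for {len(sites)} sites")
        ranks, lrs, emp = compute_lrs(scores, total=total)
        for r, sc, rk, l, e in zip(records, scores, ranks, lrs, emp):
            r.score[trait] = float(sc)
            r.rank[trait] = int(rk)
            r.lrs[trait] = float(l)
            r.empirical_p[trait] = float(e)
    agg = {"sum": np.sum, "mean": np.mean, "max": np.max}[composite]
    for r in records:
        r.composite = float(agg(list(r.lrs.values()))) if r.lrs else float("nan")
    return records


@dataclass
class LocusSelection:
    site_ids: list[str]          # selection order (descending composite)
    spacing_bp: int
    trace: list[str]             # why each considered site was kept/skipped


def select_detached_loci(
    records: list[PredictionRecord], spacing_bp: int, k: int
) -> LocusSelection:
    """Greedy stepwise top-locus selection under a spacing constraint.

    Walk records by descending composite score (ties by (chrom, pos) for
    determinism); keep a site only if it lies at least ``spacing_bp``
    from every already-kept site on the same chromosome; stop at ``k``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    order = sorted(records, key=lambda r: (-r.composite, r.chrom, r.pos))
    kept: dict[str, list[int]] = {}
    selected: list[str] = []
    trace: list[str] = []
    for r in order:
        if len(selected) >= k:
            break
        positions = kept.setdefault(r.chrom, [])
        if any(abs(r.pos - p) < spacing_bp for p in positions):
            trace.append(f"skip {r.site_id} (within {spacing_bp} bp of a kept site)")
            continue
        positions.append(r.pos)
        selected.append(r.site_id)
        trace.append(f"keep {r.site_id} (composite {r.composite:.4f})")
    return LocusSelection(site_ids=selected, spacing_bp=spacing_bp, trace=trace)
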