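"""Annotation assignment and enrichment testing for top-scoring CpGs.

Each CpG receives exactly one annotation category; when tracks overlap
the most regulatory one wins (enhancer > promoter > exon > intron >
near-gene > intergenic), and 15-state chromatin segmentations are
handled the same way with states as categories. Enrichment of a
category among top-k CpGs relative to all scored CpGs is an upper-tail
binomial test (a lower tail is available for depletion). The
kinase-style gene test is the same binomial machinery applied to genes
retrieved from a window around top loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binom

from .datamodel import CpGSite
from .io import BedInterval

__all__ = [
    "DEFAULT_PRIORITY",
    "AnnotationIndex",
    "assign_category",
    "binomial_enrichment",
    "genes_near_sites",
    "enrichment_profile",
    "EnrichmentResult",
]

DEFAULT_PRIORITY = ("enhancer", "promoter", "exon", "intron", "near_gene")
FALLBACK_CATEGORY = "intergenic"


class AnnotationIndex:
    """Interval trees per category; overlaps within a category are unioned."""

    def __init__(
        self,
        tracks: dict[str, Sequence[BedInterval]],
        priority: Sequence[str] | None = None,
        fallback: str = FALLBACK_CATEGORY,
    ):
        self.priority = list(priority) if priority is not None else sorted(tracks)
        unknown = set(tracks) - set(self.priority)
        if unknown:
            raise ValueError(f"tracks {sorted(unknown)} missing from the priority order")
        self.fallback = fallback
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        for category, intervals in tracks.items():
            per_chrom: dict[str, IntervalTree] = {}
            for iv in intervals:
                per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
            for tree in per_chrom.values():
                tree.merge_overlaps()
            self.trees[category] = per_chrom

    def category_of(self, chrom: str, pos: int) -> str:
        for category in self.priority:
            per_chrom = self.trees.get(category, {})
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                return category
        return self.fallback

    @property
    def categories(self) -> list[str]:
        return self.priority + [self.fallback]


def assign_category(sites: Iterable[CpGSite], index: AnnotationIndex) -> dict[str, str]:
    """site_id -> single category under the index's priority order."""
    return {s.site_id: index.category_of(s.chrom, s.pos) for s in sites}


def binomial_enrichment(k: int, n: int, p_bg: float, depletion: bool = False) -> float:
    """Tail probability of observing ``k`` hits in ``n`` trials.

    Upper tail P(X >= k) under X ~ Binomial(n, p_bg) for enrichment
    (exact summation via the regularized incomplete beta function);
    lower tail P(X <= k) with ``depletion=True``.
    """
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not (0 < p_bg < 1):
        raise ValueError(f"background probability {p_bg} outside (0,1)")
    if depletion:
        return float(binom.cdf(k, n, p_bg))
    return float(binom.sf(k - 1, n, p_bg))


def genes_near_sites(
    sites: Iterable[CpGSite], genes: Sequence[BedInterval], window_bp: int = 5000
) -> set[str]:
    """Deduplicated names of genes intersecting the half-open window
    [pos - window_bp, pos + window_bp) around any site.

    A gene starting exactly window_bp downstream (or ending exactly at
    pos - window_bp, half-open) does not intersect and is excluded.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.name)
    found: set[str] = set()
    for s in sites:
        tree = trees.get(s.chrom)
        if tree is None:
            continue
        lo = max(0, s.pos - window_bp)
        for hit in tree.overlap(lo, s.pos + window_bp):
            found.add(hit.data)
    return found


@dataclass
class EnrichmentResult:
    category: str
    n_observed: int
    n_total: int
    p_background: float
    observed_prop: float
    expected_prop: float
    delta: float
    p_value: float


def enrichment_profile(
    top_assignments: dict[str, str],
    background_assignments: dict[str, str],
    depletion: bool = False,
) -> list[EnrichmentResult]:
    """Observed-vs-expected category proportions for a top set.

    The expected proportion of a category is its frequency among all
    scored CpGs (the background); the p-value is the binomial tail at
    that background rate. Proportions over the emitted categories sum
    to 1 for both sets.
    """
    if not top_assignments:
        raise ValueError("empty top set")
    categories = sorted(set(background_assignments.values()) | set(top_assignments.values()))
    n_top = len(top_assignments)
    n_bg = len(background_assignments)
    if n_bg == 0:
        raise ValueError("empty background")
    top_counts = {c: 0 for c in categories}
    for c in top_assignments.values():
        top_counts[c] += 1
    bg_counts = {c: 0 for c in categories}
    for c in background_assignments.values():
        bg_counts[c] += 1
    results = []
    for c in categories:
        p_bg = bg_counts[c] / n_bg
        obs = top_counts[c] / n_top
        if 0 < p_bg < 1:
            p_val = binomial_enrichment(top_counts[c], n_top, p_bg, depletion=depletion)
        else:
            p_val = 1.0
        results.append(
            EnrichmentResult(
                category=c,
                n_observed=top_counts[c],
                n_total=n_top,
                p_background=p_bg,
                observed_prop=obs,
                expected_prop=p_bg,
                delta=obs - p_bg,
                p_value=p_val,
            )
        )
    return results
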