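"""Training-set construction: significant positives and beta-matched negatives.

Positives are array CpGs at or below a stringent EWAS p threshold.
Each positive receives ``ratio`` (default 10) matched negatives chosen,
without replacement, as the candidates nearest in mean methylation
(beta) — negatives must be non-significant (p above a conservative
threshold, default 0.40) in EVERY supplied trait. The 1:10 imbalance is
deliberate: it approximates the true scarcity of trait-associated CpGs
in the genome, and evaluation keeps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SummaryStat

__all__ = ["TrainingSet", "select_positives", "match_negatives", "build_training_set"]


@dataclass
class TrainingSet:
    trait_name: str
    positives: list[str]                      # ascending EWAS p
    negatives: list[str]
    matching: dict[str, list[str]]            # positive -> its matched negatives
    p_pos: float
    p_neg: float = 0.40
    ratio: int = 10

    def __post_init__(self):
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"{len(overlap)} sites are both positive and negative")

    @property
    def site_ids(self) -> list[str]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.positives)), np.zeros(len(self.negatives))])

    def to_frame(self, beta_mean: dict[str, float] | None = None) -> pd.DataFrame:
        matched_to = {neg: pos for pos, negs in self.matching.items() for neg in negs}
        rows = [(s, 1, "", (beta_mean or {}).get(s, np.nan)) for s in self.positives]
        rows += [(s, 0, matched_to.get(s, ""), (beta_mean or {}).get(s, np.nan)) for s in self.negatives]
        return pd.DataFrame(rows, columns=["site_id", "label", "matched_to", "beta_mean"])


def _pos_of(site_id: str) -> tuple[str, int | None]:
    # "chrom:pos" ids carry coordinates; other id schemes lose only the
    # genomic-distance tie-break
    chrom, _, pos = site_id.rpartition(":")
    if chrom and pos.isdigit():
        return chrom, int(pos)
    return site_id, None


def select_positives(stats: list[SummaryStat], p_pos: float) -> list[str]:
    """All sites with p <= p_pos, sorted by ascending p (ties: site_id)."""
    if not (1e-12 <= p_pos <= 0.05):
        raise ValueError(f"p_pos {p_pos} outside the sane range [1e-12, 0.05]")
    hits = sorted(
        (s for s in stats if not np.isnan(s.p_value) and s.p_value <= p_pos),
        key=lambda s: (s.p_value, s.site_id),
    )
    if not hits:
        raise ValueError(
            f"no CpG reaches p <= {p_pos}; relax the positive threshold (the usual range is 1e-7..1e-5)"
        )
    return [s.site_id for s in hits]


def match_negatives(
    positives: list[str],
    beta_mean: dict[str, float],
    candidates: list[str],
    ratio: int = 10,
    max_beta_diff: float = 0.1,
) -> dict[str, list[str]]:
    """Greedy nearest-beta matching without replacement.

    ``positives`` must already be in ascending-p order (the strongest
    associations get first pick). For each positive the ``ratio``
    remaining candidates closest in mean beta are taken; ties break by
    smaller genomic distance, then lexicographic site_id. Exceeding
    ``max_beta_diff`` for any assigned pair, or exhausting the pool,
    raises a shortfall error naming the positive that failed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pool = sorted(set(candidates) - set(positives))
    if len(pool) < ratio * len(positives):
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than ratio x positives ({ratio * len(positives)})"
        )
    pool_beta = np.array([beta_mean[c] for c in pool])
    pool_chrom_pos = [_pos_of(c) for c in pool]
    available = np.ones(len(pool), dtype=bool)
    matching: dict[str, list[str]] = {}
    for positive in positives:
        b = beta_mean[positive]
        p_chrom, p_pos = _pos_of(positive)
        idx = np.flatnonzero(available)
        if idx.size < ratio:
            raise ValueError(f"candidate pool exhausted while matching positive {positive}")
        diff = np.abs(pool_beta[idx] - b)
        dist = np.array(
            [
                abs(pool_chrom_pos[i][1] - p_pos)
                if (p_pos is not None and pool_chrom_pos[i][0] == p_chrom and pool_chrom_pos[i][1] is not None)
                else np.inf
                for i in idx
            ]
        )
        order = sorted(range(idx.size), key=lambda j: (diff[j], dist[j], pool[idx[j]]))
        chosen = [idx[j] for j in order[:ratio]]
        worst = float(diff[[order[ratio - 1]]][0])
        if worst > max_beta_diff:
            raise ValueError(
                f"matching shortfall for positive {positive}: nearest available negative "
                f"differs by {worst:.3f} in beta (> {max_beta_diff})"
            )
        matching[positive] = [pool[i] for i in chosen]
        available[chosen] = False
    return matching


def build_training_set(
    stats_by_trait: dict[str, list[SummaryStat]],
    trait_name: str,
    p_pos: float,
    p_neg: float = 0.40,
    ratio: int = 10,
    max_beta_diff: float = 0.1,
) -> TrainingSet:
    """Assemble the training set for one trait.

    Positives come from that trait's EWAS; negative candidates must be
    non-significant (p > p_neg) in every supplied trait.
    """
    target = {s.site_id: s for s in stats_by_trait[trait_name]}
    positives = select_positives(stats_by_trait[trait_name], p_pos)
    eligible = None
    for stats in stats_by_trait.values():
        ok = {s.site_id for s in stats if not np.isnan(s.p_value) and s.p_value > p_neg}
        eligible = ok if eligible is None else (eligible & ok)
    beta_mean = {s.site_id: s.beta_mean for s in stats_by_trait[trait_name]}
    candidates = sorted(e for e in (eligible or set()) if e in beta_mean)
    matching = match_negatives(positives, beta_mean, candidates, ratio=ratio, max_beta_diff=max_beta_diff)
    negatives = [n for pos in positives for n in matching[pos]]
    return TrainingSet(
        trait_name=trait_name,
        positives=positives,
        negatives=negatives,
        matching=matching,
        p_pos=p_pos,
        p_neg=p_neg,
        ratio=ratio,
    )
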