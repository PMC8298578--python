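"""Core domain types.

The unit of analysis is the CpG dinucleotide (the C of a forward-strand
CG pair, 0-based). Association evidence per CpG and trait is carried as a
summary statistic; epigenomic context as a sites x features matrix whose
tracks are constant within 200-bp genomic bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "TraitSpec",
    "SummaryStat",
    "FeatureMatrix",
    "Metrics",
    "site_id_of",
    "f1_score_from",
]

BIN_BP = 200  # genomic bin width shared by all feature tracks


def site_id_of(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


@dataclass(frozen=True)
class CpGSite:
    """A genomic CpG locus: position of the C on the forward strand (0-based)."""

    chrom: str
    pos: int
    on_array: bool = False

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")

    @property
    def site_id(self) -> str:
        return site_id_of(self.chrom, self.pos)

    @property
    def bin_index(self) -> int:
        return self.pos // BIN_BP


@dataclass(frozen=True)
class TraitSpec:
    """A trait used as an EWAS outcome.

    kind: "continuous" or "binary" (binary values must be 0/1).
    transform: "none", "sqrt" (non-negative values only) or
    "person_specific_slope" (the slope is precomputed upstream and the
    values are used as-is).
    """

    name: str
    kind: str = "continuous"
    transform: str = "none"

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.transform not in ("none", "sqrt", "person_specific_slope"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def apply_transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "binary":
            uniq = set(np.unique(values[~np.isnan(values)]))
            if not uniq <= {0.0, 1.0}:
                raise ValueError(f"binary trait {self.name} has values outside {{0,1}}: {sorted(uniq)}")
            return values
        if self.transform == "sqrt":
            if np.nanmin(values) < 0:
                raise ValueError(f"sqrt transform of negative values in trait {self.name}")
            return np.sqrt(values)
        return values


@dataclass(frozen=True)
class SummaryStat:
    """Per-(CpG, trait) association result plus the cohort mean beta."""

    site_id: str
    trait_name: str
    effect: float
    p_value: float
    beta_mean: float

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError(f"p_value {self.p_value} outside (0,1] for {self.site_id}")
        if not np.isfinite(self.beta_mean):
            raise ValueError(f"non-finite beta_mean for {self.site_id}")


class FeatureMatrix:
    """Sites x features value grid with an explicit missing mask.

    Backed by a pandas DataFrame (index = site ids, columns = feature
    names, NaN = missing). Rows must be imputed before entering a model;
    `median_impute` computes per-feature medians on a training set so the
    same constants can be reused at genome-scoring time.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            raise ValueError("duplicated site_ids in FeatureMatrix")
        if df.columns.duplicated().any():
            raise ValueError("duplicated feature names in FeatureMatrix")
        self.df = df.astype(float)

    @property
    def site_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return self.df.isna().to_numpy()

    def subset(self, site_ids: Sequence[str]) -> "FeatureMatrix":
        missing = set(site_ids) - set(self.df.index)
        if missing:
            raise KeyError(f"{len(missing)} site_ids absent from FeatureMatrix, e.g. {sorted(missing)[:3]}")
        return FeatureMatrix(self.df.loc[list(site_ids)])

    def median_impute(self, medians: pd.Series | None = None) -> tuple["FeatureMatrix", pd.Series]:
        """Fill missing values per feature; returns (imputed, constants used)."""
        if medians is None:
            medians = self.df.median(axis=0)
            medians = medians.fillna(0.0)  # all-missing feature
        filled = self.df.fillna(medians)
        return FeatureMatrix(filled), medians

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="site_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="site_id"))

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"FeatureMatrix({self.df.shape[0]} sites x {self.df.shape[1]} features)"


def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall <= 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class Metrics:
    """Classification metrics on [0,1]; f1 is tied to precision/recall."""

    auc: float
    auprc: float
    precision: float
    recall: float
    f1: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.f1 is None:
            object.__setattr__(self, "f1", f1_score_from(self.precision, self.recall))
        for name in ("auc", "auprc", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name}={v} outside [0,1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "AUC": self.auc,
            "AUPR": self.auprc,
            "F1": self.f1,
            "Precision": self.precision,
            "Recall": self.recall,
        }


class BinnedFeatureStore:
    """Feature tracks resolved at 200-bp genomic bins.

    Every feature has exactly one value per (chrom, bin) key, so any CpG
    maps to a feature vector through its bin. Bins absent from the store
    are reported as uncovered and are median-imputed downstream.
    """

    def __init__(self, feature_names: Sequence[str], data: dict[tuple[str, int], np.ndarray]):
        self.feature_names = list(feature_names)
        self.data = data

    def vector_for(self, chrom: str, pos: int) -> np.ndarray | None:
        return self.data.get((chrom, pos // BIN_BP))

    def matrix_for_sites(self, sites: Sequence["CpGSite"]) -> tuple[FeatureMatrix, int]:
        """Per-site matrix (NaN rows for uncovered bins) and the uncovered count."""
        n_missing = 0
        rows = np.empty((len(sites), len(self.feature_names)))
        for i, s in enumerate(sites):
            vec = self.vector_for(s.chrom, s.pos)
            if vec is None:
                rows[i] = np.nan
                n_missing += 1
            else:
                rows[i] = vec
        df = pd.DataFrame(rows, index=[s.site_id for s in sites], columns=self.feature_names)
        return FeatureMatrix(df), n_missing

    def to_tsv(self, path) -> None:
        keys = sorted(self.data)
        df = pd.DataFrame([self.data[k] for k in keys], columns=self.feature_names)
        df.insert(0, "bin", [k[1] for k in keys])
        df.insert(0, "chrom", [k[0] for k in keys])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "BinnedFeatureStore":
        df = pd.read_csv(path, sep="\t")
        names = [c for c in df.columns if c not in ("chrom", "bin")]
        data = {
            (str(r["chrom"]), int(r["bin"])): r[names].to_numpy(dtype=float)
            for _, r in df.iterrows()
        }
        return cls(names, data)


@dataclass
class PredictionRecord:
    """Genome-wide prediction for one CpG across traits.

    Per-trait maps share the same keys (trait names): a classifier score
    in [0,1], the rank of that score among all scored CpGs (1 = highest),
    the log-scale rank score LRS = -log10(rank/total), and the empirical
    p-value rank/total. ``composite`` combines the per-trait LRS values
    (sum by default) for joint prioritisation.
    """

    site_id: str
    chrom: str
    pos: int
    score: dict[str, float] = field(default_factory=dict)
    rank: dict[str, int] = field(default_factory=dict)
    lrs: dict[str, float] = field(default_factory=dict)
    empirical_p: dict[str, float] = field(default_factory=dict)
    composite: float = float("nan")


def validate_sites_against_genome(sites: Iterable[CpGSite], genome) -> None:
    """Check that each site is a CG dinucleotide in ``genome``.

    ``genome`` is any mapping of chrom -> sliceable sequence (e.g. a
    pyfaidx.Fasta). Raises ValueError on the first violation.
    """
    for s in sites:
        dinuc = str(genome[s.chrom][s.pos : s.pos + 2]).upper()
        if dinuc != "CG":
            raise ValueError(f"{s.site_id}: expected CG, found {dinuc!r}")
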