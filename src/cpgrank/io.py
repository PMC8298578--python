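"""Readers and writers for the formats the pipeline touches.

Coordinate convention is global: 0-based half-open everywhere in memory,
BED native on disk. Inputs printed 1-based (as association tables often
are) must be converted at the boundary with ``one_based=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import CpGSite, PredictionRecord, SummaryStat

log = logging.getLogger(__name__)

__all__ = [
    "BedInterval",
    "read_bed",
    "read_cpg_bed",
    "write_cpg_bed",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_summary_stats",
    "read_summary_stats",
    "write_fasta",
]


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length interval {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")


def read_bed(path, one_based: bool = False) -> list[BedInterval]:
    """Parse a 3+ column BED file into intervals.

    ``one_based=True`` accepts the 1-based fully-closed dialect used by
    printed position tables and converts to 0-based half-open
    (start-1, end).
    """
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            name = fields[3] if len(fields) > 3 else "."
            try:
                intervals.append(BedInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def read_cpg_bed(path, one_based: bool = False, on_array: bool = False) -> list[CpGSite]:
    """Read CpG sites from BED; each row must span exactly the CG dinucleotide."""
    sites = []
    for iv in read_bed(path, one_based=one_based):
        if iv.end - iv.start != 2:
            raise ValueError(f"CpG interval {iv.chrom}:{iv.start}-{iv.end} does not span 2 bp")
        sites.append(CpGSite(iv.chrom, iv.start, on_array=on_array))
    return sites


def write_cpg_bed(sites: Iterable[CpGSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 2}\t{s.site_id}\t{int(s.on_array)}\n")


def _trait_names(records: Sequence[PredictionRecord]) -> list[str]:
    names: list[str] = []
    for r in records:
        for t in r.score:
            if t not in names:
                names.append(t)
    return names


def write_scores_tsv(records: Sequence[PredictionRecord], path, allow_empty: bool = False) -> None:
    """Write prediction records as TSV (one row per CpG, 6-decimal floats)."""
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty scores file (pass allow_empty=True to override)")
    traits = _trait_names(records)
    cols = ["site_id", "chrom", "pos"]
    for t in traits:
        cols += [f"score_{t}", f"rank_{t}", f"lrs_{t}", f"empirical_p_{t}"]
    cols.append("composite")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.site_id, r.chrom, str(r.pos)]
            for t in traits:
                row += [
                    f"{r.score[t]:.6f}",
                    str(r.rank.get(t, "")),
                    f"{r.lrs[t]:.6f}" if t in r.lrs else "",
                    f"{r.empirical_p[t]:.6g}" if t in r.empirical_p else "",
                ]
            row.append(f"{r.composite:.6f}")
            fh.write("\t".join(row) + "\n")


def read_scores_tsv(path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t")
    traits = [c[len("score_"):] for c in df.columns if c.startswith("score_")]
    records = []
    for _, row in df.iterrows():
        rec = PredictionRecord(site_id=row["site_id"], chrom=str(row["chrom"]), pos=int(row["pos"]))
        for t in traits:
            rec.score[t] = float(row[f"score_{t}"])
            if f"rank_{t}" in df.columns and pd.notna(row[f"rank_{t}"]):
                rec.rank[t] = int(row[f"rank_{t}"])
            if f"lrs_{t}" in df.columns and pd.notna(row[f"lrs_{t}"]):
                rec.lrs[t] = float(row[f"lrs_{t}"])
            if f"empirical_p_{t}" in df.columns and pd.notna(row[f"empirical_p_{t}"]):
                rec.empirical_p[t] = float(row[f"empirical_p_{t}"])
        rec.composite = float(row["composite"])
        records.append(rec)
    return records


def write_summary_stats(stats: Iterable[SummaryStat], path) -> None:
    df = pd.DataFrame(
        [(s.site_id, s.trait_name, s.effect, s.p_value, s.beta_mean) for s in stats],
        columns=["site_id", "trait_name", "effect", "p_value", "beta_mean"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_summary_stats(path) -> list[SummaryStat]:
    df = pd.read_csv(path, sep="\t")
    return [
        SummaryStat(r.site_id, r.trait_name, float(r.effect), float(r.p_value), float(r.beta_mean))
        for r in df.itertuples(index=False)
    ]


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    """Write chromosome sequences as FASTA (fixed line width, stable order)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
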