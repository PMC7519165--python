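"""Genomic interval arithmetic and methylation-probe collapsing.

All coordinates are 0-based half-open (BED convention). CpG probes are
represented as 1-bp intervals at the CpG position. Promoters are the 2 kb
immediately upstream of the transcription start site; gene bodies run from
TSS to TES.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROMOTER_SIZE = 2000

__all__ = [
    "GenomicInterval",
    "GenomeAnnotation",
    "overlaps",
    "promoter_interval",
    "gene_body_interval",
    "collapse_probes",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_eqtl_table",
    "read_hic_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Container for a genome's regulatory entities.

    genes: DataFrame(gene_id, chrom, start, end, strand, name)
    probes: DataFrame(probe_id, chrom, pos) — CpG positions, 1 bp each
    peaks: DataFrame(peak_id, chrom, start, end)
    eqtl_pairs: DataFrame(snp_id, chrom, pos, gene_id)
    hic_contacts: DataFrame(chromA, startA, endA, chromB, startB, endB, fdr)
    """

    genes: pd.DataFrame
    probes: pd.DataFrame = field(default_factory=pd.DataFrame)
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    eqtl_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    hic_contacts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.genes) and self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene_ids: {sorted(set(dup))}")
        if len(self.hic_contacts):
            fdr = self.hic_contacts["fdr"].to_numpy(float)
            if np.any((fdr < 0) | (fdr > 1)):
                raise ValueError("Hi-C contact fdr values must lie in [0, 1]")

    def gene_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.gene_id)
            for r in self.genes.itertuples()
        ]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: true iff the intervals share >=1 base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def promoter_interval(gene: GenomicInterval, size: int = PROMOTER_SIZE) -> GenomicInterval:
    """Promoter of a stranded gene: ``size`` bp upstream of the TSS.

    For a + strand gene the TSS is ``start`` and the promoter is
    [TSS-size, TSS); for a - strand gene the TSS is ``end`` and the promoter
    is [TSS, TSS+size). Clamped at coordinate 0.
    """
    if gene.strand == "+":
        tss = gene.start
        if tss == 0:
            raise ValueError(f"gene {gene.id!r} has TSS at 0; promoter is empty")
        return GenomicInterval(gene.chrom, max(0, tss - size), tss,
                               gene.strand, gene.id)
    if gene.strand == "-":
        tss = gene.end
        return GenomicInterval(gene.chrom, tss, tss + size, gene.strand, gene.id)
    raise ValueError(f"promoter undefined for unstranded gene {gene.id!r}")


def gene_body_interval(gene: GenomicInterval) -> GenomicInterval:
    """Gene body = [start, end) (TSS to TES) regardless of strand."""
    return GenomicInterval(gene.chrom, gene.start, gene.end, gene.strand, gene.id)


def tss_position(gene: GenomicInterval) -> int:
    if gene.strand == "+":
        return gene.start
    if gene.strand == "-":
        return gene.end
    raise ValueError(f"TSS undefined for unstranded gene {gene.id!r}")


def _probe_interval(chrom: str, pos: int, probe_id: str) -> GenomicInterval:
    return GenomicInterval(chrom, pos, pos + 1, ".", probe_id)


def collapse_probes(
    beta: pd.DataFrame,
    probes: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    min_probes: int = 2,
) -> pd.DataFrame:
    """Average probe-level methylation betas over genomic regions.

    Parameters
    ----------
    beta : probes x samples DataFrame of methylation beta values, indexed by
        probe_id.
    probes : DataFrame(probe_id, chrom, pos) giving each probe's CpG position
        (treated as a 1-bp interval).
    regions : target intervals (promoters or gene bodies) with unique ids.
    min_probes : regions covered by fewer probes are dropped (default 2, so
        single-probe promoters/bodies never yield a collapsed value).

    Returns a regions x samples DataFrame (region id index). A probe may
    fall in several regions and then contributes to each. Missing betas are
    skipped in the mean; a region whose probes are all missing for a sample
    propagates NaN for that sample.
    """
    probe_pos = probes.set_index("probe_id")
    missing = beta.index.difference(probe_pos.index)
    if len(missing):
        raise ValueError(f"probes without coordinates: {sorted(missing)[:5]}")

    chroms = probe_pos.loc[beta.index, "chrom"].to_numpy()
    pos = probe_pos.loc[beta.index, "pos"].to_numpy(int)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    n_nan_flagged = 0
    for region in regions:
        member = (chroms == region.chrom) & (pos >= region.start) & (pos < region.end)
        if member.sum() < min_probes:
            continue
        vals = beta.loc[beta.index[member]].to_numpy(float)
        if np.isnan(vals).any():
            n_nan_flagged += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            rows.append(np.nanmean(vals, axis=0))
        ids.append(region.id)
    if n_nan_flagged:
        warnings.warn(
            f"{n_nan_flagged} regions contained missing probe values; "
            "means taken over non-missing probes",
            stacklevel=2,
        )
    out = pd.DataFrame(rows, index=pd.Index(ids, name="region_id"),
                       columns=beta.columns)
    return out


# ---------------------------------------------------------------------------
# Plain-text I/O (BED6 and TSV tables)

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 (or BED3/4) file into a DataFrame with BED6 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    for col in _BED_COLS[df.shape[1]:]:
        df[col] = "." if col in ("name", "strand") else 0
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write BED6; round-trips bit-exactly through :func:`read_bed`."""
    df[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene_id": str, "chrom": str, "strand": str,
                              "name": str, "start": int, "end": int})


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand", "name"]].to_csv(
        path, sep="\t", index=False)


def read_eqtl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"snp_id": str, "chrom": str, "gene_id": str,
                              "pos": int})


def read_hic_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def intervals_from_frame(df: pd.DataFrame, id_col: str,
                         strand_col: str | None = None) -> list[GenomicInterval]:
    """Build GenomicIntervals from a frame with chrom/start/end columns."""
    strands = df[strand_col] if strand_col else ["."] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), st, str(i))
        for c, s, e, st, i in zip(df["chrom"], df["start"], df["end"],
                                  strands, df[id_col])
    ]
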