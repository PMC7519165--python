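"""Linking H3K27ac peaks to cognate genes and expression-epigenome coupling.

A peak overlapping a gene promoter (2 kb upstream of the TSS) is assigned
to that gene directly.  Distal peaks are linked through two kinds of
functional evidence: an eSNP for the gene falling inside the peak, or a
significant chromatin contact (FDR < 1%) joining the peak to the gene's
promoter.  All evidence-supported links are kept even when sources
disagree; distal links are restricted to 1 Mb of the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import (
    GenomeAnnotation,
    GenomicInterval,
    intervals_from_frame,
    overlaps,
    promoter_interval,
    tss_position,
)

__all__ = [
    "link_peaks_to_genes",
    "baseline_window_pairs",
    "correlate_diff_signals",
    "quadrant_calls",
    "heritability_annotation_intervals",
    "write_heritability_annotations",
]

log = logging.getLogger(__name__)

HIC_FDR_MAX = 0.01
DISTAL_WINDOW = 1_000_000


def _peak_list(peaks: pd.DataFrame) -> list[GenomicInterval]:
    return intervals_from_frame(peaks, "peak_id")


def link_peaks_to_genes(
    peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
    hic_sources: dict[str, pd.DataFrame] | None = None,
    hic_fdr_max: float = HIC_FDR_MAX,
    window: int = DISTAL_WINDOW,
) -> pd.DataFrame:
    """Assign peaks to cognate genes by promoter, eQTL and Hi-C evidence.

    peaks: DataFrame(peak_id, chrom, start, end).
    hic_sources: mapping evidence label (e.g. "hic_bulk") -> contact table
        (chromA,startA,endA,chromB,startB,endB,fdr); defaults to the
        annotation's contacts under label "hic_bulk".

    Returns DataFrame(peak_id, gene_id, evidence, distance) with distance
    measured from the peak midpoint to the TSS.  Promoter-overlapping peaks
    link to their proximal gene(s) only; other peaks take the union of
    eQTL and contact-based links within ``window`` of the TSS.
    """
    genes = annotation.gene_intervals()
    promoters = {g.id: promoter_interval(g) for g in genes}
    tss = {g.id: tss_position(g) for g in genes}
    peak_iv = _peak_list(peaks)
    if hic_sources is None:
        hic_sources = ({"hic_bulk": annotation.hic_contacts}
                       if len(annotation.hic_contacts) else {})

    records = []
    promoter_peaks = set()
    for pk in peak_iv:
        for gid, prom in promoters.items():
            if overlaps(pk, prom):
                promoter_peaks.add(pk.id)
                records.append((pk.id, gid, "promoter",
                                abs(pk.midpoint - tss[gid])))

    distal = [pk for pk in peak_iv if pk.id not in promoter_peaks]

    # eQTL evidence: eSNP inside the peak links the peak to the SNP's gene
    eqtl = annotation.eqtl_pairs
    if len(eqtl):
        known = set(annotation.genes["gene_id"])
        bad = set(eqtl["gene_id"]) - known
        if bad:
            raise ValueError(f"eQTL rows name unknown genes: {sorted(bad)[:5]}")
        for pk in distal:
            hit = eqtl[(eqtl["chrom"] == pk.chrom)
                       & (eqtl["pos"] >= pk.start) & (eqtl["pos"] < pk.end)]
            for gid in pd.unique(hit["gene_id"]):
                dist = abs(pk.midpoint - tss[gid])
                if dist <= window:
                    records.append((pk.id, gid, "eqtl", dist))

    # Hi-C evidence: peak on one anchor, gene promoter on the other
    n_orphan = 0
    for label, contacts in (hic_sources or {}).items():
        sig = contacts[contacts["fdr"] < hic_fdr_max]
        for row in sig.itertuples():
            a = GenomicInterval(row.chromA, int(row.startA), int(row.endA))
            b = GenomicInterval(row.chromB, int(row.startB), int(row.endB))
            for anchor_pk, anchor_pr in ((a, b), (b, a)):
                hit_genes = [gid for gid, prom in promoters.items()
                             if overlaps(anchor_pr, prom)]
                if not hit_genes:
                    n_orphan += 1
                    continue
                for pk in distal:
                    if overlaps(pk, anchor_pk):
                        for gid in hit_genes:
                            dist = abs(pk.midpoint - tss[gid])
                            if dist <= window:
                                records.append((pk.id, gid, label, dist))
    if n_orphan:
        log.info("%d contact anchors overlapped no promoter", n_orphan)
    out = pd.DataFrame(records,
                       columns=["peak_id", "gene_id", "evidence", "distance"])
    return out.drop_duplicates(ignore_index=True).sort_values(
        ["peak_id", "gene_id", "evidence"], ignore_index=True)


def baseline_window_pairs(peaks: pd.DataFrame, genes: pd.DataFrame,
                          window: float = DISTAL_WINDOW) -> pd.DataFrame:
    """All (peak, gene) pairs with |peak midpoint - TSS| <= window.

    The naive position-independent baseline for acetylation-expression
    coupling: no functional evidence, distance only.
    """
    gene_iv = intervals_from_frame(genes, "gene_id", strand_col="strand")
    rows = []
    for pk in _peak_list(peaks):
        for g in gene_iv:
            if g.chrom != pk.chrom:
                continue
            dist = abs(pk.midpoint - tss_position(g))
            if dist <= window:
                rows.append((pk.id, g.id, dist))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def correlate_diff_signals(diff_acetyl: pd.DataFrame, diff_expr: pd.DataFrame,
                           links: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of differential acetylation vs expression effects.

    links must carry peak_id and gene_id; the effect estimates come from
    the two DiffTables.  Returns (R, p, pair table with signed estimates);
    the p-value is the linear-model slope test of expr-effect on
    acetyl-effect (identical to the correlation test).
    """
    pairs = links[["peak_id", "gene_id"]].drop_duplicates()
    pairs = pairs[pairs["peak_id"].isin(diff_acetyl.index)
                  & pairs["gene_id"].isin(diff_expr.index)].copy()
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 linked pairs with statistics, got {len(pairs)}")
    pairs["acetyl_effect"] = diff_acetyl.loc[pairs["peak_id"], "estimate"].to_numpy()
    pairs["expr_effect"] = diff_expr.loc[pairs["gene_id"], "estimate"].to_numpy()
    r, p = stats.pearsonr(pairs["acetyl_effect"], pairs["expr_effect"])
    return float(r), float(p), pairs.reset_index(drop=True)


def quadrant_calls(pairs: pd.DataFrame) -> pd.DataFrame:
    """Contributory vs compensatory classification of linked pairs.

    A pair is contributory when acetylation and expression change in the
    same direction and compensatory when they oppose.  Pairs with a zero
    estimate are skipped (counted in the "skipped" attribute).
    """
    nz = (pairs["acetyl_effect"] != 0) & (pairs["expr_effect"] != 0)
    skipped = int((~nz).sum())
    sub = pairs[nz].copy()
    sa = np.sign(sub["acetyl_effect"].to_numpy())
    se = np.sign(sub["expr_effect"].to_numpy())
    sub["quadrant"] = [
        f"{'up' if a > 0 else 'down'}/{'up' if e > 0 else 'down'}"
        for a, e in zip(sa, se)
    ]
    sub["call"] = np.where(sa == se, "contributory", "compensatory")
    out = sub.reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


GENE_FLANK = 10_000
PEAK_FLANK = 1_000


def heritability_annotation_intervals(regions: pd.DataFrame,
                                      mode: str) -> pd.DataFrame:
    """Expand regions into heritability-partition annotation intervals.

    mode "gene": gene body +-10 kb; mode "peak": peak +-1 kb.  Intervals
    are clamped at 0, sorted, and overlapping/adjacent intervals merged.
    Returns a BED-like frame (chrom, start, end).
    """
    flank = {"gene": GENE_FLANK, "peak": PEAK_FLANK}.get(mode)
    if flank is None:
        raise ValueError("mode must be 'gene' or 'peak'")
    df = regions[["chrom", "start", "end"]].copy()
    df["start"] = np.maximum(0, df["start"].to_numpy(int) - flank)
    df["end"] = df["end"].to_numpy(int) + flank
    df = df.sort_values(["chrom", "start", "end"], ignore_index=True)
    merged: list[list] = []
    for row in df.itertuples(index=False):
        if merged and merged[-1][0] == row.chrom and row.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], row.end)
        else:
            merged.append([row.chrom, row.start, row.end])
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def write_heritability_annotations(regions: pd.DataFrame, mode: str, path) -> pd.DataFrame:
    """Expand, merge and write annotation intervals as BED3."""
    out = heritability_annotation_intervals(regions, mode)
    out.to_csv(path, sep="\t", header=False, index=False)
    return out
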