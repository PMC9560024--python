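"""Post-processing of CLR selection-scan tracks into sweep regions and genes.

The filtering rules: positions with CLR at or above the empirical top-q
quantile (q = 1% by default) are candidate sites; candidate regions
closer than 1000 bp (strictly) are connected into one sweep region;
population-specific sweeps are the three-way intersection of the merged
regions of two within-species matchups and an outgroup-polarized scan;
genes overlapping a final region by at least 1 bp are reported.

CLR grid positions are 1-based single-base test sites (SweepFinder2
convention) and are converted to 0-based half-open intervals internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GenomicInterval

logger = logging.getLogger("glacierpace")


@dataclass(frozen=True)
class CLRTrack:
    """Per-position composite-likelihood-ratio scores on one chromosome."""

    chrom: str
    positions: np.ndarray  # 1-based, strictly ascending
    clr: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        clr = np.asarray(self.clr, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "clr", clr)
        if pos.shape != clr.shape or pos.ndim != 1 or pos.size == 0:
            raise ValueError("positions and clr must be equal-length non-empty 1-D arrays")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly ascending")
        if np.any(clr < 0):
            raise ValueError("CLR scores must be >= 0")


def read_clr_track(path: str | Path, chrom: str = "chr1") -> CLRTrack:
    """Read a SweepFinder2-style track TSV with columns ``location`` and
    ``LR`` (extra columns such as ``alpha`` are ignored)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "location" not in cols or "lr" not in cols:
        raise ValueError("track file must have 'location' and 'LR' columns")
    return CLRTrack(
        chrom=chrom,
        positions=df[cols["location"]].astype(float).round().astype(int).to_numpy(),
        clr=df[cols["lr"]].astype(float).to_numpy(),
    )


def write_clr_track(track: CLRTrack, path: str | Path) -> None:
    pd.DataFrame({"location": track.positions, "LR": track.clr}).to_csv(
        path, sep="\t", index=False
    )


def top_quantile_regions(track: CLRTrack, q: float = 0.01) -> list[GenomicInterval]:
    """Intervals covering grid positions with CLR in the top-q tail.

    The threshold is the empirical (1-q) quantile (linear interpolation);
    ties at the threshold are included.  Each selected 1-based position p
    becomes [p-1, p); runs of base-consecutive selected positions
    collapse into one interval.
    """
    if not (0.0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    threshold = float(np.quantile(track.clr, 1.0 - q))
    selected = track.positions[track.clr >= threshold]
    if selected.size == 0:
        return []
    intervals: list[GenomicInterval] = []
    run_start = prev = int(selected[0])
    for p in selected[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
            continue
        intervals.append(GenomicInterval(track.chrom, run_start - 1, prev))
        run_start = prev = p
    intervals.append(GenomicInterval(track.chrom, run_start - 1, prev))
    return intervals


def merge_regions(intervals: list[GenomicInterval], gap: int = 1000) -> list[GenomicInterval]:
    """Connect intervals whose separation (start2 - end1) is strictly < gap.

    Output is sorted and disjoint.  Idempotent for gap >= 0.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        out: list[GenomicInterval] = []
        for chrom in sorted(chroms):
            out.extend(merge_regions([iv for iv in intervals if iv.chrom == chrom], gap))
        return out
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start - last.end < gap:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def intersect_region_sets(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise interval intersections, per chromosome, sorted."""
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted({iv.chrom for iv in a} & set(by_chrom_b)):
        xs = sorted((iv for iv in a if iv.chrom == chrom), key=lambda iv: iv.start)
        ys = sorted(by_chrom_b[chrom], key=lambda iv: iv.start)
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return out


def genes_in_regions(
    regions: list[GenomicInterval],
    annotations: list[GeneAnnotation],
    contained: bool = False,
) -> list[str]:
    """Sorted unique ids of genes overlapping any region by >= 1 bp
    (or fully contained in a region when ``contained`` is set)."""
    hits: set[str] = set()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for gene in annotations:
        for iv in by_chrom.get(gene.chrom, ()):
            if contained:
                ok = iv.start <= gene.start and gene.end <= iv.end
            else:
                ok = gene.start < iv.end and iv.start < gene.end
            if ok:
                hits.add(gene.gene_id)
                break
    return sorted(hits)


def population_sweep_genes(
    matchup1: CLRTrack,
    matchup2: CLRTrack,
    polarized: CLRTrack,
    annotations: list[GeneAnnotation],
    q: float = 0.01,
    gap: int = 1000,
) -> tuple[list[str], dict[str, list[GenomicInterval]]]:
    """Population-specific sweep genes from two matchups plus a polarized scan.

    Each track is thresholded at its own top-q quantile and merged; the
    final sweep regions are the three-way intersection of the merged
    region sets, and the gene set is everything overlapping them.  The
    returned table carries the intermediate and final interval sets.
    """
    merged = {
        "matchup1": merge_regions(top_quantile_regions(matchup1, q), gap),
        "matchup2": merge_regions(top_quantile_regions(matchup2, q), gap),
        "polarized": merge_regions(top_quantile_regions(polarized, q), gap),
    }
    common = intersect_region_sets(merged["matchup1"], merged["matchup2"])
    final = intersect_region_sets(common, merged["polarized"])
    table = dict(merged, common_matchups=common, final=final)
    genes = genes_in_regions(final, annotations)
    logger.info("population_sweep_genes: %d final regions, %d genes",
                len(final), len(genes))
    return genes, table
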