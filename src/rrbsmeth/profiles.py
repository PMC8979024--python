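"""Metagene/TE methylation profiles and per-region summaries.

A metagene profile averages methylation over a set of features in a common
coordinate system: a fixed number of fixed-width windows across each 2-kb
flank plus a fixed number of windows across the length-scaled body, ordered
5'->3' in the feature's own orientation (for minus-strand features the
genomic coordinates of successive bins descend).  Bin levels are
read-weighted by default: the level of a bin is sum(n_meth)/sum(n_total)
over every site of the given context falling in that bin across all
features of the kind, so deeply covered sites count proportionally more.

Region summaries apply the same read-weighted aggregation to named genic
regions: gene body, 2-kb flanks, exon, intron, CDS and UTRs.  Introns are
derived as the body minus the union of annotated exons.  A site may
contribute to several overlapping region classes (body and exon, say);
within one class it is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CONTEXTS, GenomicFeature

log = logging.getLogger("rrbsmeth")

REGION_LABELS = ("genebody", "up2k", "down2k", "exon", "intron", "CDS",
                 "5UTR", "3UTR")


@dataclass(frozen=True)
class Bin:
    region: str   # "up2k", "body" or "down2k"
    index: int    # 0-based within the whole profile, 5'->3'
    start: int    # genomic, 0-based half-open; start == end for clipped bins
    end: int


def bin_feature(feature: GenomicFeature, flank_bp: int = 2000,
                flank_bins: int = 20, body_bins: int = 40,
                contig_length: int | None = None) -> list[Bin]:
    """Ordered genomic bin intervals for one feature, 5'->3'.

    Flank bins have fixed width ``flank_bp / flank_bins``; body bins split
    the body into ``body_bins`` near-equal parts with the remainder given to
    the 5'-most bins.  Bins truncated by contig boundaries are clipped and
    may be empty (start == end).
    """
    edges = [round(i * flank_bp / flank_bins) for i in range(flank_bins + 1)]
    length = feature.length
    base, rem = divmod(length, body_bins)
    sizes = [base + 1 if i < rem else base for i in range(body_bins)]
    cum = np.concatenate([[0], np.cumsum(sizes)])

    def clipped(s: int, e: int) -> tuple[int, int]:
        lo = max(0, s)
        hi = e if contig_length is None else min(contig_length, e)
        if hi > lo:
            return lo, hi
        edge = max(0, hi)  # fully clipped bin collapses onto the boundary
        return edge, edge

    bins: list[Bin] = []
    idx = 0
    if feature.strand == "+":
        origin = feature.start - flank_bp
        for i in range(flank_bins):
            s, e = clipped(origin + edges[i], origin + edges[i + 1])
            bins.append(Bin("up2k", idx, s, e)); idx += 1
        for i in range(body_bins):
            bins.append(Bin("body", idx, feature.start + int(cum[i]),
                            feature.start + int(cum[i + 1]))); idx += 1
        for i in range(flank_bins):
            s, e = clipped(feature.end + edges[i], feature.end + edges[i + 1])
            bins.append(Bin("down2k", idx, s, e)); idx += 1
    else:
        origin = feature.end + flank_bp
        for i in range(flank_bins):
            s, e = clipped(origin - edges[i + 1], origin - edges[i])
            bins.append(Bin("up2k", idx, s, e)); idx += 1
        for i in range(body_bins):
            bins.append(Bin("body", idx, feature.end - int(cum[i + 1]),
                            feature.end - int(cum[i]))); idx += 1
        for i in range(flank_bins):
            s, e = clipped(feature.start - edges[i + 1],
                           feature.start - edges[i])
            bins.append(Bin("down2k", idx, s, e)); idx += 1
    return bins


class _ChromIndex:
    """Position-sorted per-chromosome arrays for fast interval aggregation."""

    def __init__(self, calls: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray,
                                        np.ndarray]] = {}
        ctx_code = {c: i for i, c in enumerate(CONTEXTS)}
        for chrom, group in calls.groupby("chrom", sort=False, observed=True):
            g = group.sort_values("pos")
            self._by_chrom[chrom] = (
                g["pos"].to_numpy(),
                g["context"].map(ctx_code).to_numpy(),
                g["n_meth"].to_numpy(dtype=float),
                g["n_total"].to_numpy(dtype=float),
            )

    def accumulate(self, chrom: str, start: int, end: int,
                   meth_acc: np.ndarray, total_acc: np.ndarray,
                   site_acc: np.ndarray) -> None:
        """Add per-context sums over sites in [start, end) into accumulators."""
        if chrom not in self._by_chrom or end <= start:
            return
        pos, ctx, meth, total = self._by_chrom[chrom]
        i0, i1 = np.searchsorted(pos, [start, end])
        if i1 <= i0:
            return
        sl = slice(i0, i1)
        meth_acc += np.bincount(ctx[sl], weights=meth[sl], minlength=3)
        total_acc += np.bincount(ctx[sl], weights=total[sl], minlength=3)
        site_acc += np.bincount(ctx[sl], minlength=3)


def profile_features(calls: pd.DataFrame, features: list[GenomicFeature],
                     flank_bp: int = 2000, flank_bins: int = 20,
                     body_bins: int = 40,
                     contig_lengths: dict[str, int] | None = None,
                     weighting: str = "read_weighted") -> pd.DataFrame:
    """Metagene profile per feature kind.

    Returns a frame with columns kind, bin_index, region, context, level,
    n_meth, n_total, n_sites; level is NaN for bins without covered sites.
    With ``weighting="site_mean"`` levels are unweighted means of per-site
    levels instead of read-weighted ratios.
    """
    n_bins = 2 * flank_bins + body_bins
    kinds = sorted({f.kind for f in features})
    if not kinds:
        log.warning("profile_features: no features given")
    index = _ChromIndex(calls)
    site_mean = weighting == "site_mean"
    if weighting not in ("read_weighted", "site_mean"):
        raise ValueError(f"unknown weighting {weighting!r}")

    rows = []
    for kind in kinds:
        kind_features = [f for f in features if f.kind == kind]
        meth = np.zeros((n_bins, 3))
        total = np.zeros((n_bins, 3))
        sites = np.zeros((n_bins, 3))
        lvl_sum = np.zeros((n_bins, 3))
        regions = None
        for f in kind_features:
            clen = contig_lengths.get(f.chrom) if contig_lengths else None
            bins = bin_feature(f, flank_bp, flank_bins, body_bins, clen)
            if regions is None:
                regions = [b.region for b in bins]
            for b in bins:
                index.accumulate(f.chrom, b.start, b.end,
                                 meth[b.index], total[b.index], sites[b.index])
                if site_mean:
                    _accumulate_site_levels(index, f.chrom, b.start, b.end,
                                            lvl_sum[b.index])
        for j in range(n_bins):
            for c, ctx in enumerate(CONTEXTS):
                if total[j, c] > 0:
                    level = (lvl_sum[j, c] / sites[j, c] if site_mean
                             else meth[j, c] / total[j, c])
                else:
                    level = float("nan")
                rows.append((kind, j, regions[j] if regions else "", ctx,
                             level, meth[j, c], total[j, c], int(sites[j, c])))
    return pd.DataFrame(rows, columns=["kind", "bin_index", "region", "context",
                                       "level", "n_meth", "n_total", "n_sites"])


def _accumulate_site_levels(index: _ChromIndex, chrom: str, start: int,
                            end: int, acc: np.ndarray) -> None:
    if chrom not in index._by_chrom or end <= start:
        return
    pos, ctx, meth, total = index._by_chrom[chrom]
    i0, i1 = np.searchsorted(pos, [start, end])
    if i1 <= i0:
        return
    sl = slice(i0, i1)
    covered = total[sl] > 0
    levels = np.where(covered, meth[sl] / np.where(covered, total[sl], 1), 0.0)
    acc += np.bincount(ctx[sl], weights=levels, minlength=3)


def region_intervals(feature: GenomicFeature, region: str,
                     flank_bp: int = 2000) -> list[tuple[int, int]]:
    """Genomic intervals making up a named region of one feature.

    Flank regions are strand-aware; intron is the body minus the exon union.
    Regions requiring sub-features return [] when none are annotated.
    Intervals below 0 are clipped at 0.
    """
    plus = feature.strand == "+"
    if region == "genebody":
        ivs = [(feature.start, feature.end)]
    elif region == "up2k":
        ivs = ([(feature.start - flank_bp, feature.start)] if plus
               else [(feature.end, feature.end + flank_bp)])
    elif region == "down2k":
        ivs = ([(feature.end, feature.end + flank_bp)] if plus
               else [(feature.start - flank_bp, feature.start)])
    elif region in ("exon", "CDS", "5UTR", "3UTR"):
        ivs = feature.sub(region)
    elif region == "intron":
        exons = sorted(feature.sub("exon"))
        if not exons:
            return []
        ivs = []
        cursor = feature.start
        for s, e in exons:
            if s > cursor:
                ivs.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < feature.end:
            ivs.append((cursor, feature.end))
    else:
        raise ValueError(f"unknown region {region!r}")
    return [(max(0, s), e) for s, e in ivs if e > max(0, s)]


def region_summaries(calls: pd.DataFrame, features: list[GenomicFeature],
                     flank_bp: int = 2000,
                     regions: tuple[str, ...] = REGION_LABELS) -> pd.DataFrame:
    """Read-weighted methylation level per (region, context) over features.

    Columns: region, context, level, n_sites, n_reads.  Sub-feature regions
    (exon/intron/CDS/UTRs) draw only on features that annotate them.
    """
    index = _ChromIndex(calls)
    rows = []
    for region in regions:
        meth = np.zeros(3)
        total = np.zeros(3)
        sites = np.zeros(3)
        for f in features:
            for s, e in region_intervals(f, region, flank_bp):
                index.accumulate(f.chrom, s, e, meth, total, sites)
        for c, ctx in enumerate(CONTEXTS):
            level = meth[c] / total[c] if total[c] > 0 else float("nan")
            rows.append((region, ctx, level, int(sites[c]), total[c]))
    return pd.DataFrame(rows, columns=["region", "context", "level",
                                       "n_sites", "n_reads"])


def feature_region_levels(calls: pd.DataFrame, features: list[GenomicFeature],
                          regions: tuple[str, ...] = ("up2k", "genebody",
                                                      "down2k"),
                          flank_bp: int = 2000) -> pd.DataFrame:
    """Per-feature, per-region, per-context read-weighted levels.

    The per-gene building block of methylome-expression integration.
    Columns: feature_id, region, context, level, n_meth, n_total, n_sites.
    """
    index = _ChromIndex(calls)
    rows = []
    for f in features:
        for region in regions:
            meth = np.zeros(3)
            total = np.zeros(3)
            sites = np.zeros(3)
            for s, e in region_intervals(f, region, flank_bp):
                index.accumulate(f.chrom, s, e, meth, total, sites)
            for c, ctx in enumerate(CONTEXTS):
                level = meth[c] / total[c] if total[c] > 0 else float("nan")
                rows.append((f.id, region, ctx, level, meth[c], total[c],
                             int(sites[c])))
    return pd.DataFrame(rows, columns=["feature_id", "region", "context",
                                       "level", "n_meth", "n_total", "n_sites"])
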