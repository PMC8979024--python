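"""Six-criterion differentially methylated region (DMR) caller.

Candidate regions are maximal runs of seed sites — cytosines of one context
called methylated in at least one of the two samples — in which every gap
between adjacent seeds is under 200 bp.  A candidate becomes a DMR when it
passes, per context:

1. more than five methylated cytosines in at least one sample;
2. more than 10 reads covering every member cytosine in both samples, and
   more than four methylated reads for a site to qualify as a methylated
   cytosine (the >4-read bound is part of the definition of a methylated
   cytosine counted by criterion 1, not a veto on the region: a weakly
   methylated member simply does not count);
3. a span between 40 bp and 10 kb (inclusive);
4. the under-200-bp adjacency used for seeding;
5. a fold change of the two read-weighted mean levels above 2;
6. a Pearson chi-square p-value (1 df, pooled 2x2 read counts, no continuity
   correction) at or below 0.05.

The "more than" bounds are read literally as strict inequalities; all are
config keys.  No correction across regions is applied.  Direction is relative
to sample A (control): a region is "hyper" when the treated sample B is the
higher one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULTS, log_filter
from .formats import CONTEXTS, GenomicFeature

log = logging.getLogger("rrbsmeth")


@dataclass
class CandidateRegion:
    """A run of seed sites with both samples' counts at each member."""

    chrom: str
    start: int
    end: int            # last seed position + 1
    context: str
    pos: np.ndarray     # member positions, sorted
    meth_a: np.ndarray
    total_a: np.ndarray
    meth_b: np.ndarray
    total_b: np.ndarray
    ismeth_a: np.ndarray
    ismeth_b: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    mean_level_a: float
    mean_level_b: float
    fold_change: float
    chi2: float
    p_value: float
    direction: str  # "hyper"/"hypo" of treated (B) vs control (A)
    linked_features: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_context(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                   context: str) -> pd.DataFrame:
    """Outer-join the two samples' calls of one context on site identity.

    Sites absent from a sample get zero counts there (and later fail the
    coverage criterion, which is the conservative reading).
    """
    keys = ["chrom", "pos", "strand"]
    cols = keys + ["n_meth", "n_total", "is_methylated"]
    a = calls_a.loc[calls_a["context"] == context, cols]
    b = calls_b.loc[calls_b["context"] == context, cols]
    merged = a.merge(b, on=keys, how="outer", suffixes=("_a", "_b"))
    for suffix in ("a", "b"):
        for col in (f"n_meth_{suffix}", f"n_total_{suffix}"):
            merged[col] = merged[col].fillna(0).astype(int)
        merged[f"is_methylated_{suffix}"] = (
            merged[f"is_methylated_{suffix}"].fillna(False).astype(bool))
    return merged.sort_values(keys[:2], ignore_index=True)


def seed_candidate_regions(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                           context: str,
                           max_gap: int | None = None) -> list[CandidateRegion]:
    """Partition union-methylated sites into runs with adjacent gaps < max_gap."""
    if max_gap is None:
        max_gap = DEFAULTS["dmr_max_gap"]
    merged = _merge_context(calls_a, calls_b, context)
    seeds = merged[merged["is_methylated_a"] | merged["is_methylated_b"]]
    regions: list[CandidateRegion] = []
    for chrom, group in seeds.groupby("chrom", sort=True, observed=True):
        pos = group["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        group = group.iloc[order]
        pos = pos[order]
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= max_gap) + 1
        for chunk_idx in np.split(np.arange(pos.size), breaks):
            chunk = group.iloc[chunk_idx]
            cpos = pos[chunk_idx]
            regions.append(CandidateRegion(
                chrom=chrom, start=int(cpos[0]), end=int(cpos[-1]) + 1,
                context=context, pos=cpos,
                meth_a=chunk["n_meth_a"].to_numpy(),
                total_a=chunk["n_total_a"].to_numpy(),
                meth_b=chunk["n_meth_b"].to_numpy(),
                total_b=chunk["n_total_b"].to_numpy(),
                ismeth_a=chunk["is_methylated_a"].to_numpy(),
                ismeth_b=chunk["is_methylated_b"].to_numpy(),
            ))
    return regions


def apply_count_and_coverage_filters(region: CandidateRegion,
                                     min_mc: int | None = None,
                                     min_cov: int | None = None,
                                     min_meth_reads: int | None = None) -> bool:
    """Count and coverage criteria; all bounds strict (counts must exceed them).

    A member counts as a methylated cytosine in a sample when its calling
    verdict is positive there and it carries more than ``min_meth_reads``
    methylated reads; the region needs more than ``min_mc`` such cytosines in
    at least one sample.  Every member must exceed ``min_cov`` reads in both
    samples — members lacking coverage in a sample disqualify the region
    rather than being dropped (conservative, deterministic).
    """
    if min_mc is None:
        min_mc = DEFAULTS["dmr_min_mc"]
    if min_cov is None:
        min_cov = DEFAULTS["dmr_min_cov"]
    if min_meth_reads is None:
        min_meth_reads = DEFAULTS["dmr_min_meth_reads"]
    n_mc_a = int((region.ismeth_a & (region.meth_a > min_meth_reads)).sum())
    n_mc_b = int((region.ismeth_b & (region.meth_b > min_meth_reads)).sum())
    if not (n_mc_a > min_mc or n_mc_b > min_mc):
        return False
    if not ((region.total_a > min_cov).all() and (region.total_b > min_cov).all()):
        return False
    return True


def apply_length_filter(region: CandidateRegion, min_len: int | None = None,
                        max_len: int | None = None) -> bool:
    """Criterion (3): span within [min_len, max_len], bounds inclusive."""
    if min_len is None:
        min_len = DEFAULTS["dmr_min_len"]
    if max_len is None:
        max_len = DEFAULTS["dmr_max_len"]
    return min_len <= region.length <= max_len


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]].

    Degenerate tables (a zero marginal) have identical proportions by
    convention: chi2 = 0, p = 1.  A zero row sum is the caller's error.
    """
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if row1 == 0 or row2 == 0:
        raise ValueError("2x2 table has a zero row sum")
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    n = row1 + row2
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def test_region(region: CandidateRegion) -> tuple[float, float, float, str]:
    """Pooled 2x2 test of a candidate: (chi2, p, fold_change, direction).

    Counts are pooled over member sites per sample; mean levels are
    read-weighted.  fold_change is the larger mean over the smaller
    (infinite when the smaller is 0 and the larger is not; 1 when both are 0).
    Raises ValueError when a sample has no reads in the region.
    """
    a_m, a_t = int(region.meth_a.sum()), int(region.total_a.sum())
    b_m, b_t = int(region.meth_b.sum()), int(region.total_b.sum())
    if a_t == 0 or b_t == 0:
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} "
                         "has no reads in one sample")
    chi2, p = pearson_chi2_2x2(a_m, a_t - a_m, b_m, b_t - b_m)
    mean_a, mean_b = a_m / a_t, b_m / b_t
    lo, hi = min(mean_a, mean_b), max(mean_a, mean_b)
    if hi == 0:
        fold = 1.0
    elif lo == 0:
        fold = float("inf")
    else:
        fold = hi / lo
    direction = "hyper" if mean_b > mean_a else "hypo"
    return chi2, p, fold, direction


def call_dmrs(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
              contexts: tuple[str, ...] = CONTEXTS,
              config: dict | None = None) -> list[DMR]:
    """Run the full six-criterion pipeline per context.

    ``calls_a`` is the control sample, ``calls_b`` the treated one.
    Deterministic given inputs and parameters.
    """
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    dmrs: list[DMR] = []
    for context in contexts:
        candidates = seed_candidate_regions(calls_a, calls_b, context,
                                            cfg["dmr_max_gap"])
        counted = [r for r in candidates
                   if apply_count_and_coverage_filters(
                       r, cfg["dmr_min_mc"], cfg["dmr_min_cov"],
                       cfg["dmr_min_meth_reads"])]
        log_filter(f"dmr/{context}/count+coverage", len(candidates), len(counted))
        sized = [r for r in counted
                 if apply_length_filter(r, cfg["dmr_min_len"], cfg["dmr_max_len"])]
        log_filter(f"dmr/{context}/length", len(counted), len(sized))
        kept = 0
        for region in sized:
            try:
                chi2, p, fold, direction = test_region(region)
            except ValueError as exc:
                log.info("dmr/%s: region rejected: %s", context, exc)
                continue
            if fold > cfg["dmr_min_fold"] and p <= cfg["dmr_max_p"]:
                a_m, a_t = int(region.meth_a.sum()), int(region.total_a.sum())
                b_m, b_t = int(region.meth_b.sum()), int(region.total_b.sum())
                dmrs.append(DMR(
                    chrom=region.chrom, start=region.start, end=region.end,
                    context=context, n_sites=region.n_sites,
                    meth_a=a_m, unmeth_a=a_t - a_m,
                    meth_b=b_m, unmeth_b=b_t - b_m,
                    mean_level_a=a_m / a_t, mean_level_b=b_m / b_t,
                    fold_change=fold, chi2=chi2, p_value=p,
                    direction=direction))
                kept += 1
        log_filter(f"dmr/{context}/fold+chi2", len(sized), kept)
    return dmrs


def annotate_dmrs(dmrs: list[DMR], features: list[GenomicFeature],
                  flank_bp: int = 2000) -> list[DMR]:
    """Link each DMR to features it overlaps (body or strand-aware 2-kb flank).

    Any base-pair overlap links; the relation per feature is "body" when the
    DMR overlaps the body, else "up2k"/"down2k" by which flank it touches
    (body takes precedence, upstream over downstream).  A DMR may link to
    several features.  Mutates and returns ``dmrs``.
    """
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for d in dmrs:
        links: list[tuple[str, str]] = []
        for f in by_chrom.get(d.chrom, []):
            if d.start < f.end + flank_bp and d.end > f.start - flank_bp:
                if d.start < f.end and d.end > f.start:
                    relation = "body"
                else:
                    upstream_is_left = f.strand == "+"
                    dmr_is_left = d.end <= f.start
                    relation = ("up2k" if dmr_is_left == upstream_is_left
                                else "down2k")
                links.append((f.id, relation))
        d.linked_features = links
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabular view of a DMR collection (one row per DMR)."""
    rows = [{
        "chrom": d.chrom, "start": d.start, "end": d.end, "context": d.context,
        "n_sites": d.n_sites, "meth_a": d.meth_a, "unmeth_a": d.unmeth_a,
        "meth_b": d.meth_b, "unmeth_b": d.unmeth_b,
        "mean_level_a": d.mean_level_a, "mean_level_b": d.mean_level_b,
        "fold_change": d.fold_change, "chi2": d.chi2, "p_value": d.p_value,
        "direction": d.direction,
        "linked_features": ";".join(f"{fid}:{rel}"
                                    for fid, rel in d.linked_features),
    } for d in dmrs]
    columns = ["chrom", "start", "end", "context", "n_sites", "meth_a",
               "unmeth_a", "meth_b", "unmeth_b", "mean_level_a",
               "mean_level_b", "fold_change", "chi2", "p_value", "direction",
               "linked_features"]
    return pd.DataFrame(rows, columns=columns)
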