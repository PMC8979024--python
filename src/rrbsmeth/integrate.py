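"""Methylome-transcriptome integration.

The differential-expression table is an input contract (gene_id,
level_control, level_treated, log2fc, fdr); DE model fitting happens
upstream.  This module selects DEGs at a strict FDR threshold, stratifies
genes by expression, tests per-site differential methylation (DMPs),
computes Spearman rank correlations between per-gene regional methylation
change and expression change, and intersects annotated DMRs with DEGs to
produce the correlated-gene set.

A DMP (differentially methylated position) here is a cytosine covered by
more than 10 reads in both samples whose levels differ by at least 0.1 with
a two-sided Fisher exact p <= 0.05 on the 2x2 read counts — a per-site
analogue of the regional criteria; all three bounds are config keys.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import DEFAULTS, log_filter
from .formats import GenomicFeature
from .profiles import feature_region_levels, profile_features

log = logging.getLogger("rrbsmeth")

STRATA = ("high", "moderate", "low", "none")


def select_degs(table: pd.DataFrame,
                fdr_threshold: float | None = None) -> pd.DataFrame:
    """Differentially expressed genes: fdr strictly below the threshold.

    Adds a ``direction`` column: "up" for log2fc > 0, "down" for < 0, and
    "flat" for the degenerate log2fc == 0 case.  Records without an FDR are
    skipped with a warning.
    """
    if fdr_threshold is None:
        fdr_threshold = DEFAULTS["deg_fdr_threshold"]
    usable = table[table["fdr"].notna()]
    if len(usable) < len(table):
        log.warning("select_degs: skipped %d records without FDR",
                    len(table) - len(usable))
    degs = usable[usable["fdr"] < fdr_threshold].copy()
    degs["direction"] = np.select([degs["log2fc"] > 0, degs["log2fc"] < 0],
                                  ["up", "down"], default="flat")
    log_filter("select_degs", len(table), len(degs))
    return degs.reset_index(drop=True)


def stratify_by_expression(table: pd.DataFrame, condition: str = "control",
                           zero_cutoff: float | None = None
                           ) -> dict[str, list[str]]:
    """Partition genes into none/low/moderate/high expression strata.

    Genes at or below ``zero_cutoff`` form the "none" stratum; the rest are
    split into tertiles of their expression level (bottom -> low,
    top -> high).  Ties and the split itself are made deterministic by
    sorting on (level, gene_id); when the nonzero count is not divisible by
    three the lower strata take the extra genes.
    """
    if zero_cutoff is None:
        zero_cutoff = DEFAULTS["zero_expression_cutoff"]
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be control/treated, got {condition!r}")
    level_col = f"level_{condition}"
    frame = table[["gene_id", level_col]].copy()
    none_mask = frame[level_col] <= zero_cutoff
    strata = {label: [] for label in STRATA}
    strata["none"] = sorted(frame.loc[none_mask, "gene_id"].tolist())
    expressed = frame[~none_mask].sort_values([level_col, "gene_id"],
                                              kind="stable")
    genes = expressed["gene_id"].tolist()
    parts = np.array_split(np.asarray(genes, dtype=object), 3)
    strata["low"] = list(parts[0])
    strata["moderate"] = list(parts[1])
    strata["high"] = list(parts[2])
    return strata


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and its p-value.

    Undefined (NaN, NaN, with a warning) for fewer than 3 points or a
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("spearman_rho: undefined (n < 3 or zero variance)")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_exact_two_sided(meth_a, unmeth_a, meth_b, unmeth_b) -> np.ndarray:
    """Vectorized two-sided Fisher exact p-values for 2x2 count tables.

    Standard two-sided definition (as in scipy.stats.fisher_exact): the sum
    of hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.  Computed in one
    shot over arrays via the log-pmf, which keeps per-site differential
    methylation testing tractable at methylome scale.
    """
    ma = np.atleast_1d(np.asarray(meth_a, dtype=np.int64))
    ua = np.atleast_1d(np.asarray(unmeth_a, dtype=np.int64))
    mb = np.atleast_1d(np.asarray(meth_b, dtype=np.int64))
    ub = np.atleast_1d(np.asarray(unmeth_b, dtype=np.int64))
    total = ma + ua + mb + ub          # M: grand total
    row_a = ma + ua                    # N: sample-A margin
    col_m = ma + mb                    # n: methylated-read margin
    lo = np.maximum(0, col_m - (total - row_a))
    hi = np.minimum(col_m, row_a)
    width = int((hi - lo).max()) + 1 if len(ma) else 1
    # counts are small integers: a log-factorial lookup table beats gammaln
    max_n = int(total.max()) if len(ma) else 1
    lfact = special.gammaln(np.arange(max_n + 1) + 1.0)  # lfact[x] = ln(x!)

    def log_comb(n, k):
        return lfact[n] - lfact[k] - lfact[n - k]

    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    k_safe = np.where(valid, k, lo[:, None])
    logpmf = (log_comb(row_a[:, None], k_safe)
              + log_comb((total - row_a)[:, None], col_m[:, None] - k_safe)
              - log_comb(total, col_m)[:, None])
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    obs = pmf[np.arange(len(ma)), (ma - lo)]
    # the 1 + 1e-7 relative slack absorbs floating-point ties, as scipy does
    p = np.where(pmf <= obs[:, None] * (1 + 1e-7), pmf, 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def find_dmps(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
              min_cov: int | None = None, min_delta: float | None = None,
              alpha: float | None = None) -> pd.DataFrame:
    """Per-site differential methylation between two samples.

    Columns: chrom, pos, strand, context, level_a, level_b, delta, p_value.
    """
    if min_cov is None:
        min_cov = DEFAULTS["dmp_min_cov"]
    if min_delta is None:
        min_delta = DEFAULTS["dmp_min_delta"]
    if alpha is None:
        alpha = DEFAULTS["dmp_max_p"]
    keys = ["chrom", "pos", "strand", "context"]
    cols = keys + ["n_meth", "n_total"]
    merged = calls_a[cols].merge(calls_b[cols], on=keys, suffixes=("_a", "_b"))
    covered = merged[(merged["n_total_a"] > min_cov)
                     & (merged["n_total_b"] > min_cov)].copy()
    covered["level_a"] = covered["n_meth_a"] / covered["n_total_a"]
    covered["level_b"] = covered["n_meth_b"] / covered["n_total_b"]
    covered["delta"] = covered["level_b"] - covered["level_a"]
    candidates = covered[covered["delta"].abs() >= min_delta].reset_index(drop=True)
    log_filter("find_dmps/coverage+delta", len(merged), len(candidates))
    if candidates.empty:
        return pd.DataFrame(columns=keys + ["level_a", "level_b", "delta",
                                            "p_value"])
    p = fisher_exact_two_sided(
        candidates["n_meth_a"], candidates["n_total_a"] - candidates["n_meth_a"],
        candidates["n_meth_b"], candidates["n_total_b"] - candidates["n_meth_b"])
    candidates["p_value"] = p
    dmps = candidates.loc[p <= alpha,
                          keys + ["level_a", "level_b", "delta", "p_value"]]
    log_filter("find_dmps/fisher", len(candidates), len(dmps))
    return dmps.reset_index(drop=True)


def build_pairs(calls_control: pd.DataFrame, calls_treated: pd.DataFrame,
                features: list[GenomicFeature], expression: pd.DataFrame,
                flank_bp: int = 2000) -> pd.DataFrame:
    """Per-gene (region, context) methylation joined with expression.

    One row per gene x region (up2k/genebody/down2k) x context with the
    read-weighted methylation level in both conditions, the level change
    ``delta_meth``, its log2 fold change ``log2_meth_ratio`` (with a small
    pseudo-level so fully unmethylated regions stay finite), and the gene's
    expression columns.
    """
    genes = [f for f in features if f.kind == "gene"]
    meth_c = feature_region_levels(calls_control, genes, flank_bp=flank_bp)
    meth_t = feature_region_levels(calls_treated, genes, flank_bp=flank_bp)
    keys = ["feature_id", "region", "context"]
    merged = meth_c[keys + ["level"]].merge(
        meth_t[keys + ["level"]], on=keys, suffixes=("_meth_control",
                                                     "_meth_treated"))
    merged = merged.rename(columns={"feature_id": "gene_id"})
    merged["delta_meth"] = (merged["level_meth_treated"]
                            - merged["level_meth_control"])
    eps = 0.01  # pseudo-level: keeps the ratio finite at level 0
    merged["log2_meth_ratio"] = np.log2(
        (merged["level_meth_treated"] + eps)
        / (merged["level_meth_control"] + eps))
    return merged.merge(expression, on="gene_id", how="inner")


def rho_distribution(pairs: pd.DataFrame, subset: str = "all",
                     degs: pd.DataFrame | None = None,
                     dmps: pd.DataFrame | None = None,
                     features: list[GenomicFeature] | None = None,
                     flank_bp: int = 2000,
                     meth_column: str = "log2_meth_ratio",
                     expr_column: str = "log2fc") -> pd.DataFrame:
    """Spearman rho per (region, context) between methylation and expression.

    Both default axes are log2 fold changes, so a promoter that loses most
    of its methylation ranks as strongly demethylated even when the absolute
    level change matches the genome-wide shift.

    ``subset="all"`` uses every gene with defined values; ``"dmp_by_deg"``
    keeps only pairs where the gene is a DEG and its region contains at least
    one DMP of the matching context.  Groups with fewer than 3 usable genes
    are skipped with a warning.  Columns: region, context, rho, p_value, n.
    """
    frame = pairs
    if subset == "dmp_by_deg":
        if degs is None or dmps is None or features is None:
            raise ValueError("dmp_by_deg subset needs degs, dmps and features")
        deg_ids = set(degs["gene_id"])
        keep_keys = _dmp_region_keys(dmps, features, flank_bp)
        mask = [
            (row.gene_id in deg_ids)
            and ((row.gene_id, row.region, row.context) in keep_keys)
            for row in frame.itertuples()
        ]
        frame = frame[np.asarray(mask, dtype=bool)] if len(frame) else frame
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    rows = []
    for (region, context), group in frame.groupby(["region", "context"],
                                                  sort=True, observed=True):
        usable = group[[meth_column, expr_column]].dropna()
        if len(usable) < 3:
            log.warning("rho_distribution: %s/%s has %d usable genes, skipped",
                        region, context, len(usable))
            continue
        rho, p = spearman_rho(usable[meth_column], usable[expr_column])
        rows.append((region, context, rho, p, len(usable)))
    return pd.DataFrame(rows, columns=["region", "context", "rho", "p_value",
                                       "n"])


def _dmp_region_keys(dmps: pd.DataFrame, features: list[GenomicFeature],
                     flank_bp: int) -> set[tuple[str, str, str]]:
    """(gene_id, region, context) triples containing at least one DMP."""
    from .profiles import region_intervals

    keys: set[tuple[str, str, str]] = set()
    genes = [f for f in features if f.kind == "gene"]
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: group.sort_values("pos")
        for chrom, group in dmps.groupby("chrom", sort=False, observed=True)}
    for f in genes:
        group = by_chrom.get(f.chrom)
        if group is None:
            continue
        pos = group["pos"].to_numpy()
        ctx = group["context"].to_numpy()
        for region in ("up2k", "genebody", "down2k"):
            for s, e in region_intervals(f, region, flank_bp):
                i0, i1 = np.searchsorted(pos, [s, e])
                for c in set(ctx[i0:i1]):
                    keys.add((f.id, region, c))
    return keys


def correlated_gene_set(dmrs, degs: pd.DataFrame) -> list[str]:
    """Genes that are DEGs and carry at least one linked DMR (any relation).

    Requires annotated DMRs (``linked_features`` populated).  Returns the
    sorted gene ids; the count is logged.
    """
    deg_ids = set(degs["gene_id"])
    linked: set[str] = set()
    for d in dmrs:
        for fid, _relation in d.linked_features:
            if fid in deg_ids:
                linked.add(fid)
    log.info("correlated_gene_set: %d genes", len(linked))
    return sorted(linked)


def stratified_profiles(calls: pd.DataFrame, features: list[GenomicFeature],
                        strata: dict[str, list[str]],
                        **profile_kwargs) -> dict[str, pd.DataFrame]:
    """Metagene profile per expression stratum (delegates to profiles).

    Empty strata are skipped with a warning.
    """
    genes = {f.id: f for f in features if f.kind == "gene"}
    out: dict[str, pd.DataFrame] = {}
    for label, gene_ids in strata.items():
        members = [genes[g] for g in gene_ids if g in genes]
        if not members:
            log.warning("stratified_profiles: stratum %r is empty, skipped",
                        label)
            continue
        out[label] = profile_features(calls, members, **profile_kwargs)
    return out
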