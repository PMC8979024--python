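"""Sequence-context assignment and binomial-corrected methylation calling.

Plant cytosines are methylated in three sequence contexts — CG, CHG and CHH
(H = A, T or C) — read 5'->3' on the cytosine's own strand.  Bisulfite
treatment converts unmethylated C to T with a small failure rate, so an
observed unconverted read is only evidence of methylation beyond that
background.  Each covered site is therefore tested one-sided against
``Binomial(n_total, conversion_error_rate)``; p-values are corrected with
Benjamini-Hochberg across all tested sites and a site is called methylated
when its q-value passes the FDR threshold (and it has at least one
methylated read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULTS, log_filter
from .formats import CONTEXTS, GenomeSequence

log = logging.getLogger("rrbsmeth")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


def assign_context(genome: GenomeSequence, chrom: str, pos: int,
                   strand: str) -> str | None:
    """Context of the cytosine at 0-based ``pos`` on ``strand``.

    The context is read from the two bases immediately downstream on the
    site's strand: CG if the next base is G, CHG if the base after that is G,
    otherwise CHH.  Returns ``None`` when fewer than two downstream bases
    exist or any involved base is N.  Raises if the addressed base is not a
    cytosine on the stated strand (G on the plus strand for ``-`` sites).
    """
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"{chrom}:{pos} outside contig of length {len(seq)}")
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}:+ is {base}, not C")
        if pos + 2 >= len(seq):
            return None
        b1, b2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}:- is {base} on the plus strand, "
                             "not G (no C on the minus strand)")
        if pos - 2 < 0:
            return None
        # downstream on the minus strand = upstream on plus, complemented
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        b1, b2 = comp[seq[pos - 1]], comp[seq[pos - 2]]
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if "N" in (b1, b2):
        return None
    if b1 == "G":
        return "CG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def enumerate_cytosines(genome: GenomeSequence) -> pd.DataFrame:
    """All cytosines with a defined context, both strands, as a sites frame.

    Columns: chrom, pos (0-based), strand, context; n_meth/n_total are absent
    (this is annotation, not observation).  Vectorized over each contig.
    """
    frames = []
    contig_names = sorted(genome.contigs)
    for chrom, seq in sorted(genome.contigs.items()):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        # plus strand
        pos_p = np.flatnonzero(arr == _C)
        pos_p = pos_p[pos_p <= n - 3]
        b1, b2 = arr[pos_p + 1], arr[pos_p + 2]
        ok = (b1 != _N) & (b2 != _N)
        pos_p, b1, b2 = pos_p[ok], b1[ok], b2[ok]
        ctx_p = np.where(b1 == _G, 0, np.where(b2 == _G, 1, 2))
        # minus strand: plus-strand G, context from upstream plus-strand bases
        pos_m = np.flatnonzero(arr == _G)
        pos_m = pos_m[pos_m >= 2]
        u1, u2 = arr[pos_m - 1], arr[pos_m - 2]
        ok = (u1 != _N) & (u2 != _N)
        pos_m, u1, u2 = pos_m[ok], u1[ok], u2[ok]
        ctx_m = np.where(u1 == _C, 0, np.where(u2 == _C, 1, 2))

        pos = np.concatenate([pos_p, pos_m])
        ctx = np.concatenate([ctx_p, ctx_m])
        strand = np.concatenate([np.zeros(pos_p.size, dtype=np.int8),
                                 np.ones(pos_m.size, dtype=np.int8)])
        order = np.lexsort((strand, pos))
        frames.append(pd.DataFrame({
            "chrom": pd.Categorical.from_codes(
                np.full(pos.size, contig_names.index(chrom), dtype=np.int8),
                categories=contig_names),
            "pos": pos[order],
            "strand": pd.Categorical.from_codes(strand[order],
                                                categories=["+", "-"]),
            "context": pd.Categorical.from_codes(ctx[order].astype(np.int8),
                                                 categories=list(CONTEXTS)),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    return pd.concat(frames, ignore_index=True)


def binomial_tail_p(n_meth, n_total, error_rate: float):
    """One-sided tail P(X >= n_meth) for X ~ Binomial(n_total, error_rate)."""
    return stats.binom.sf(np.asarray(n_meth) - 1, np.asarray(n_total),
                          error_rate)


def call_methylated_sites(sites: pd.DataFrame,
                          conversion_error_rate: float | None = None,
                          fdr_alpha: float | None = None) -> pd.DataFrame:
    """Test every covered site against the conversion-error null.

    Sites with ``n_total == 0`` are excluded (logged).  Returns a calls frame
    with ``level``, ``p_value``, ``q_value`` (Benjamini-Hochberg over all
    tested sites) and ``is_methylated`` (q <= fdr_alpha and n_meth >= 1).
    """
    if conversion_error_rate is None:
        conversion_error_rate = DEFAULTS["conversion_error_rate"]
    if fdr_alpha is None:
        fdr_alpha = DEFAULTS["fdr_alpha"]
    if not 0 <= conversion_error_rate < 1:
        raise ValueError("conversion_error_rate must be in [0, 1)")
    if len(sites) and ((sites["n_meth"] < 0).any() or (sites["n_total"] < 0).any()):
        raise ValueError("negative counts in sites frame")
    if (sites["n_meth"] > sites["n_total"]).any():
        raise ValueError("n_meth > n_total in sites frame")

    covered = sites[sites["n_total"] > 0].copy()
    log_filter("call_methylated_sites/coverage", len(sites), len(covered))
    if covered.empty:
        for col in ("level", "p_value", "q_value"):
            covered[col] = pd.Series(dtype=float)
        covered["is_methylated"] = pd.Series(dtype=bool)
        return covered

    n_meth = covered["n_meth"].to_numpy()
    n_total = covered["n_total"].to_numpy()
    p = binomial_tail_p(n_meth, n_total, conversion_error_rate)
    q = multipletests(p, method="fdr_bh")[1]
    covered["level"] = n_meth / n_total
    covered["p_value"] = p
    covered["q_value"] = q
    covered["is_methylated"] = (q <= fdr_alpha) & (n_meth >= 1)
    log_filter("call_methylated_sites/verdict", len(covered),
               int(covered["is_methylated"].sum()))
    return covered.reset_index(drop=True)


def methylation_level(calls: pd.DataFrame,
                      weighting: str = "read_weighted") -> float:
    """Aggregate methylation level of a collection of sites.

    ``read_weighted`` (default): sum(n_meth) / sum(n_total);
    ``site_mean``: mean of per-site levels over sites with coverage.
    Returns NaN (with a warning) when no reads are available.
    """
    covered = calls[calls["n_total"] > 0]
    if covered.empty:
        log.warning("methylation_level: no covered sites, level undefined")
        return float("nan")
    if weighting == "read_weighted":
        return float(covered["n_meth"].sum() / covered["n_total"].sum())
    if weighting == "site_mean":
        return float((covered["n_meth"] / covered["n_total"]).mean())
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class GenomeMethylationSummary:
    """Genome-wide methylated-site counts per context and their proportions."""

    n_mcg: int
    n_mchg: int
    n_mchh: int

    @property
    def total(self) -> int:
        return self.n_mcg + self.n_mchg + self.n_mchh

    @property
    def degenerate(self) -> bool:
        return self.total == 0

    @property
    def proportions(self) -> dict[str, float]:
        """Exact fractions of the total (0 when the total is 0)."""
        t = self.total
        counts = dict(zip(CONTEXTS, (self.n_mcg, self.n_mchg, self.n_mchh)))
        return {ctx: (c / t if t else 0.0) for ctx, c in counts.items()}

    @property
    def proportions_percent(self) -> dict[str, float]:
        """Two-decimal percentages that sum to exactly 100.00.

        Largest-remainder rounding: floor every percentage at hundredths,
        then hand the missing hundredths to the largest fractional parts
        (ties broken by context order).  Plain per-entry rounding can sum to
        100.01; summary tables conventionally reconcile to 100.
        """
        if self.degenerate:
            return {ctx: 0.0 for ctx in CONTEXTS}
        hundredths = {ctx: 10_000 * p for ctx, p in self.proportions.items()}
        floors = {ctx: int(v) for ctx, v in hundredths.items()}
        shortfall = 10_000 - sum(floors.values())
        order = sorted(CONTEXTS, key=lambda c: hundredths[c] - floors[c],
                       reverse=True)
        for ctx in order[:shortfall]:
            floors[ctx] += 1
        return {ctx: floors[ctx] / 100 for ctx in CONTEXTS}

    @classmethod
    def from_counts(cls, n_mcg: int, n_mchg: int,
                    n_mchh: int) -> "GenomeMethylationSummary":
        return cls(n_mcg, n_mchg, n_mchh)


def genome_summary(calls: pd.DataFrame) -> GenomeMethylationSummary:
    """Count methylated sites per context over a calls frame."""
    if calls.empty:
        log.warning("genome_summary: empty calls, degenerate total")
        return GenomeMethylationSummary(0, 0, 0)
    meth = calls[calls["is_methylated"]]
    counts = meth["context"].value_counts()
    return GenomeMethylationSummary(int(counts.get("CG", 0)),
                                    int(counts.get("CHG", 0)),
                                    int(counts.get("CHH", 0)))
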