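"""10-mer alignments around called cytosines and position frequency profiles.

For every class (context x methylated/unmethylated verdict) the 10 bases
around each site are collected with the focal cytosine at the fifth position
(1-based): plus-strand sites take the window four bases upstream through five
downstream; minus-strand sites take the reverse complement of the mirrored
window.  Per-position base frequencies and information content
(IC = 2 + sum_b p_b log2 p_b, in bits) summarize each alignment, and two
alignments are compared position-by-position with a chi-square homogeneity
test on the base counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenomeSequence

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

WINDOW = 10
FOCAL_INDEX = 4  # 0-based; "the fifth position"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerAlignment:
    """Fixed-width windows around the focal cytosines of one class."""

    label: str               # e.g. "CG:methylated"
    sequences: list[str]
    skipped: int = 0         # sites near contig edges or containing N

    def __post_init__(self) -> None:
        for s in self.sequences:
            if len(s) != WINDOW:
                raise ValueError(f"window {s!r} is not {WINDOW} bases")
            if s[FOCAL_INDEX] != "C":
                raise ValueError(f"window {s!r} lacks C at the focal position")


@dataclass
class PositionProfile:
    label: str
    counts: np.ndarray       # (WINDOW, 4) integer base counts
    frequencies: np.ndarray  # (WINDOW, 4), rows sum to 1
    information: np.ndarray  # (WINDOW,) bits in [0, 2]


def extract_10mers(genome: GenomeSequence, calls: pd.DataFrame, context: str,
                   methylated: bool) -> KmerAlignment:
    """Collect 10-base windows for one (context, verdict) class.

    The unmethylated class means covered sites whose verdict is False, not
    merely uncovered positions.  Windows running off the contig or containing
    N are skipped and counted.
    """
    subset = calls[(calls["context"] == context)
                   & (calls["is_methylated"] == methylated)]
    sequences: list[str] = []
    skipped = 0
    for chrom, group in subset.groupby("chrom", sort=False, observed=True):
        seq = genome[chrom]
        n = len(seq)
        for pos, strand in zip(group["pos"], group["strand"]):
            if strand == "+":
                lo, hi = pos - FOCAL_INDEX, pos + (WINDOW - FOCAL_INDEX)
                if lo < 0 or hi > n:
                    skipped += 1
                    continue
                window = seq[lo:hi]
            else:
                lo, hi = pos - (WINDOW - FOCAL_INDEX - 1), pos + FOCAL_INDEX + 1
                if lo < 0 or hi > n:
                    skipped += 1
                    continue
                window = reverse_complement(seq[lo:hi])
            if "N" in window:
                skipped += 1
                continue
            sequences.append(window)
    label = f"{context}:{'methylated' if methylated else 'unmethylated'}"
    return KmerAlignment(label=label, sequences=sequences, skipped=skipped)


def position_profile(alignment: KmerAlignment,
                     small_sample_correction: bool = False) -> PositionProfile:
    """Column base frequencies and per-position information content.

    IC uses the standard 2 - entropy formulation; the optional small-sample
    correction subtracts the first-order bias term 3 / (2 ln2 * n).
    """
    if not alignment.sequences:
        raise ValueError(f"alignment {alignment.label!r} is empty")
    depth = len(alignment.sequences)
    counts = np.zeros((WINDOW, 4), dtype=int)
    code = {b: i for i, b in enumerate(BASES)}
    for seq in alignment.sequences:
        for j, base in enumerate(seq):
            counts[j, code[base]] += 1
    freqs = counts / depth
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        ic = np.maximum(0.0, ic - 3.0 / (2.0 * np.log(2) * depth))
    return PositionProfile(label=alignment.label, counts=counts,
                           frequencies=freqs, information=ic)


def compare_profiles(profile_a: PositionProfile,
                     profile_b: PositionProfile) -> pd.DataFrame:
    """Per-position frequency differences and homogeneity p-values.

    For each position the two columns' base counts form a 2x4 contingency
    table tested with Pearson chi-square (bases absent from both columns are
    dropped; identical single-base columns give chi2 = 0, p = 1).
    Columns: position (1-based), dA..dT (freq_b - freq_a), chi2, p_value.
    """
    if profile_a.counts.shape != profile_b.counts.shape:
        raise ValueError("profiles have mismatched window lengths")
    rows = []
    for j in range(profile_a.counts.shape[0]):
        diff = profile_b.frequencies[j] - profile_a.frequencies[j]
        table = np.vstack([profile_a.counts[j], profile_b.counts[j]])
        keep = table.sum(axis=0) > 0
        reduced = table[:, keep]
        if reduced.shape[1] < 2:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(reduced, correction=False)
        rows.append((j + 1, *diff, float(chi2), float(p)))
    return pd.DataFrame(rows, columns=["position", "dA", "dC", "dG", "dT",
                                       "chi2", "p_value"])


def profiles_to_frame(profiles: list[PositionProfile]) -> pd.DataFrame:
    """Long-format table (class, position, A, C, G, T, IC) for TSV export."""
    rows = []
    for p in profiles:
        for j in range(p.frequencies.shape[0]):
            rows.append((p.label, j + 1, *p.frequencies[j],
                         float(p.information[j])))
    return pd.DataFrame(rows, columns=["class", "position", "A", "C", "G", "T",
                                       "IC"])
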