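"""On-disk formats, coordinate conventions, and domain containers.

Internal coordinates are 0-based half-open everywhere.  1-based conventions
exist only at file boundaries: GFF3 (1-based closed) and the six-column
cytosine report (1-based positions).  The cytosine report is the canonical
per-site exchange format::

    chrom <TAB> pos(1-based) <TAB> strand <TAB> context <TAB> n_meth <TAB> n_total

A "methylation-ratio"-style dialect with a trailing level column is accepted
on read (the extra column is ignored).

In memory, collections of cytosine sites are pandas DataFrames with columns
``chrom, pos (0-based), strand, context, n_meth, n_total`` ("sites frame");
calling adds ``p_value, q_value, is_methylated, level`` ("calls frame").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("rrbsmeth")

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
SITE_COLUMNS = REPORT_COLUMNS  # same names; pos is 0-based in a sites frame
CALL_COLUMNS = SITE_COLUMNS + ["level", "p_value", "q_value", "is_methylated"]

_ALPHABET = set("ACGTN")


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by contig name (A/C/G/T/N only)."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"contig {name!r} contains non-DNA symbols {bad}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
        return cls(contigs)

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in self.contigs.items()]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class GenomicFeature:
    """A gene or transposable element with an optional sub-feature layout.

    ``start``/``end`` are the 0-based half-open body interval.  Sub-features
    are ``(kind, start, end)`` triples with kind in
    {exon, intron, CDS, 5UTR, 3UTR}, all contained in the body.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # "gene" or "TE"
    subfeatures: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.id}: end <= start "
                             f"({self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"feature {self.id}: unknown strand {self.strand!r}")
        for kind, s, e in self.subfeatures:
            if s < self.start or e > self.end:
                raise ValueError(f"feature {self.id}: {kind} [{s},{e}) outside "
                                 f"body [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sub(self, kind: str) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.subfeatures if k == kind]


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path,
                         genome: GenomeSequence | None = None) -> pd.DataFrame:
    """Read a six-column cytosine report into a report-dialect DataFrame.

    Positions stay 1-based as in the file; use :func:`report_to_sites` for the
    internal 0-based frame.  If ``genome`` is given, each record's context is
    re-derived from the sequence and mismatches are flagged in a boolean
    ``context_ok`` column (and counted in the log).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 7:  # ratio-style dialect: trailing level ignored
                parts = parts[:6]
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, "
                                 f"got {len(parts)}")
            chrom, pos, strand, context, n_meth, n_total = parts
            try:
                pos_i, n_meth_i, n_total_i = int(pos), int(n_meth), int(n_total)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {exc}") from None
            if pos_i < 1:
                raise ValueError(f"{path}:{lineno}: position {pos_i} < 1")
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            if context not in CONTEXTS:
                raise ValueError(f"{path}:{lineno}: unknown context {context!r}")
            if n_meth_i < 0 or n_total_i < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if n_meth_i > n_total_i:
                raise ValueError(f"{path}:{lineno}: n_meth {n_meth_i} > "
                                 f"n_total {n_total_i}")
            rows.append((chrom, pos_i, strand, context, n_meth_i, n_total_i))
    if not rows:
        log.warning("cytosine report %s is empty", path)
        return pd.DataFrame(columns=REPORT_COLUMNS)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if genome is not None:
        from .methcall import assign_context  # local import: no cycle at load

        derived = [
            assign_context(genome, chrom, pos - 1, strand)
            if chrom in genome else None
            for chrom, pos, strand in zip(report["chrom"], report["pos"],
                                          report["strand"])
        ]
        report["context_ok"] = [d == c for d, c in zip(derived, report["context"])]
        n_bad = int((~report["context_ok"]).sum())
        if n_bad:
            log.warning("%s: %d/%d records disagree with genome-derived context",
                        path, n_bad, len(report))
    return report


def write_cytosine_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a report-dialect frame (1-based positions) as six-column TSV."""
    report[REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def report_to_sites(report: pd.DataFrame) -> pd.DataFrame:
    """Convert the 1-based report dialect to the internal 0-based sites frame."""
    sites = report[REPORT_COLUMNS].copy()
    sites["pos"] = sites["pos"] - 1
    return sites


def sites_to_report(sites: pd.DataFrame) -> pd.DataFrame:
    report = sites[REPORT_COLUMNS].copy()
    report["pos"] = report["pos"] + 1
    return report


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    """Read a calls TSV written by :func:`write_calls_tsv` (0-based internally)."""
    calls = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls["pos"] = calls["pos"] - 1
    calls["is_methylated"] = calls["is_methylated"].astype(bool)
    return calls


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls[CALL_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature annotations
# ---------------------------------------------------------------------------

_GFF_KIND = {"gene": "gene", "TE": "transposable_element"}
_GFF_SUB = {"exon": "exon", "CDS": "CDS",
            "five_prime_UTR": "5UTR", "three_prime_UTR": "3UTR",
            "intron": "intron"}


def read_features(path: str | Path, kind: str = "gene") -> list[GenomicFeature]:
    """Load gene or TE annotations from GFF3 or BED (dialect by extension).

    GFF3 intervals (1-based closed) are converted to internal 0-based
    half-open; BED passes through.  ``kind`` is "gene" or "TE"; in GFF3 these
    map to the ``gene`` and ``transposable_element`` feature types, with
    exon/CDS/UTR children attached to parents by ID.
    """
    if kind not in ("gene", "TE"):
        raise ValueError(f"kind must be 'gene' or 'TE', got {kind!r}")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_features_gff(path, kind)
    if suffix == ".bed":
        return _read_features_bed(path, kind)
    raise ValueError(f"cannot auto-detect annotation dialect from {path.name!r} "
                     "(expected .gff/.gff3 or .bed)")


def _read_features_gff(path: Path, kind: str) -> list[GenomicFeature]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    features = []
    for top in db.features_of_type(_GFF_KIND[kind], order_by="start"):
        if top.strand not in STRANDS:
            raise ValueError(f"{path}: feature {top.id}: unknown strand "
                             f"{top.strand!r}")
        start, end = top.start - 1, top.end  # 1-based closed -> 0-based half-open
        if end <= start:
            raise ValueError(f"{path}: feature {top.id}: empty interval")
        subs = []
        for child in db.children(top.id, order_by="start"):
            sub_kind = _GFF_SUB.get(child.featuretype)
            if sub_kind is None:
                continue
            subs.append((sub_kind, child.start - 1, child.end))
        features.append(GenomicFeature(id=top.id, chrom=top.seqid, start=start,
                                       end=end, strand=top.strand, kind=kind,
                                       subfeatures=subs))
    return features


def _read_features_bed(path: Path, kind: str) -> list[GenomicFeature]:
    features = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{kind}_{lineno}"
            strand = parts[5] if len(parts) > 5 else "+"
            if strand == ".":
                strand = "+"
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            features.append(GenomicFeature(id=name, chrom=chrom, start=start,
                                           end=end, strand=strand, kind=kind))
    return features


def write_features_gff(features: list[GenomicFeature], path: str | Path) -> None:
    """Write features (and sub-features) as GFF3, 1-based closed intervals."""
    type_of = {"gene": "gene", "TE": "transposable_element"}
    sub_type = {v: k for k, v in _GFF_SUB.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f"{f.chrom}\trrbsmeth\t{type_of[f.kind]}\t{f.start + 1}\t"
                     f"{f.end}\t.\t{f.strand}\t.\tID={f.id}\n")
            for i, (kind, s, e) in enumerate(f.subfeatures):
                fh.write(f"{f.chrom}\trrbsmeth\t{sub_type[kind]}\t{s + 1}\t{e}\t"
                         f".\t{f.strand}\t.\tID={f.id}.{kind}{i};Parent={f.id}\n")


# ---------------------------------------------------------------------------
# result exports
# ---------------------------------------------------------------------------

def write_dmr_bed(dmrs, path: str | Path) -> None:
    """Write DMRs as BED6: name ``context:direction``, score ``-log10 p``.

    The score is capped at 1000 (p = 0 maps to the cap); strand is ``.``.
    """
    with open(path, "w") as fh:
        for d in dmrs:
            score = 1000.0 if d.p_value <= 0 else min(1000.0, -math.log10(d.p_value))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}:{d.direction}\t"
                     f"{score:g}\t.\n")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table TSV.

    Required columns: gene_id, level_control, level_treated, log2fc, fdr.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "level_control", "level_treated", "log2fc", "fdr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a metagene profile frame (bin_index, region, context, ...) as TSV."""
    profile.to_csv(path, sep="\t", index=False)


def export_scaffold_tracks(calls: pd.DataFrame, path: str | Path,
                           window: int = 10000) -> pd.DataFrame:
    """Per-scaffold windowed methylated-site counts, a plain circos-style track.

    One row per (chrom, window, context): window start/end and the number of
    methylated sites falling inside.  Returns the frame and writes it as TSV.
    """
    meth = calls[calls["is_methylated"]]
    rows = []
    for (chrom, context), group in meth.groupby(["chrom", "context"], sort=True, observed=True):
        if group.empty:
            continue
        bins = group["pos"] // window
        counts = bins.value_counts().sort_index()
        for b, n in counts.items():
            rows.append((chrom, int(b) * window, (int(b) + 1) * window,
                         context, int(n)))
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                        "n_methylated"])
    track.to_csv(path, sep="\t", index=False)
    return track
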