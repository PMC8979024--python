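"""Synthetic RRBS-like data generator with an emitted ground truth.

The generator emulates the statistical structure of a cold-stress RRBS
methylome experiment so that every downstream stage is testable offline:

* a random genome representing the MspI-enriched, CG-rich genome fraction
  that reduced-representation sequencing actually samples (CCGG motifs are
  injected at a configurable mean spacing so size-selected fragments tile
  most of the simulated sequence);
* non-overlapping genes (with exon/CDS/UTR layouts) and TEs, spaced at
  least 4 kb apart so 2-kb flanks never collide;
* per-cytosine true methylation levels built from feature-class/context
  baselines (mCG > mCHG > mCHH; TEs above genes above intergenic), a
  "W"-shaped positional profile for gene bodies (dips at both body edges),
  a single-hump profile for TEs (high body, exponentially decaying flanks),
  and a cold condition that demethylates everything except TE-body mCG,
  which it slightly increases;
* planted hypo-CG blocks (the DMR ground truth), half of them in gene
  promoters where they drive up-regulation in the simulated expression
  table; planted blocks carry unmethylated margins on both sides so that
  their recovery measures the region caller rather than chance chaining
  into the surrounding background;
* an observation model: per-site coverage is Poisson, and observed
  methylated reads are Binomial(n_total, level + (1 - level) * err), i.e.
  failed bisulfite conversion is the only error mode;
* a differential-expression table with log-normal baselines, a positive
  log2 fold-change effect for promoter-demethylated genes, and FDRs from a
  generator-internal two-group test on simulated replicates.

Everything is deterministic given the seed; the truth (planted blocks,
affected genes, per-site levels) is emitted alongside the data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import (CONTEXTS, GenomeSequence, GenomicFeature,
                      sites_to_report, write_cytosine_report,
                      write_expression_table, write_features_gff)
from .methcall import enumerate_cytosines

log = logging.getLogger("rrbsmeth")


def _default(d):
    return field(default_factory=lambda: dict(d))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Baseline levels and the cold multipliers encode the qualitative pattern
    of the emulated experiment: heavier methylation in TEs than genes, the
    CG > CHG > CHH ordering, global demethylation under cold except for a
    slight TE-body mCG increase.  The TE-body mCG factor (x1.05) is a stated
    invention for testing — the emulated effect is only known to be "slight".
    """

    seed: int = 0
    # genome
    n_contigs: int = 2
    contig_length: int = 500_000
    gc_content: float = 0.40          # CG-rich RRBS fraction, not whole genome
    mspi_spacing: float = 100.0       # mean bp between injected CCGG motifs
    mspi_spacing_sd: float = 25.0     # spread of the (truncated) spacing
    # annotation
    n_genes: int = 40
    n_tes: int = 20
    gene_length: tuple[int, int] = (2000, 5000)
    te_length: tuple[int, int] = (1000, 3000)
    min_feature_gap: int = 4000       # body-to-body, keeps 2-kb flanks apart
    flank_bp: int = 2000
    # true methylation levels
    gene_baseline: dict = _default({"CG": 0.60, "CHG": 0.35, "CHH": 0.15})
    te_baseline: dict = _default({"CG": 0.85, "CHG": 0.60, "CHH": 0.30})
    intergenic_baseline: dict = _default({"CG": 0.02, "CHG": 0.02, "CHH": 0.02})
    cold_gene_multiplier: dict = _default({"CG": 0.6, "CHG": 0.6, "CHH": 0.6})
    cold_te_multiplier: dict = _default({"CG": 1.05, "CHG": 0.7, "CHH": 0.7})
    cold_intergenic_multiplier: float = 0.6
    gene_dip_depth: float = 0.6       # "W": fractional dip at body edges
    gene_dip_width: float = 0.08      # Gaussian sigma, fraction of body length
    te_flank_decay: float = 300.0     # bp, exponential hump shoulder
    # observation model
    coverage_mean: float = 30.0
    conversion_error_rate: float = 0.005
    fragment_size_min: int = 40
    fragment_size_max: int = 220
    # planted DMR truth
    n_planted_dmrs: int = 10
    planted_span: tuple[int, int] = (200, 800)
    planted_level_control: float = 0.8
    planted_level_treated: float = 0.1
    planted_margin: int = 600         # unmethylated CG margin on each side
    promoter_dmr_fraction: float = 0.5
    # expression model
    expression_log_mu: float = 2.0    # natural-log mean of baseline level
    expression_log_sigma: float = 1.0
    expression_effect_log2fc: float = 2.0  # promoter-demethylation effect
    expression_null_sigma: float = 0.2     # log2fc noise for unaffected genes
    expression_rep_sigma: float = 0.25     # log2 replicate noise
    n_replicates: int = 3
    silenced_fraction: float = 0.15   # genes with no expression
    silenced_downstream_boost: float = 2.0  # their down2k methylation factor

    def validate(self) -> None:
        for d in (self.gene_baseline, self.te_baseline,
                  self.intergenic_baseline):
            for ctx, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"baseline {ctx}={v} outside [0, 1]")
        if not 0 <= self.conversion_error_rate < 1:
            raise ValueError("conversion_error_rate must be in [0, 1)")


@dataclass
class PlantedBlock:
    """One planted hypo-CG block; the DMR ground truth."""

    chrom: str
    start: int
    end: int
    context: str = "CG"
    direction: str = "hypo"
    gene_id: str | None = None
    relation: str | None = None  # "up2k" or "body" when linked to a gene


@dataclass
class TruthRecord:
    planted: list[PlantedBlock]
    promoter_genes: list[str]       # genes with a planted promoter block
    silenced_genes: list[str]
    de_truth: dict[str, bool]       # gene id -> truly up-regulated
    levels_control: pd.DataFrame    # chrom,pos,strand,context,level
    levels_treated: pd.DataFrame
    clip_events: int = 0


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    features: list[GenomicFeature]
    fragments: dict[str, list[tuple[int, int]]]
    truth: TruthRecord
    report_control: pd.DataFrame    # sites frame with observed counts
    report_treated: pd.DataFrame
    expression: pd.DataFrame


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeSequence, list[GenomicFeature]]:
    """Random genome plus non-overlapping gene/TE annotations.

    Deterministic per seed.  Raises when the requested features cannot be
    placed with the required spacing.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_pool = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ccgg = np.frombuffer(b"CCGG", dtype=np.uint8)

    # Inter-site spacing is a truncated normal held inside the size-selection
    # window: the simulated sequence models the retained CG-dense fraction,
    # so nearly every fragment survives the 40-220 bp cut.
    def next_spacing() -> float:
        s = rng.normal(config.mspi_spacing, config.mspi_spacing_sd)
        return float(np.clip(s, config.fragment_size_min,
                             config.fragment_size_max - 20))

    contigs: dict[str, str] = {}
    for i in range(config.n_contigs):
        arr = rng.choice(base_pool, size=config.contig_length, p=probs)
        p = next_spacing()
        while p + 4 < config.contig_length:
            q = int(p)
            arr[q:q + 4] = ccgg
            p += 4 + next_spacing()
        contigs[f"ctg{i + 1}"] = arr.tobytes().decode("ascii")
    genome = GenomeSequence(contigs)

    kinds = ["gene"] * config.n_genes + ["TE"] * config.n_tes
    kinds = [kinds[j] for j in rng.permutation(len(kinds))]
    per_contig: list[list[str]] = [[] for _ in range(config.n_contigs)]
    for j, kind in enumerate(kinds):
        per_contig[j % config.n_contigs].append(kind)

    features: list[GenomicFeature] = []
    n_gene = n_te = 0
    margin = config.flank_bp + 500
    for i, contig_kinds in enumerate(per_contig):
        chrom = f"ctg{i + 1}"
        cursor = margin + int(rng.integers(0, 1000))
        for kind in contig_kinds:
            lo, hi = (config.gene_length if kind == "gene"
                      else config.te_length)
            length = int(rng.integers(lo, hi + 1))
            if cursor + length > config.contig_length - margin:
                raise ValueError(
                    "feature placement infeasible: reduce n_genes/n_tes or "
                    "increase contig_length")
            strand = str(rng.choice(["+", "-"]))
            if kind == "gene":
                n_gene += 1
                fid = f"g{n_gene:04d}"
                subs = _gene_layout(cursor, cursor + length, strand)
            else:
                n_te += 1
                fid = f"te{n_te:04d}"
                subs = []
            features.append(GenomicFeature(id=fid, chrom=chrom, start=cursor,
                                           end=cursor + length, strand=strand,
                                           kind=kind, subfeatures=subs))
            cursor += length + config.min_feature_gap + int(rng.integers(0, 1500))
    return genome, features


def _gene_layout(start: int, end: int, strand: str) -> list[tuple[str, int, int]]:
    """Exon/CDS/UTR sub-features for one gene (local fractions, strand-aware)."""
    length = end - start
    utr = max(100, round(0.1 * length))
    cuts = [0, 0.25, 0.40, 0.60, 0.75, 1.0]
    edges = [round(c * length) for c in cuts]
    exons_local = [(edges[0], edges[1]), (edges[2], edges[3]),
                   (edges[4], edges[5])]
    cds_window = (utr, length - utr)
    subs_local: list[tuple[str, int, int]] = []
    subs_local.append(("5UTR", 0, utr))
    subs_local.append(("3UTR", length - utr, length))
    for s, e in exons_local:
        subs_local.append(("exon", s, e))
        cs, ce = max(s, cds_window[0]), min(e, cds_window[1])
        if ce > cs:
            subs_local.append(("CDS", cs, ce))

    def to_genomic(s: int, e: int) -> tuple[int, int]:
        if strand == "+":
            return start + s, start + e
        return end - e, end - s

    return [(kind, *to_genomic(s, e)) for kind, s, e in subs_local]


# ---------------------------------------------------------------------------
# MspI digest
# ---------------------------------------------------------------------------

def mspI_digest(genome: GenomeSequence, size_min: int = 40,
                size_max: int = 220) -> dict[str, list[tuple[int, int]]]:
    """In-silico MspI digest with size selection.

    The enzyme cuts C^CGG — between the first and second base of every CCGG
    occurrence.  Fragments whose length lies in [size_min, size_max] are
    retained; downstream coverage is restricted to retained fragments.
    """
    retained: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in genome.contigs.items():
        cuts = [m.start() + 1 for m in re.finditer("CCGG", seq)]
        bounds = [0] + cuts + [len(seq)]
        frags = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
                 if bounds[i + 1] > bounds[i]]
        retained[chrom] = [(s, e) for s, e in frags
                           if size_min <= e - s <= size_max]
    return retained


def sites_in_fragments(sites: pd.DataFrame,
                       fragments: dict[str, list[tuple[int, int]]]
                       ) -> np.ndarray:
    """Boolean mask: which sites fall inside a retained fragment."""
    sites = sites.reset_index(drop=True)
    mask = np.zeros(len(sites), dtype=bool)
    for chrom, group in sites.groupby("chrom", sort=False, observed=True):
        frags = fragments.get(chrom, [])
        if not frags:
            continue
        starts = np.array([s for s, _ in frags])
        ends = np.array([e for _, e in frags])
        pos = group["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[group.index.to_numpy()] = inside
    return mask


# ---------------------------------------------------------------------------
# true methylome
# ---------------------------------------------------------------------------

def plant_blocks(features: list[GenomicFeature], silenced: set[str],
                 config: SimulationConfig,
                 rng: np.random.Generator) -> list[PlantedBlock]:
    """Place the planted hypo-CG blocks: promoters first, then gene bodies."""
    genes = [f for f in features if f.kind == "gene"]
    eligible = [g for g in genes if g.id not in silenced]
    n_prom = round(config.n_planted_dmrs * config.promoter_dmr_fraction)
    n_body = config.n_planted_dmrs - n_prom
    if n_prom + n_body > len(eligible):
        raise ValueError("not enough non-silenced genes to host planted blocks")
    order = rng.permutation(len(eligible))
    hosts = [eligible[j] for j in order[:n_prom + n_body]]

    blocks: list[PlantedBlock] = []
    span_lo, span_hi = config.planted_span
    for g in hosts[:n_prom]:
        span = int(rng.integers(span_lo, span_hi + 1))
        gap = int(rng.integers(100, max(101, config.flank_bp - span + 1)))
        if g.strand == "+":
            start = g.start - gap - span
        else:
            start = g.end + gap
        blocks.append(PlantedBlock(chrom=g.chrom, start=start,
                                   end=start + span, gene_id=g.id,
                                   relation="up2k"))
    for g in hosts[n_prom:]:
        span = min(int(rng.integers(span_lo, span_hi + 1)), g.length - 200)
        start = g.start + (g.length - span) // 2
        blocks.append(PlantedBlock(chrom=g.chrom, start=start,
                                   end=start + span, gene_id=g.id,
                                   relation="body"))
    return blocks


def simulate_methylome(genome: GenomeSequence,
                       features: list[GenomicFeature],
                       config: SimulationConfig, condition: str,
                       planted: list[PlantedBlock] | None = None,
                       silenced: set[str] | None = None,
                       sites: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, int]:
    """True per-site methylation levels for one condition.

    Each cytosine's level is its feature-class/context baseline times the
    positional shape function, times the condition multiplier under "cold";
    planted blocks override CG levels locally and zero their margins.
    Returns (levels frame, number of clipped sites).
    """
    if condition not in ("control", "cold"):
        raise ValueError(f"condition must be control/cold, got {condition!r}")
    cold = condition == "cold"
    planted = planted or []
    silenced = silenced or set()
    if sites is None:
        sites = enumerate_cytosines(genome)

    ctx_code = {c: i for i, c in enumerate(CONTEXTS)}
    ig = np.array([config.intergenic_baseline[c] for c in CONTEXTS])
    gene_b = np.array([config.gene_baseline[c] for c in CONTEXTS])
    te_b = np.array([config.te_baseline[c] for c in CONTEXTS])
    gene_m = np.array([config.cold_gene_multiplier[c] for c in CONTEXTS])
    te_m = np.array([config.cold_te_multiplier[c] for c in CONTEXTS])
    ig_m = config.cold_intergenic_multiplier

    frames = []
    clip_events = 0
    for chrom, group in sites.groupby("chrom", sort=True, observed=True):
        group = group.sort_values("pos", kind="stable")
        pos = group["pos"].to_numpy()
        ctx = group["context"].map(ctx_code).to_numpy()
        level = ig[ctx] * (ig_m if cold else 1.0)

        for f in (f for f in features if f.chrom == chrom):
            flank = config.flank_bp
            i0, i1 = np.searchsorted(pos, [f.start, f.end])
            j0, j1 = np.searchsorted(pos, [f.start - flank, f.start])
            k0, k1 = np.searchsorted(pos, [f.end, f.end + flank])
            body, left, right = slice(i0, i1), slice(j0, j1), slice(k0, k1)
            if f.kind == "gene":
                t = ((pos[body] - f.start) if f.strand == "+"
                     else (f.end - 1 - pos[body])) / f.length
                w = config.gene_dip_width
                shape = 1.0 - config.gene_dip_depth * (
                    np.exp(-0.5 * (t / w) ** 2)
                    + np.exp(-0.5 * ((1 - t) / w) ** 2))
                level[body] = gene_b[ctx[body]] * shape
                level[left] = gene_b[ctx[left]]
                level[right] = gene_b[ctx[right]]
                if f.id in silenced:
                    down = right if f.strand == "+" else left
                    level[down] = level[down] * config.silenced_downstream_boost
                if cold:
                    for sl in (body, left, right):
                        level[sl] = level[sl] * gene_m[ctx[sl]]
            else:  # TE: single hump with exponentially decaying shoulders
                body_val = te_b * (te_m if cold else 1.0)
                ig_val = ig * (ig_m if cold else 1.0)
                level[body] = body_val[ctx[body]]
                d_left = f.start - pos[left]
                d_right = pos[right] - f.end + 1
                # shoulders are methylation spreading out of the TE: they
                # interpolate the condition-specific body and background
                # states, so near the TE they follow the body's cold response
                for sl, d in ((left, d_left), (right, d_right)):
                    level[sl] = (ig_val[ctx[sl]]
                                 + (body_val[ctx[sl]] - ig_val[ctx[sl]])
                                 * np.exp(-d / config.te_flank_decay))

        is_cg = ctx == 0
        target = (config.planted_level_treated if cold
                  else config.planted_level_control)
        for block in (b for b in planted if b.chrom == chrom):
            m = config.planted_margin
            b0, b1 = np.searchsorted(pos, [block.start, block.end])
            inside = slice(b0, b1)
            level[inside] = np.where(is_cg[inside], target, level[inside])
            for ms, me in ((block.start - m, block.start),
                           (block.end, block.end + m)):
                m0, m1 = np.searchsorted(pos, [ms, me])
                sl = slice(m0, m1)
                level[sl] = np.where(is_cg[sl], 0.0, level[sl])

        clipped = np.clip(level, 0.0, 1.0)
        clip_events += int((clipped != level).sum())
        out = group.copy()
        out["level"] = clipped
        frames.append(out)
    if clip_events:
        log.info("simulate_methylome/%s: clipped %d site levels into [0, 1]",
                 condition, clip_events)
    levels = pd.concat(frames, ignore_index=True) if frames else sites.copy()
    return levels, clip_events


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def simulate_counts(levels: pd.DataFrame,
                    fragments: dict[str, list[tuple[int, int]]],
                    config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Observed counts for sites inside retained fragments.

    Coverage is Poisson(coverage_mean); methylated reads are
    Binomial(n_total, level + (1 - level) * err).  Sites drawing zero
    coverage are not emitted.
    """
    inside = sites_in_fragments(levels, fragments)
    covered = levels[inside].reset_index(drop=True)
    n_total = rng.poisson(config.coverage_mean, size=len(covered))
    keep = n_total > 0
    covered = covered[keep].reset_index(drop=True)
    n_total = n_total[keep]
    err = config.conversion_error_rate
    p_obs = covered["level"].to_numpy() * (1 - err) + err
    n_meth = rng.binomial(n_total, p_obs)
    report = covered[["chrom", "pos", "strand", "context"]].copy()
    report["n_meth"] = n_meth
    report["n_total"] = n_total
    return report


# ---------------------------------------------------------------------------
# expression model
# ---------------------------------------------------------------------------

def simulate_expression(features: list[GenomicFeature],
                        promoter_genes: list[str], silenced: set[str],
                        config: SimulationConfig,
                        rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """DE table rows plus the truth labels for up-regulation.

    Genes whose promoter was demethylated under cold receive a log2
    fold-change drawn around the configured effect size; others draw null
    noise; silenced genes have zero expression throughout.  FDRs come from a
    generator-internal two-group t-test on simulated replicates (the
    pipeline never refits this model — the DE table is an input contract).
    """
    genes = [f for f in features if f.kind == "gene"]
    promoter = set(promoter_genes)
    effect = config.expression_effect_log2fc
    rows = []
    pvals = []
    truth: dict[str, bool] = {}
    for g in genes:
        if g.id in silenced:
            base, lfc, p = 0.0, 0.0, 1.0
            truth[g.id] = False
        else:
            base = float(rng.lognormal(config.expression_log_mu,
                                       config.expression_log_sigma))
            if g.id in promoter:
                lfc = float(rng.normal(effect, 0.3))
                truth[g.id] = effect != 0
            else:
                lfc = float(rng.normal(0.0, config.expression_null_sigma))
                truth[g.id] = False
            reps_c = np.log2(base) + rng.normal(
                0, config.expression_rep_sigma, config.n_replicates)
            reps_t = np.log2(base) + lfc + rng.normal(
                0, config.expression_rep_sigma, config.n_replicates)
            p = float(stats.ttest_ind(reps_t, reps_c).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((g.id, base, base * 2.0 ** lfc, lfc))
        pvals.append(p)
    fdr = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    table = pd.DataFrame(rows, columns=["gene_id", "level_control",
                                        "level_treated", "log2fc"])
    table["fdr"] = fdr
    return table, truth


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig,
                     null: bool = False) -> SimulatedDataset:
    """Generate one complete two-condition dataset with its truth record.

    With ``null=True`` the treated condition shares the control truth (no
    cold effect, planted blocks identical in both conditions, no expression
    effect); observation noise is still drawn independently — the
    configuration for calibration experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, features = simulate_genome(config, rng)
    fragments = mspI_digest(genome, config.fragment_size_min,
                            config.fragment_size_max)
    genes = [f for f in features if f.kind == "gene"]
    n_silenced = round(config.silenced_fraction * len(genes))
    silenced_idx = rng.permutation(len(genes))[:n_silenced]
    silenced = {genes[j].id for j in silenced_idx}
    planted = plant_blocks(features, silenced, config, rng)
    promoter_genes = [b.gene_id for b in planted if b.relation == "up2k"]

    sites = enumerate_cytosines(genome)
    levels_c, clips_c = simulate_methylome(genome, features, config, "control",
                                           planted, silenced, sites)
    if null:
        levels_t, clips_t = levels_c.copy(), 0
    else:
        levels_t, clips_t = simulate_methylome(genome, features, config,
                                               "cold", planted, silenced,
                                               sites)
    report_c = simulate_counts(levels_c, fragments, config, rng)
    report_t = simulate_counts(levels_t, fragments, config, rng)

    if null:
        null_cfg_effect = 0.0
        saved = config.expression_effect_log2fc
        config.expression_effect_log2fc = null_cfg_effect
        expression, de_truth = simulate_expression(features, promoter_genes,
                                                   silenced, config, rng)
        config.expression_effect_log2fc = saved
    else:
        expression, de_truth = simulate_expression(features, promoter_genes,
                                                   silenced, config, rng)

    truth = TruthRecord(planted=planted, promoter_genes=promoter_genes,
                        silenced_genes=sorted(silenced), de_truth=de_truth,
                        levels_control=levels_c, levels_treated=levels_t,
                        clip_events=clips_c + clips_t)
    return SimulatedDataset(config=config, genome=genome, features=features,
                            fragments=fragments, truth=truth,
                            report_control=report_c, report_treated=report_t,
                            expression=expression)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write FASTA, GFF3, the two cytosine reports, DE table and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.genome.to_fasta(outdir / "genome.fa")
    write_features_gff(dataset.features, outdir / "features.gff3")
    write_cytosine_report(sites_to_report(dataset.report_control),
                          outdir / "control.report.tsv")
    write_cytosine_report(sites_to_report(dataset.report_treated),
                          outdir / "cold.report.tsv")
    write_expression_table(dataset.expression, outdir / "expression.tsv")
    planted = pd.DataFrame(
        [(b.chrom, b.start, b.end, b.context, b.direction, b.gene_id or "",
          b.relation or "") for b in dataset.truth.planted],
        columns=["chrom", "start", "end", "context", "direction", "gene_id",
                 "relation"])
    planted.to_csv(outdir / "truth.planted.tsv", sep="\t", index=False)
    for name, levels in (("control", dataset.truth.levels_control),
                         ("cold", dataset.truth.levels_treated)):
        out = levels.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(outdir / f"truth.levels.{name}.tsv", sep="\t", index=False)
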