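# Methods

## Scope

The package analyses two-condition RRBS methylomes from per-cytosine count
tables onward. Read filtering, alignment, and differential-expression model
fitting are upstream of its scope: the cytosine report and the DE table are
input contracts. Internally all coordinates are 0-based half-open; 1-based
conventions exist only in the file dialects (GFF3, the cytosine report).

## Methylation calling

A cytosine's context is determined by the two bases immediately downstream
on its own strand: CG if the next base is G, CHG if the base after next is
G, otherwise CHH (H ∈ {A, T, C}). Sites with fewer than two downstream bases
or an N in the window have undefined context and are not called.

Unmethylated cytosines survive bisulfite conversion at a small failure rate
ε, so observed methylated reads at a truly unmethylated site follow
Binomial(n_total, ε). Each covered site is tested one-sided
(p = P(X ≥ n_meth)); Benjamini–Hochberg correction runs over all tested
sites jointly, and a site is called methylated when q ≤ α and n_meth ≥ 1.

* `conversion_error_rate` — ε, default 0.005. A typical bisulfite
  non-conversion rate; the package has no spike-in control data from which
  to estimate it, so it is a config key.
* `fdr_alpha` — default 0.05.
* `level_weighting` — aggregate levels are read-weighted
  (Σ n_meth / Σ n_total) by default; an unweighted per-site mean
  (`site_mean`) is selectable wherever levels are aggregated, because
  "average methylation" is ambiguous between the two conventions.
* Sites with zero coverage are excluded from calling and every summary.

The one-sided binomial test is conservative at small ε because the test
statistic is discrete: at coverage 20 and ε = 0.005 a single methylated read
gives p ≈ 0.095, so the realized null rejection rate at p ≤ 0.05 is far
below 0.05. The acceptance script measures this.

Genome-wide summary percentages use largest-remainder rounding at two
decimals so the three context percentages sum to exactly 100.00 — the
convention that reproduces published summary tables of this kind, which
per-entry rounding does not (it can sum to 100.01).

## DMR detection

Within one context, the caller seeds maximal chains of sites called
methylated in at least one sample, splitting wherever adjacent seeds are
200 bp or more apart (`dmr_max_gap`, the criterion is "< 200 bp"). A chain
becomes a DMR when all of the following hold (every bound a config key):

1. more than `dmr_min_mc` = 5 methylated cytosines in at least one sample,
   where a member counts as a methylated cytosine only if its calling
   verdict is positive **and** it carries more than `dmr_min_meth_reads` = 4
   methylated reads in that sample;
2. every member cytosine has more than `dmr_min_cov` = 10 reads in both
   samples — a member lacking coverage in either sample disqualifies the
   region (conservative and deterministic, rather than silently dropping
   the member);
3. span within [`dmr_min_len` = 40 bp, `dmr_max_len` = 10 kb], inclusive;
4. (the seeding rule above);
5. fold change of the two read-weighted mean levels strictly above
   `dmr_min_fold` = 2 (one mean zero and the other positive counts as
   infinite fold; both zero as fold 1);
6. Pearson chi-square on the pooled 2×2 read counts (meth/unmeth × sample),
   1 df, no continuity correction, p ≤ `dmr_max_p` = 0.05, inclusive.

Design choices that were genuinely open:

* The "more than five / more than ten / more than four" wordings are
  implemented as strict inequalities; each is a config key so the ≥
  readings are one override away.
* The >4-methylated-reads clause is part of the *definition* of a
  methylated cytosine rather than a veto on the region. Under the veto
  reading, any region containing one weakly methylated site (2–4 methylated
  reads — routinely produced by a truly low-level site at moderate
  coverage) could never be a DMR, which would make hypo-methylated regions
  with residual 10% methylation systematically undetectable. The
  qualification reading matches the conventional role of such read bounds
  in methylation callers: they gate which sites count, not which regions
  survive.
* The chi-square is computed on pooled read counts, not per-site levels.
* Direction is relative to the control sample: "hyper" means the treated
  sample is higher.
* No multiple-testing correction across regions is applied.

Annotation links a DMR to every gene/TE it overlaps by at least one base
pair, either in the body or in the strand-aware 2-kb flanks (body takes
precedence).

## Profiles

Metagene profiles use 20 fixed 100-bp bins per 2-kb flank and 40
length-scaled body bins (`flank_bins`, `body_bins`, `flank_bp`), ordered
5′→3′ in the feature's orientation; the division remainder goes to the
5′-most body bins. Bin levels are read-weighted by default. A site falling
into the windows of several overlapping features contributes to each
independently (metagene-averaging convention); within one feature no bin
double-counts a site. Transcription start/termination are taken to be the
body boundaries — the annotations in scope carry no finer TSS information.
Region summaries cover gene body, the 2-kb flanks, exon, intron
(= body minus the exon union), CDS and UTRs.

## Logos

For each class (context × verdict) the 10 bases around the site are
collected with the focal cytosine at the fifth position; minus-strand
windows are reverse-complemented. "Unmethylated" means covered-but-negative
verdict, not uncovered. Information content is 2 + Σ p·log2 p bits per
column, without small-sample correction by default
(`ic_small_sample_correction` enables the 3/(2·ln2·n) first-order term).
Classes are compared column-wise with a chi-square homogeneity test on the
two columns' base counts. No subsampling is applied.

## Integration

DEGs are rows of the input DE table with FDR strictly below
`deg_fdr_threshold` = 0.05. (Published analyses of this kind sometimes
quote a stricter FDR < 0.001 in results while stating 0.05 in methods; the
threshold is a config key, defaulting to the methods value.)

A DMP — a differentially methylated position, needed for the
"DMP-by-DEG" correlation subset but not otherwise defined in the
literature this package follows — is a cytosine with more than
`dmp_min_cov` = 10 reads in both samples, |level difference| ≥
`dmp_min_delta` = 0.1, and two-sided Fisher exact p ≤ `dmp_max_p` = 0.05 on
its 2×2 read counts: the minimal per-site analogue of the regional
criteria. The Fisher test is evaluated vectorized through the
hypergeometric log-pmf (exactly the scipy two-sided definition; the test
suite checks agreement to 1e-9).

Methylation–expression correlations are Spearman rank correlations (scipy,
tie-corrected) per (region, context) across genes, between the methylation
log2 fold change of the region (with a 0.01 pseudo-level so unmethylated
regions stay finite) and the expression log2 fold change. Both axes being
fold changes matters: under global demethylation the *absolute* methylation
loss of a specifically demethylated promoter can equal the genome-wide
shift, while its *relative* loss stands out. Expression strata are the
zero-expression genes ("none") plus tertiles of the nonzero genes, sorted
deterministically by (level, gene id), remainders going to the lower
strata. The correlated-gene set is DEGs ∩ genes carrying ≥ 1 linked DMR —
a stated proxy for "expression correlated with methylation change", not a
claim of equivalence with any visual-inspection count.

## The synthetic-data generator

The generator emulates the statistical structure of a cold-stress RRBS
experiment; its defaults are the package's study conditions.

**Sequence.** `n_contigs` = 2 × 500 kb at GC 0.40, with CCGG motifs
injected at truncated-normal spacing (mean 100 bp, sd 25, clipped into the
40–220 bp size window). The simulated sequence therefore models the
MspI-enriched, CG-dense genome *fraction* that RRBS actually samples — not
a whole plant genome (which would be AT-richer and mostly invisible after
size selection). With this spacing essentially every fragment survives the
in-silico C^CGG digest and 40–220 bp selection, so the retained fragments
tile the sequence; an exponential-spacing model was rejected because its
heavy tail leaves ~6% of fragments over-length, punching coverage holes
that make planted signal invisible and fragmenting candidate regions into
short, noisy chains.

**Annotation.** 40 genes (2–5 kb, with exon/intron/CDS/UTR layouts) and 20
TEs (1–3 kb), alternating across contigs with at least 4 kb between bodies
so 2-kb flanks never overlap a neighboring body.

**True methylation.** Baselines per context: genes CG/CHG/CHH =
0.60/0.35/0.15, TEs 0.85/0.60/0.30, intergenic 0.02. Gene bodies are
multiplied by a "W" shape — Gaussian dips (depth 0.6 of baseline, width
0.08 of body length) at both body edges — with flanks at the genic
plateau, giving minima at the transcription boundaries. TE shoulders decay
exponentially (300 bp scale) from the body level toward intergenic. Cold
multiplies genic and intergenic levels by 0.6 in all contexts, TE-body CHG
and CHH by 0.7, and TE-body CG by 1.05 — the "slight increase" is a stated
invention for testing; only its sign is anchored. TE shoulders interpolate
between the condition-specific body and intergenic endpoints, since they
represent methylation spreading out of the TE and must follow the body's
cold response near the boundary. A `silenced_fraction` = 0.15 of genes has
zero expression and doubled downstream-flank methylation (clipped at 1;
clip events are logged), giving the no-expression stratum its elevated
downstream signal.

**Planted DMRs.** 10 hypo-CG blocks of 200–800 bp, levels 0.8 (control) →
0.1 (cold); half sit in gene promoters (and drive the expression effect),
half mid-body in distinct genes. Each block carries a 600-bp CG-unmethylated
margin on both sides so the < 200 bp chaining rule reliably separates the
block from background methylation: recovery then measures the caller, not
chance chaining. The margin is three times the chaining gap because a
single spurious conversion-error call cannot bridge more than twice the
gap, and three simultaneous spurious calls in one margin are vanishingly
rare.

**Observation model.** For each cytosine inside a retained fragment,
coverage ~ Poisson(30) and methylated reads ~ Binomial(n, level +
(1−level)·ε) with ε = 0.005 — failed conversion is the only error mode; no
sequencing miscalls, no fragment-level read simulation (counts suffice for
every downstream stage). Sites drawing zero coverage are not emitted.

**Expression.** Baselines are log-normal (ln-scale mean 2, sd 1); genes
with a planted promoter block draw log2FC ~ N(+2, 0.3), others N(0, 0.2),
silenced genes stay at zero. FDRs come from a generator-internal two-group
t-test on three simulated replicates per condition (log2 noise sd 0.25)
with BH correction — the pipeline never refits this model.

Everything is deterministic given the seed, and the truth record (per-site
levels per condition, planted blocks, promoter-linked and silenced genes,
DE labels) is emitted with the data.

**What passing tests do and do not show.** The generator reproduces the
*statistical shape* of an RRBS cold-stress experiment: context-dependent
levels, positional profiles, a global shift with one opposing TE effect, a
planted monotone promoter–expression link. It does not model realistic
sequence composition, CpG-island structure, read-level artifacts (mapping
bias, PCR duplicates, strand imbalance), biological replicate variation
(each condition is a single pooled sample, as in the emulated design), or
any genome-scale correlation structure beyond the planted one. Green tests
demonstrate that the pipeline recovers known truth under its stated noise
model — not that the biological conclusions would replicate on real data.

## Numerical and degenerate-input conventions

* Binomial tails via the survival function; ε = 0 puts all mass at zero, so
  any methylated read is certain evidence.
* Chi-square tables with a zero methylated/unmethylated column are treated
  as identical proportions (chi2 = 0, p = 1); a zero row (no reads in one
  sample) rejects the region with a logged reason.
* Fold change max/min with min = 0 is infinite (passes criterion 5), both
  zero is 1.
* Spearman is undefined (NaN, warning) below n = 3 or at zero variance.
* Empty bins, empty strata, and empty alignments are skipped with warnings;
  empty candidate collections propagate as empty results, never errors.
* Every filtering stage logs records-in/records-out for auditability.

## Problem sizes

The standard scenario (1 Mb genome, ~200,000 covered sites per condition)
runs the full simulate–call–DMR–profile–integrate pipeline in a few seconds
on one core; the acceptance script, which also runs a 50,000-site
calibration, a null dataset, and two 1,000-case oracle sweeps, completes in
well under a minute. These sizes were chosen so the complete evidence for
the package can be regenerated interactively.
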