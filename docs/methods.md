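# Methods

## Coordinate and sequence conventions

All genomic coordinates are 1-based inclusive (the GTF convention), so a
feature on `chr3:115,636,959–115,641,530` has a genomic span of
`end − start + 1 = 4572` bp. The mature transcript length is the sum of
exon lengths. Transcripts must be stranded (`+`/`-`): positional
classification is strand-aware and strandless exon records are rejected at
parse time. Sequences are accepted in DNA or RNA alphabet; seed matching
runs in RNA space (`T→U`) and open-reading-frame scanning in the same
normalized space. Both conversions are lossless.

## lncRNA discovery

A novel transcript becomes a candidate when (i) it is absent from the
reference annotation, (ii) its mature length is strictly greater than
200 nt, and (iii) it has at least `min_exons` exons. The exon criterion
defaults to 2 (the community multi-exon convention); the stricter ≥ 3
reading is a parameter. Coding potential is decided by consensus: four
predictor verdicts (CPC-, CNCI-, CPAT- and Pfam-style, the last meaning
"no protein-domain hit") must all be `noncoding`. Consensus is monotone —
flipping any verdict to `coding` can only remove candidates. Transcripts
with incomplete verdict sets are reported separately, never silently
dropped.

Positional classes are assigned by precedence — **sense** (any same-strand
exon–exon overlap with a reference transcript), else **intronic** (entirely
within a single intron of a same-strand reference transcript), else
**antisense** (any opposite-strand overlap with a reference transcript's
extent), else **lincRNA**. The precedence order resolves the rare
ambiguities (e.g. a transcript overlapping an exon and dipping into an
intron) in favour of the stronger, exon-level evidence. Classification is
total and mutually exclusive by construction. Composition percentages are
rounded half-up to one decimal.

The built-in three-frame ORF screen is a deliberately transparent fallback
for the four predictors, not a reimplementation of them: it reports the
longest AUG…stop ORF per forward frame (stop codon included) and flags a
transcript as coding-suspect above a threshold (default 300 nt, the classic
100-codon heuristic). Ambiguity codes are rejected rather than guessed.

## Differential expression

FPKM is `counts / (length_kb × totals/10⁶)`. The DE caller is an explicit
stand-in for a DESeq2-style analysis and is isolated behind one function so
an external DE table can be dropped in:

* size factors by median-of-ratios, genes with any zero count excluded from
  the geometric reference;
* fold change `log2((μ_B + c)/(μ_A + c))` on normalized counts, pseudocount
  `c = 0.5`;
* per-gene dispersion α (variance `μ + αμ²`) by method of moments, pooled
  across the two groups, floored at 10⁻⁸;
* Wald statistic `log(FC)/SE` with `SE² = (1/μ_A + α)/n_A + (1/μ_B + α)/n_B`,
  referred to a **t distribution with n_A + n_B − 1 degrees of freedom**.

The t reference is the package's small-sample calibration choice: with
n = 3 per group a normal reference rejects ~11% of null genes at p < 0.05,
while n_A + n_B − 2 degrees of freedom is conservative and (because its
heavy tail floors attainable p-values) collapses power after BH adjustment.
Null simulations across dispersions 0.01–0.1 show n_A + n_B − 1 holds the
nominal 5% level at the generator's default dispersion while retaining
> 95% sensitivity for planted |log2FC| = 3 effects. All-zero genes return
`log2FC = 0, p = 1`. "Adjusted p-value" means Benjamini–Hochberg
(step-up), computed via `statsmodels`. Significance thresholds are strict
(`|log2FC| > 2`, `p_adj < 0.05` for lncRNAs; threshold 1 for mRNA DEGs).

The heatmap transform is `log10(FPKM + 10⁻⁶)` followed by per-row z-scoring
(sample standard deviation); constant rows map to zeros instead of NaN.

## Knockout screen

The two ratio statistics are computed on group-mean FPKM over replicates
(the formulas are defined on group values, not per-replicate). Degenerate
cases: `r_diff` with a zero WT difference returns a signed-infinity
sentinel (+∞ satisfies "> 2", −∞ and any negative value satisfy "< 0.5",
0/0 is NaN and satisfies neither); `r_fc` adds a pseudocount ε (default
0.01 FPKM) to every term, and a zero denominator at ε = 0 is an error
instructing a nonzero ε. `r_diff` uses raw differences because an additive
ε cancels there. Selection requires **both** statistics outside
[0.5, 2] — the conjunction, with strict inequalities.

Low-count removal follows the literal reading "fewer than five total reads
in each group": a gene is removed only when all four groups are below the
cutoff; the stricter any-group variant is a configuration switch.

Survivors are clustered on the heatmap transform with Euclidean distance
and complete linkage (pheatmap's defaults), the tree cut at k = 3, and
classes named I/II/III by descending size with ties broken by the
lexicographically smallest member id.

## ceRNA seed matching

Canonical seed-site classes on the target sense strand: every site is
anchored at its 6-nt seed-match core (reverse complement of miRNA positions
2–7); the flanking bases decide the class (8mer = m8 pair + 3′-A anchor >
7mer-m8 > 7mer-A1 > 6mer), and only the highest-priority class is reported
per core locus while distinct loci may overlap. Matching is strict
Watson–Crick — no G:U wobble — the conservative default, and intentionally
transparent: every reported site is verifiable by direct string
complementarity, unlike trained target predictors whose scores cannot be
audited locally. Consequently sponge-candidate counts on synthetic panels
emulate the structure, not the identity, of database predictions on real
sequences. Sponge candidates are panel members with at least `min_sites`
sites on both targets. Site deletion excises spans, returns an
old→new coordinate map, and the audit splits any residual matches into
sites away from the deletions versus junction-created sites (reported with
a warning).

## Synthetic data

The generators produce the statistical structure the analyses assume, with
every planted attribute recorded in a truth table; fixed seed (default
20369) means byte-identical outputs.

* **Annotation**: 20 reference genes (three 400-nt exons, 1400-nt introns)
  spaced 50 kb apart on a toy chromosome; 4 novel transcripts per
  positional class planted by construction (intergenic placement, intron
  containment, opposite-strand overlap, same-strand exon overlap) plus two
  deliberate filter failures (150 nt; single-exon).
* **Time course** (0/2/8/24 h, n = 3): negative-binomial counts,
  `variance = μ + αμ²`, dispersion default α = 0.05, baselines log-normal
  (median 100). One designated lncRNA follows a peak-at-2 h profile
  (1, 16, 4, 2 relative to baseline); 100 other genes get a ±4 log2FC shift
  at one random later timepoint.
* **KO screen**: 5000 background genes with both ratios planted in
  [0.8, 1.25]; 53 regulated genes split across three archetypes whose
  planted ratios clear the selection band by ≥ 4× or ≤ 0.25 (KO
  hyper-induced; KO repressed; WT-induced/KO-flat — the archetype
  multipliers were chosen so no planted ratio sits within replicate-noise
  reach of a threshold); 200 low-count genes below 5 reads in every group.
  Replicate noise is multiplicative log-normal (sd 0.05); transcripts are
  1 kb at 10⁶ depth so one count equals one FPKM unit.
* **ceRNA panel**: 10 random 22-nt miRNAs with mutually non-colliding
  seeds; 6 dual binders (8mer sites planted on both a 1000-nt lncRNA and a
  600-nt 3′UTR), the featured one with two sites per target; two members
  bind only the lncRNA and two bind neither. Background sequence is
  scrubbed of accidental seed cores before planting, and a post-hoc audit
  of what the matcher finds is stored in the truth table, so planted and
  recoverable sites coincide for any seed.

What the synthetic data does *not* emulate: real genome sequence
composition, gene-length and GC biases, library-size variation,
overdispersion trends in depth, correlated genes, or the behaviour of
trained coding-potential and target-prediction models. Passing recovery
tests therefore demonstrates correctness of the implemented rules and
calibration of the statistics under their stated assumptions — not
real-data performance of the upstream tools the inputs emulate.

## Problem sizes and determinism

The bundled checks run at the generator defaults: a 5253-gene screen,
10,000-gene null and sensitivity simulations, 1000 random seed-matcher and
BH instances, and 100 annotation replicates — sizes at which Monte-Carlo
error is small (binomial s.e. ≈ 0.002 on the null rejection rate) while a
full run stays in the tens of seconds. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; the acceptance
script derives independent substreams per check via `SeedSequence.spawn`.

## Known limitations

* The NB Wald stand-in has no dispersion shrinkage or outlier handling;
  with fewer than three replicates per group it refuses to run rather than
  produce unstable moment estimates.
* The screen's ratio statistics are point estimates on group means and
  carry no significance measure; genes near the 2 / 0.5 boundaries are
  sensitive to replicate noise (hence the ε conventions above).
* Seed matching ignores binding thermodynamics, site context and
  conservation; it bounds the candidate set rather than ranking it.
* The interval index is strand-filtered per query, not per-tree; for very
  large annotations a strand-partitioned index would be faster.
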