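# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter when reproducing output.

## Differential expression from tag counts

The expression model treats each library as a multinomial draw over
genes: the observed tag count xᵢ for gene g is proportional to the
gene's share of the library. Normalization divides by the same-library
count of a designated reference gene, which cancels library-composition
shifts exactly (any constant rescaling of one library's counts leaves
normalized ratios unchanged; this is a tested property). The fold change
is symmetric (max(r, 1/r)) with a direction label; genes with a zero
count in either condition get a 0.5 pseudocount in both conditions
before the ratio, which keeps folds finite while preserving ordering.

No formula is standard for a z statistic on a pair of single-library tag
counts; the pooled two-proportion z on library fractions is the
conventional serial-tag-count statistic and is fully determined by the
four numbers involved, so it is the one implemented (the pooled form is
also what `statsmodels.proportions_ztest` computes, which the tests use
as an independent oracle). z is defined as 0 when both counts are zero.
The filters follow the stated conventions exactly: fold bins compare
with ≥, the z gate and expression floor are strict (>). The floor is
applied to the control condition only; `absolute` mode (100 tags) is the
default and `fraction` mode (0.06 % of the marker gene's control tags,
158,000 × 0.0006 = 94.8) is a configuration switch, because the two
renderings of the floor differ slightly and the absolute reading is the
more conservative.

## Peak calling

The caller is deliberately minimal: binned coverage (10 bp bins),
candidate bins where treatment > fold_min × depth-scaled input, merging
across gaps of at most one bin, and a Poisson gate at the summit bin.
λ is the scaled input at the summit floored at the genome-wide scaled
input mean — the standard safeguard against calling against a locally
empty input. Summit ties break leftmost; all coordinates are 0-based
half-open; intervals narrower than `min_span` (50 bp) are discarded.
Defaults follow the analysis conventions of the domain: fold_min 2.0 and
p_max 1e-5 (1e-8 is the appropriate choice for deeper or noisier
material; both are plain parameters).

Count monotonicity in the gates (tightening fold_min or p_max never
yields more peaks) holds for unimodal enrichment profiles and is tested
there. It cannot hold universally for *any* threshold-merge caller: a
noisy plateau that straddles the gate fragments into several intervals
as the gate rises. This is a known, documented limitation rather than a
defect of this particular implementation.

## Annotation

Summit position — never interval overlap — decides membership
everywhere, so the location distribution, the gene assignment, and the
motif analysis share one basis and no peak is double-counted. Location
windows are strand-aware and evaluated with the precedence promoter →
gene body (exon/intron) → TES window, which matters only for genes
shorter than the combined window spans; promoter dominance is the
conventional choice. The exon/intron split inside gene bodies is a
refinement this module adds; consumers that only need the classic
categories can merge the two. For the genome-wide distribution each peak
is classified against its nearest gene (smallest absolute distance from
summit to transcript span, ties to the lexicographically smaller
gene id); for per-gene tallies a peak counts once for every gene whose
span ± 50 Kb contains its summit, since association windows overlap.

## Motif scanning and discovery

The dimer element is arm + spacer + reverse-complement(arm). Because
that structure equals its own reverse complement, a forward scan of the
sequence finds every genomic locus once; on the minus strand the same
locus appears with the two arms' mismatch counts swapped, which the
per-arm mismatch budget makes equivalent. N never matches. The default
mismatch budget is 0 for fixture-grade checks and 1 per arm is the
recommended setting for genome-scale scans of real data (near-canonical
arms dominate real binding sites).

Discovery replaces an external motif finder with exhaustive enumeration:
the 4⁶/2 reverse-complement-collapsed arms × spacers 3–5 (or all
contiguous k-mers) are scored by presence/absence support across
windows, against expected support from dinucleotide-preserving shuffles
(Altschul–Erickson edge shuffling, seeded), ranked by binomial
upper-tail p-value then log₂ enrichment. A +0.5 pseudo-count on shuffle
support keeps motifs never seen in the background at finite enrichment.
k-mer results optionally merge pairs differing at one position into an
IUPAC consensus when the pooled support lowers the binomial p-value.
Windows are summit ± 100 bp (201 bp scanned; a pattern must lie wholly
inside the window), reading "within 100 bp on either side of the top of
the peak" literally.

## Synthetic data

The generator emulates the *shape* of the study's inputs at desk scale:
a two-chromosome 200 kb-per-chromosome genome at GC 0.42, 30 genes with
exon structure and functional-category labels, one β-actin-like
reference (expected 30,000 control tags) and one Col2a1-like marker
(expected 158,000 control tags, the highest in the table), libraries of
2 × 10⁶ tags drawn multinomially, planted fold changes at levels
2/3/4/6/8 in both directions (two genes per level per direction), 20
enrichment peaks at 5-fold over a Poisson input background, and a
planted canonical dimer near 74.2 % of summits.

Three generator choices deserve explanation:

- **Planted folds are bin targets.** A gene planted at an expression
  ratio of exactly 8.0 would fall below the ≥ 8 bin in roughly half of
  all draws, making "recovery" a coin flip by construction. Planted
  genes therefore carry a ratio of level × 1.15 (recorded exactly in the
  ground truth), and their baseline expression is floored at 0.1 % of
  the library (~2,000 control tags) so the fold is quantifiable — the
  same reason the analysis itself applies a 100-tag floor. With those
  counts the sampling SD of the log fold is ≈ 0.07, so a planted gene
  sits > 2 SD inside its bin.
- **Peaks are Gaussian bumps, not plateaus.** The treatment rate is
  λ(1 + (fold−1)·exp(−(x−s)²/2σ²)) with σ = 25 bp over a 500 bp
  footprint. A flat plateau has no identifiable summit; the bump makes
  the true summit the coverage mode, as fragment pileups around a point
  source are in real data.
- **Input depth 100 tags per 10 bp bin.** The study does not state its
  input depth, so it is a free parameter. Summit localization to ± 1 bin
  requires the summit bin's expected count to dominate its neighbours by
  several Poisson SDs; at λ = 100 the summit bin expects ~500 tags and
  bins two away sit ~4 SD lower, giving > 99 % localization, whereas at
  λ = 10 localization is statistically impossible at that precision.
  Recovery (not localization) is additionally verified at λ = 10, where
  it still exceeds 95 %.

Motif flags are deterministic — the first ⌊fraction · n⌋ peaks in
coordinate order — so fixtures hit printed numerators exactly, and
chance occurrences of the canonical dimer near unflagged summits are
scrubbed (one arm base mutated) so the recorded flags agree with the
scanner by construction, at any seed.

What the generator does **not** emulate: read-level sequencing (FASTQ,
alignment, duplicates), biological dispersion beyond multinomial
sampling (no overdispersion between replicates — the design has none),
repeat structure and mappability of real genomes, correlated peak/gene
placement (peaks land uniformly, not preferentially at promoters), and
degenerate motif variants (planted dimers are exact-consensus). Passing
recovery tests therefore demonstrates correctness of the pipeline's
logic under its stated sampling model, not performance on real
libraries.

## Determinism and numerics

All randomness flows from a single integer seed through per-stage
`numpy` SeedSequences, so every artifact is byte-identical across reruns
and independent of Python's hash randomization (set iterations feeding
RNG consumption are sorted). Percentages round half-up to one decimal
via `decimal.Decimal` (banker's rounding would turn 6.25 into 6.2).
Poisson tails use `scipy.stats.poisson.sf`; tests check them against
direct pmf summation. Test problem sizes (30-gene tables, 400 kb
genomes, 500 scan windows, 20-seed calibration loops) were chosen as the
smallest sizes at which the calibration statements have power; the whole
suite runs in well under a minute.

## Known limitations

Single-replicate design throughout (no dispersion estimation, no FDR);
the caller has no fragment-shift model and a single background scale;
annotation is gene-span based, not isoform-aware; discovery enumerates
exact arms/k-mers and will summarize—not align—families of degenerate
sites; species-overlap comparison assumes symbol-keyed identity between
annotation spaces.
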