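# soxtarget

SOX9 is the master transcription factor of chondrocyte (cartilage cell)
differentiation: it binds DNA as a homodimer on an inverted-repeat element
and activates the extracellular-matrix program of cartilage. `soxtarget`
is a small, fully tested pipeline for asking which genes SOX9 (or any
factor with a dimeric binding element) regulates *directly*: it combines
two-condition RNA-Seq tag counts (factor depleted vs control) with
ChIP-Seq-style binding peaks and reports, per fold-change bin, the
fraction of regulated genes that carry a binding site near the gene.

It is aimed at computational biologists who want a transparent,
desk-scale reimplementation of this classic integration analysis, with a
seeded synthetic-data generator standing in for raw sequencing data so
every step can be validated against known ground truth.

## The analysis

**Differential expression from tag counts.** Per-gene tag counts in two
libraries are normalized to a stable reference gene (β-actin-like):
x̃ᵢ = xᵢ / x_ref per condition. The symmetric fold change is
max(r, 1/r) for r = x̃_treated / x̃_control. Significance uses the pooled
two-proportion z statistic on library fractions p̂ᵢ = xᵢ/nᵢ:

    z = (p̂₁ − p̂₂) / √( p̄(1−p̄)(1/n₁ + 1/n₂) ),   p̄ = (x₁+x₂)/(n₁+n₂)

Genes pass with |z| > 4.0 and a control-condition expression floor
(> 100 tags by default, or > 0.06 % of a Col2a1-like marker gene's
control tags). Surviving genes enter nested fold bins (≥2, ≥3, ≥4, ≥6,
≥8) per direction.

**Peak calling.** A minimal binned caller: bins where treatment coverage
exceeds `fold_min` × library-scaled input are merged (gaps ≤ one bin);
each interval's summit is its maximum-coverage bin center; the interval
is kept if the summit-bin count t has Poisson upper-tail probability
P(X ≥ t | λ) < `p_max`, with λ the scaled input at the summit floored at
the genome-wide scaled input mean.

**Annotation.** Each summit is classified against strand-aware windows —
upstream (−50 to −5 Kb of TSS), promoter (−5 to +0.5 Kb of TSS),
exon/intron (gene body), TES window (−0.5 to +5 Kb of TES), downstream
(+5 to +50 Kb of TES), else distant — and peaks are assigned to every
gene whose span ± 50 Kb contains the summit.

**Motif analysis.** Summit ± 100 bp windows are scanned for the SOX9
dimer element ACAAAG-N₄-CTTTGT (a 6-bp arm, 4-bp spacer, and the arm's
reverse complement; the structure is its own reverse complement, so one
forward scan covers both strands). Discovery enumerates all 4⁶ arms ×
spacers (and contiguous k-mers) against dinucleotide-preserving shuffled
backgrounds, ranking by binomial upper-tail p-value.

**Integration.** For each fold bin, the cross-tabulation reports how many
member genes have ≥ 1 assigned peak, with percentages rounded half-up to
one decimal.

## Worked example

```python
import soxtarget as st

bundle = st.run_all(st.SyntheticConfig(seed=1))
print(len(bundle["peaks"]), bundle["motif_fraction"])
print(bundle["crosstab"].head(3).to_string(index=False))
```

prints

```
20 0.7
direction  fold_threshold  n_genes  n_with_sites   pct
 decrease             2.0       10            10 100.0
 decrease             3.0        8             8 100.0
 decrease             4.0        6             6 100.0
```

All 20 planted peaks are recovered, 14 of 20 (70 %) carry the planted
dimer (⌊0.742 × 20⌋ = 14 by the generator's deterministic flag rule),
and every gene planted with a ≥ 2-fold change is both detected and —
on this dense toy genome — within 50 Kb of a peak, so each nested bin
shows 2 genes per direction per planted level with 100 % binding. A
planted fold-8 decrease gene (`g0018`) shows 6277 control vs 335 treated
tags: a normalized 9.8-fold decrease with z ≈ 73.

The same pipeline is available from the shell:

```sh
soxtarget simulate --out sim/ --seed 3
soxtarget de --counts sim/counts.tsv --reference g0000 --marker g0001 --out de.tsv
soxtarget callpeaks --treat sim/treatment.bdg --input sim/input.bdg --out peaks.bed
soxtarget annotate --peaks peaks.bed --genes sim/genes.bed12 --out ann/
soxtarget motif scan --genome sim/genome.fa --peaks peaks.bed --out hits.tsv
soxtarget run-all --out results/ --seed 1
```

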