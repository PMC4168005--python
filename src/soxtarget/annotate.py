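"""Peak-to-gene annotation.

Classifies each peak summit relative to gene models using strand-aware
coordinate windows (upstream −50 to −5 Kb of the TSS, promoter −5 to
+0.5 Kb of the TSS, gene body split into exon/intron, a −0.5 to +5 Kb
window around the TES, downstream +5 to +50 Kb of the TES, and distant
otherwise) and assigns peaks to every gene whose ±50 Kb association
window contains the summit.  Membership is decided by the summit alone,
never by interval overlap, so a peak is counted on one basis throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, LocationCall, Peak

DEFAULT_FLANK = 50_000

# strand-aware window edges, in transcribed-orientation bp
UPSTREAM_FAR = 50_000
UPSTREAM_NEAR = 5_000
PROMOTER_DOWN = 500
TES_UP = 500
TES_DOWN = 5_000
DOWNSTREAM_FAR = 50_000


def classify_location(summit: int, gene: GeneModel, chrom: str | None = None) -> str:
    """Category of a summit relative to one gene.

    Distances are measured in the direction of transcription from the TSS
    and TES anchors.  Precedence for overlapping windows of short genes:
    promoter, then gene body (exon/intron), then the TES window.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"summit chromosome {chrom!r} does not match gene on {gene.chrom!r}"
        )
    sign = 1 if gene.strand == "+" else -1
    d_tss = sign * (summit - gene.tss)
    d_tes = sign * (summit - gene.tes)

    if -UPSTREAM_NEAR <= d_tss < PROMOTER_DOWN:
        return "promoter"
    in_body = gene.tx_start <= summit < gene.tx_end
    if in_body and d_tss >= PROMOTER_DOWN and d_tes < -TES_UP:
        return "exon" if gene.contains_in_exon(summit) else "intron"
    if -TES_UP <= d_tes < TES_DOWN:
        return "TES_window"
    if -UPSTREAM_FAR <= d_tss < -UPSTREAM_NEAR:
        return "upstream"
    if TES_DOWN <= d_tes < DOWNSTREAM_FAR:
        return "downstream"
    return "distant"


def _span_distance(summit: int, gene: GeneModel) -> int:
    """Signed genomic distance from the summit to the transcript span.

    Zero inside the span, negative 5' of tx_start, positive 3' of tx_end
    (genomic coordinates, strand-independent).
    """
    if summit < gene.tx_start:
        return summit - gene.tx_start
    if summit >= gene.tx_end:
        return summit - (gene.tx_end - 1)
    return 0


@dataclass
class GenePeakAssignment:
    """Peaks assigned to genes by summit containment in ±flank windows."""

    flank: int
    gene_to_peaks: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    peak_to_genes: dict[str, list[str]] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def genes_with_peaks(self) -> set[str]:
        return {g for g, pks in self.gene_to_peaks.items() if pks}


def assign_peaks_to_genes(
    peaks: list[Peak],
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> GenePeakAssignment:
    """Assign each peak to every gene whose ±flank window holds its summit.

    The window is ``[tx_start − flank, tx_end + flank)`` in genomic
    coordinates, so a peak between two close genes is assigned to both.
    Peaks within no window are collected in ``unassigned``.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for gene in genes:
        by_id[gene.gene_id] = gene
        tree = trees.setdefault(gene.chrom, IntervalTree())
        lo = max(0, gene.tx_start - flank)
        tree.addi(lo, gene.tx_end + flank, gene.gene_id)

    assignment = GenePeakAssignment(flank=flank)
    assignment.gene_to_peaks = {g.gene_id: [] for g in genes}
    for pk in peaks:
        tree = trees.get(pk.chrom)
        hits = sorted(iv.data for iv in tree[pk.summit]) if tree else []
        assignment.peak_to_genes[pk.peak_id] = hits
        if not hits:
            assignment.unassigned.append(pk.peak_id)
            continue
        for gid in hits:
            dist = _span_distance(pk.summit, by_id[gid])
            assignment.gene_to_peaks[gid].append((pk.peak_id, dist))
    return assignment


def classify_peaks(
    peaks: list[Peak],
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[LocationCall]:
    """One location call per peak against its nearest gene.

    The nearest gene is the one with the smallest absolute summit-to-span
    distance (ties broken by lexicographically smaller gene_id), so each
    peak contributes exactly once to the genome-wide location
    distribution.  Peaks farther than ``flank`` from every gene are
    called distant with no gene.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)

    calls: list[LocationCall] = []
    for pk in peaks:
        candidates = by_chrom.get(pk.chrom, [])
        best: GeneModel | None = None
        best_key: tuple[int, str] | None = None
        for gene in candidates:
            key = (abs(_span_distance(pk.summit, gene)), gene.gene_id)
            if best_key is None or key < best_key:
                best, best_key = gene, key
        if best is None or best_key[0] > flank:
            calls.append(LocationCall(pk.peak_id, None, "distant"))
            continue
        category = classify_location(pk.summit, best, chrom=pk.chrom)
        gid = None if category == "distant" else best.gene_id
        calls.append(LocationCall(pk.peak_id, gid, category))
    return calls


def location_distribution(calls: list[LocationCall]) -> pd.DataFrame:
    """Counts and fractions per location category.

    Fractions sum to 1 over the categories present; an empty input yields
    an empty table.
    """
    if not calls:
        return pd.DataFrame(columns=["category", "count", "fraction"])
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
    total = len(calls)
    rows = [
        {"category": cat, "count": n, "fraction": n / total}
        for cat, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
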