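"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout; BED emission keeps that
convention and FASTA extraction converts as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with exon structure and functional-category labels.

    The transcription start site (TSS) is ``tx_start`` on the + strand and
    ``tx_end - 1`` on the − strand; the transcription end site (TES) is the
    opposite anchor.  Exons are disjoint, sorted, half-open intervals
    contained in ``[tx_start, tx_end)``.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(
                f"invalid transcript span [{self.tx_start}, {self.tx_end}) "
                f"for gene {self.gene_id}"
            )
        prev_end = self.tx_start - 1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty exon ({start}, {end}) in {self.gene_id}")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(f"exon outside transcript span in {self.gene_id}")
            if start <= prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    def contains_in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass(frozen=True)
class Peak:
    """An enriched interval with its summit and enrichment statistics.

    ``p_value`` is the upper-tail Poisson probability of the summit-bin
    treatment count given the library-scaled input background.
    """

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    p_value: float
    cell_label: str = ""
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


# Location categories for peak-summit classification relative to a gene.
LOCATION_CATEGORIES = (
    "promoter",
    "exon",
    "intron",
    "TES_window",
    "upstream",
    "downstream",
    "distant",
)


@dataclass(frozen=True)
class LocationCall:
    peak_id: str
    gene_id: str | None
    category: str

    def __post_init__(self) -> None:
        if self.category not in LOCATION_CATEGORIES:
            raise ValueError(f"unknown location category {self.category!r}")


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of an inverted-repeat dimer in a scanned sequence.

    ``offset`` is the signed distance of the pattern start from the scan
    anchor (the peak summit when scanning flanks, else the sequence start).
    The second arm begins ``spacer`` bases after the first arm ends, so the
    whole pattern spans ``len(arm1_seq) + spacer + len(arm2_seq)`` bases.
    """

    peak_id: str
    offset: int
    arm1_seq: str
    arm2_seq: str
    spacer: int
    mismatches: int
    orientation: str = "forward"


@dataclass(frozen=True)
class DimerMotif:
    """A candidate dimer motif with its support and shuffle-based enrichment."""

    arm_consensus: str
    spacer: int
    support: int
    expected_support: float
    background_rate: float
    enrichment: float
    p_value: float


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for recovery tests.

    ``gene_fold`` maps each planted gene_id to (bin-target fold level,
    direction); ``gene_ratio`` records the exact expression ratio planted
    for that gene (>= 1, on the same side as ``direction``).  ``peaks`` is
    a list of dicts with the true summit, interval, fold and motif flag;
    ``peak_gene`` maps peak_id -> owning gene_id or None.  Genes absent
    from ``gene_fold`` were generated unchanged.
    """

    gene_fold: dict[str, tuple[float, str]] = field(default_factory=dict)
    gene_ratio: dict[str, float] = field(default_factory=dict)
    peaks: list[dict] = field(default_factory=list)
    peak_gene: dict[str, str | None] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            gene_fold={**self.gene_fold, **other.gene_fold},
            gene_ratio={**self.gene_ratio, **other.gene_ratio},
            peaks=self.peaks + other.peaks,
            peak_gene={**self.peak_gene, **other.peak_gene},
        )
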