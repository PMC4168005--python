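"""Readers and writers for the pipeline's on-disk formats.

Genomes are FASTA (read back through pyfaidx), gene models are BED12
plus a tab-separated category map keyed by gene_id, counts are TSV, and
ground truth is JSON.  All coordinates are 0-based half-open, matching
BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .models import GeneModel, GroundTruth


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fasta = Fasta(str(path))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_gene_models(
    genes: list[GeneModel], bed_path: str | Path, category_path: str | Path
) -> None:
    """BED12 gene models plus a gene_id -> categories TSV."""
    with open(bed_path, "w") as fh:
        for g in genes:
            block_sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            block_starts = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t"
                f"{block_sizes}\t{block_starts}\n"
            )
    with open(category_path, "w") as fh:
        fh.write("gene_id\tsymbol\tcategories\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{';'.join(g.categories)}\n")


def read_gene_models(
    bed_path: str | Path, category_path: str | Path | None = None
) -> list[GeneModel]:
    symbols: dict[str, str] = {}
    categories: dict[str, tuple[str, ...]] = {}
    if category_path is not None:
        cat = pd.read_csv(category_path, sep="\t", dtype=str).fillna("")
        for row in cat.itertuples(index=False):
            symbols[row.gene_id] = row.symbol
            categories[row.gene_id] = tuple(
                c for c in str(row.categories).split(";") if c
            )
    genes: list[GeneModel] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=symbols.get(name, name),
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                    categories=categories.get(name, ()),
                )
            )
    return genes


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gene_fold": {
            gid: {"level": level, "direction": direction}
            for gid, (level, direction) in truth.gene_fold.items()
        },
        "gene_ratio": truth.gene_ratio,
        "peaks": truth.peaks,
        "peak_gene": truth.peak_gene,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth = GroundTruth()
    truth.gene_fold = {
        gid: (rec["level"], rec["direction"])
        for gid, rec in payload["gene_fold"].items()
    }
    truth.gene_ratio = payload["gene_ratio"]
    truth.peaks = payload["peaks"]
    truth.peak_gene = payload["peak_gene"]
    return truth
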