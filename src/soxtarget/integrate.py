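"""Cross-tabulation of differential expression against binding sites.

Combines the fold-change bins, the peak-to-gene assignment, functional
category labels, and motif flags into the study-shaped summary tables:
the per-bin percentage of regulated genes that carry at least one
binding site, the same fractions per functional category, and the
overlap between gene sets from two cell types keyed by symbol.
``run_all`` drives the whole pipeline on a synthetic configuration.
"""

from __future__ import annotations

import logging
import time
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .annotate import (
    GenePeakAssignment,
    assign_peaks_to_genes,
    classify_peaks,
    location_distribution,
)
from .expression import bin_by_fold, differential_expression
from .motif import summit_flank_fraction
from .peaks import call_peaks
from .synthetic import SyntheticConfig, simulate

logger = logging.getLogger("soxtarget")

Bins = dict[tuple[str, float], list[str]]


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (0.0 for an empty group)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _site_genes(assignment: GenePeakAssignment | set[str]) -> set[str]:
    if isinstance(assignment, GenePeakAssignment):
        return assignment.genes_with_peaks()
    return set(assignment)


def crosstab_de_binding(
    bins: Bins,
    assignment: GenePeakAssignment | set[str],
    cell_label: str = "",
    gene_universe: set[str] | None = None,
) -> pd.DataFrame:
    """Per-bin counts and percentages of genes with >= 1 binding site.

    One row per (direction, fold threshold) bin; ``pct`` is
    ``100 * n_with_sites / n_genes`` rounded half-up to one decimal.
    Site-bearing gene ids outside ``gene_universe`` (when given) are
    reported as a warning and excluded.
    """
    site_genes = _site_genes(assignment)
    if gene_universe is not None:
        unknown = site_genes - gene_universe
        if unknown:
            warnings.warn(
                f"{len(unknown)} site-bearing gene ids not in the gene "
                f"universe were excluded: {sorted(unknown)[:5]}",
                stacklevel=2,
            )
            site_genes &= gene_universe

    rows = []
    for (direction, threshold), gene_ids in sorted(bins.items()):
        genes = set(gene_ids)
        with_sites = genes & site_genes
        rows.append(
            {
                "direction": direction,
                "fold_threshold": threshold,
                "n_genes": len(genes),
                "n_with_sites": len(with_sites),
                "pct": round_pct(len(with_sites), len(genes)),
                "cell_label": cell_label,
            }
        )
    return pd.DataFrame(rows)


def category_binding_fraction(
    bins: Bins,
    categories: dict[str, tuple[str, ...]],
    assignment: GenePeakAssignment | set[str],
    min_group: int = 5,
    direction: str = "decrease",
    threshold: float = 6.0,
    cell_label: str = "",
) -> pd.DataFrame:
    """Binding-site fractions per functional category for one fold bin.

    A gene with several categories counts once in each.  Groups with at
    most ``min_group`` genes are still reported but flagged
    ``below_threshold`` (the study only quotes groups of more than five
    genes).
    """
    key = (direction, float(threshold))
    if key not in bins:
        raise KeyError(f"bin {key} not present in the provided bins")
    site_genes = _site_genes(assignment)
    members = set(bins[key])

    per_cat: dict[str, set[str]] = {}
    for gid in members:
        for cat in categories.get(gid, ()):
            per_cat.setdefault(cat, set()).add(gid)

    rows = []
    for cat, genes in sorted(per_cat.items()):
        with_sites = genes & site_genes
        rows.append(
            {
                "category": cat,
                "direction": direction,
                "fold_threshold": float(threshold),
                "n_genes": len(genes),
                "n_with_sites": len(with_sites),
                "pct": round_pct(len(with_sites), len(genes)),
                "below_threshold": len(genes) <= min_group,
                "cell_label": cell_label,
            }
        )
    return pd.DataFrame(rows)


def species_overlap(
    geneset_a: set[str], geneset_b: set[str]
) -> tuple[int, float, float]:
    """Symbol-keyed overlap between two gene sets.

    Returns (|a ∩ b|, fraction of a shared, fraction of b shared).
    Empty sets make the fractions undefined and raise.
    """
    if not geneset_a or not geneset_b:
        raise ValueError("species overlap is undefined for an empty gene set")
    common = set(geneset_a) & set(geneset_b)
    return len(common), len(common) / len(geneset_a), len(common) / len(geneset_b)


def run_all(
    config: SyntheticConfig,
    *,
    fold_min: float = 2.0,
    p_max: float = 1e-5,
    flank: int = 50_000,
    motif_flank: int = 100,
    cell_label: str = "synthetic",
) -> dict:
    """Full pipeline on synthetic data: simulate, filter, call, annotate,
    scan, cross-tabulate.  Deterministic given the config seed; the
    returned bundle carries every threshold used."""
    t0 = time.time()
    sim = simulate(config)
    logger.info("simulated %d genes, %d true peaks (%.1fs)",
                len(sim["genes"]), len(sim["truth"].peaks), time.time() - t0)

    de = differential_expression(sim["counts"], "g0000", "g0001")
    bins = bin_by_fold(de)
    logger.info("DE: %d genes pass floor, %d in >=2 decrease",
                int(de["passes_floor"].sum()),
                len(bins[("decrease", 2.0)]))

    called = call_peaks(
        sim["treatment"], sim["input"],
        fold_min=fold_min, p_max=p_max, cell_label=cell_label,
    )
    logger.info("called %d peaks at fold>%g, p<%g", len(called), fold_min, p_max)

    assignment = assign_peaks_to_genes(called, sim["genes"], flank=flank)
    calls = classify_peaks(called, sim["genes"], flank=flank)
    locations = location_distribution(calls)

    fraction, flags, hits = (
        summit_flank_fraction(called, sim["genome"], flank=motif_flank)
        if called
        else (0.0, {}, [])
    )
    logger.info("motif present near %d/%d summits (%.1f%%)",
                sum(flags.values()), len(flags), 100 * fraction)

    crosstab = crosstab_de_binding(
        bins, assignment, cell_label=cell_label,
        gene_universe={g.gene_id for g in sim["genes"]},
    )
    categories = {g.gene_id: g.categories for g in sim["genes"]}
    category_table = category_binding_fraction(
        bins, categories, assignment, cell_label=cell_label
    )

    return {
        "config": config,
        "de": de,
        "bins": bins,
        "peaks": called,
        "assignment": assignment,
        "location_calls": calls,
        "location_distribution": locations,
        "motif_fraction": fraction,
        "motif_flags": flags,
        "motif_hits": hits,
        "crosstab": crosstab,
        "category_table": category_table,
        "truth": sim["truth"],
        "provenance": {
            "version": _version,
            "seed": config.seed,
            "fold_min": fold_min,
            "p_max": p_max,
            "flank": flank,
            "motif_flank": motif_flank,
            "z_threshold": 4.0,
            "cell_label": cell_label,
        },
    }


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write the report tables of a run_all bundle as TSV/JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["de"].to_csv(outdir / "de.tsv", sep="\t", index=False)
    bundle["crosstab"].to_csv(outdir / "crosstab.tsv", sep="\t", index=False)
    bundle["category_table"].to_csv(
        outdir / "category_binding.tsv", sep="\t", index=False
    )
    bundle["location_distribution"].to_csv(
        outdir / "location_distribution.tsv", sep="\t", index=False
    )
    from .peaks import write_peaks_bed

    write_peaks_bed(bundle["peaks"], outdir / "peaks.bed")
    report = {
        "motif_fraction": bundle["motif_fraction"],
        "n_peaks": len(bundle["peaks"]),
        "provenance": bundle["provenance"],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
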