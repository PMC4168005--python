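"""Two-condition tag-count differential expression.

Takes a table of per-gene sequencing-tag counts from a control and a
treated library, normalizes each condition to a reference gene (a
beta-actin-like stable gene), computes fold changes and a two-proportion
z statistic, applies an expression floor anchored to a highly expressed
marker gene (Col2a1-like), and collects the surviving genes into nested
fold-change bins per direction.

The fold bins are cumulative: a gene with a 8.2-fold decrease appears in
every decrease bin from >=2 through >=8.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

DEFAULT_FOLD_THRESHOLDS: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0)
DEFAULT_Z_THRESHOLD = 4.0
DEFAULT_FLOOR_TAGS = 100
DEFAULT_FLOOR_FRACTION = 0.0006

REQUIRED_COLUMNS = ("gene_id", "tags_control", "tags_treated")


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in count table: {dupes[:5]}")
    if (table["tags_control"] < 0).any() or (table["tags_treated"] < 0).any():
        raise ValueError("tag counts must be non-negative")


def normalize(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Divide each gene's tags by the same-condition reference-gene tags.

    Returns a copy of ``table`` with ``norm_control`` and ``norm_treated``
    columns; the reference gene itself maps to (1, 1).

    Raises ``ValueError`` if the reference gene is absent or has zero tags
    in either condition.
    """
    _validate_table(table)
    ref = table.loc[table["gene_id"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    ref_control = float(ref["tags_control"].iloc[0])
    ref_treated = float(ref["tags_treated"].iloc[0])
    if ref_control <= 0 or ref_treated <= 0:
        raise ValueError(
            f"reference gene {reference_gene!r} must have positive tags in "
            f"both conditions (got {ref_control}, {ref_treated})"
        )
    out = table.copy()
    out["norm_control"] = out["tags_control"] / ref_control
    out["norm_treated"] = out["tags_treated"] / ref_treated
    return out


def z_score(
    tags_control: float,
    tags_treated: float,
    total_control: float,
    total_treated: float,
) -> float:
    """Pooled two-proportion z statistic on per-library tag fractions.

    With p̂₁ = x₁/n₁ and p̂₂ = x₂/n₂ and the pooled fraction
    p̄ = (x₁+x₂)/(n₁+n₂), returns
    ``(p̂₁ − p̂₂) / sqrt(p̄(1−p̄)(1/n₁ + 1/n₂))``.

    Defined as 0 when both counts are zero or the proportions are equal.
    """
    if total_control <= 0 or total_treated <= 0:
        raise ValueError("library totals must be positive")
    x1, x2 = float(tags_control), float(tags_treated)
    n1, n2 = float(total_control), float(total_treated)
    if x1 == 0.0 and x2 == 0.0:
        return 0.0
    p1, p2 = x1 / n1, x2 / n2
    if p1 == p2:
        return 0.0
    pooled = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        # pooled fraction of 1 means both libraries are a single gene
        return math.inf if p1 > p2 else -math.inf
    return (p1 - p2) / denom


def fold_change_and_direction(
    norm_control: float, norm_treated: float, pseudocount_applied: bool = False
) -> tuple[float, str]:
    """Symmetric fold change (>= 1) and direction of the treated condition.

    ``direction`` is "decrease" when treated < control, "increase" when
    treated > control, "unchanged" when equal.
    """
    if norm_control <= 0 or norm_treated <= 0:
        raise ValueError("normalized expression must be positive; apply a "
                         "pseudocount before computing fold change")
    r = norm_treated / norm_control
    if r < 1.0:
        return 1.0 / r, "decrease"
    if r > 1.0:
        return r, "increase"
    return 1.0, "unchanged"


def differential_expression(
    table: pd.DataFrame,
    reference_gene: str,
    marker_gene: str,
    *,
    floor_mode: str = "absolute",
    floor_tags: int = DEFAULT_FLOOR_TAGS,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full per-gene differential-expression table.

    Normalizes to ``reference_gene``, computes fold change and direction
    (with ``pseudocount`` added to both raw counts of any gene that has a
    zero), the pooled two-proportion z on raw tags against library totals,
    and the expression floor relative to ``marker_gene``.

    Returns a DataFrame with columns gene_id, tags_control, tags_treated,
    norm_control, norm_treated, fold_change, direction, z, passes_floor.
    """
    normed = normalize(table, reference_gene)

    total_control = float(normed["tags_control"].sum())
    total_treated = float(normed["tags_treated"].sum())

    ref = normed.loc[normed["gene_id"] == reference_gene].iloc[0]
    ref_control = float(ref["tags_control"])
    ref_treated = float(ref["tags_treated"])

    folds: list[float] = []
    directions: list[str] = []
    zs: list[float] = []
    for row in normed.itertuples(index=False):
        tc, tt = float(row.tags_control), float(row.tags_treated)
        if tc == 0.0 or tt == 0.0:
            nc = (tc + pseudocount) / ref_control
            nt = (tt + pseudocount) / ref_treated
        else:
            nc, nt = float(row.norm_control), float(row.norm_treated)
        fold, direction = fold_change_and_direction(nc, nt)
        folds.append(fold)
        directions.append(direction)
        zs.append(z_score(tc, tt, total_control, total_treated))

    normed["fold_change"] = folds
    normed["direction"] = directions
    normed["z"] = zs
    return apply_floor(
        normed,
        marker_gene,
        mode=floor_mode,
        floor_tags=floor_tags,
        floor_fraction=floor_fraction,
    )


def apply_floor(
    results: pd.DataFrame,
    marker_gene: str,
    *,
    mode: str = "absolute",
    floor_tags: int = DEFAULT_FLOOR_TAGS,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> pd.DataFrame:
    """Flag genes whose control-condition expression clears the floor.

    The floor is anchored to the marker gene's control-condition tags.  In
    "absolute" mode (default) the threshold is ``floor_tags``; in
    "fraction" mode it is ``floor_fraction`` times the marker's control
    tags; in "max" mode it is the larger of the two.  A gene passes iff
    its control tags are strictly greater than the threshold.
    """
    marker = results.loc[results["gene_id"] == marker_gene]
    if marker.empty:
        raise ValueError(f"marker gene {marker_gene!r} not in table")
    marker_control = float(marker["tags_control"].iloc[0])

    if mode == "absolute":
        threshold = float(floor_tags)
    elif mode == "fraction":
        threshold = floor_fraction * marker_control
    elif mode == "max":
        threshold = max(float(floor_tags), floor_fraction * marker_control)
    else:
        raise ValueError(f"unknown floor mode {mode!r}")

    out = results.copy()
    out["passes_floor"] = out["tags_control"] > threshold
    out.attrs["floor_mode"] = mode
    out.attrs["floor_threshold"] = threshold
    return out


def bin_by_fold(
    results: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_FOLD_THRESHOLDS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> dict[tuple[str, float], list[str]]:
    """Nested fold-change bins per direction.

    A gene enters bin ``(direction, t)`` iff its fold_change >= t, |z| is
    strictly greater than ``z_threshold``, and it passes the expression
    floor.  Bins nest: every gene in the >=8 bin is also in >=6, >=4, >=3
    and >=2 of the same direction.  "unchanged" genes enter no bin.
    """
    needed = {"gene_id", "fold_change", "direction", "z", "passes_floor"}
    missing = needed - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")

    eligible = results[
        (results["z"].abs() > z_threshold)
        & results["passes_floor"]
        & (results["direction"] != "unchanged")
    ]
    bins: dict[tuple[str, float], list[str]] = {}
    for direction in ("decrease", "increase"):
        sub = eligible[eligible["direction"] == direction]
        for t in thresholds:
            hit = sub.loc[sub["fold_change"] >= t, "gene_id"]
            bins[(direction, float(t))] = hit.tolist()
    return bins


def read_counts(path) -> pd.DataFrame:
    """Read a tab-separated count table with a required header."""
    table = pd.read_csv(path, sep="\t")
    _validate_table(table)
    return table


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
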