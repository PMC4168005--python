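"""Minimal binned fold-plus-Poisson peak caller.

Calls enriched intervals from a treatment coverage track against an
input-DNA control: bins where treatment exceeds ``fold_min`` times the
library-scaled input are merged into candidate intervals, each interval's
summit is the maximum-coverage bin center, and the interval is kept only
if the summit bin's treatment count is Poisson-improbable under the
scaled-input background (lambda floored at the genome-wide scaled input
mean, the standard safeguard against sparse-input artifacts).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import stats

from .models import Peak
from .tracks import CoverageTrack


def scale_libraries(treatment_total: float, input_total: float) -> float:
    """Factor by which input coverage is multiplied before comparison.

    Matches the input library depth to the treatment library depth.
    """
    if treatment_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    return float(treatment_total) / float(input_total)


def _merge_candidate_bins(idx: np.ndarray, max_gap_bins: int = 1) -> list[tuple[int, int]]:
    """Merge sorted candidate bin indices, bridging gaps of <= max_gap_bins."""
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev <= max_gap_bins + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_peaks(
    treatment: CoverageTrack,
    input_track: CoverageTrack,
    *,
    fold_min: float = 2.0,
    p_max: float = 1e-5,
    min_span: int = 50,
    cell_label: str = "",
) -> list[Peak]:
    """Call enriched peaks from treatment vs input coverage.

    Parameters
    ----------
    fold_min : minimum treatment / scaled-input ratio for a candidate bin
        (strictly greater than)
    p_max : maximum Poisson upper-tail p-value at the summit bin
        (strictly less than)
    min_span : minimum peak width in base pairs
    """
    if treatment.n_bins() == 0 or input_track.n_bins() == 0:
        raise ValueError("empty coverage track")
    if not treatment.compatible_with(input_track):
        raise ValueError("treatment and input tracks cover different spaces")
    if input_track.total() <= 0:
        raise ValueError(
            "input track has zero coverage everywhere; a positive input "
            "background is required for peak calling"
        )

    scale = scale_libraries(treatment.total(), input_track.total())
    lam_floor = scale * input_track.mean()
    bin_size = treatment.bin_size

    peaks: list[Peak] = []
    for chrom in treatment.chroms:
        t = treatment.counts[chrom]
        i = input_track.counts[chrom] * scale
        candidate = np.flatnonzero(t > fold_min * i)
        if candidate.size == 0:
            continue
        for b0, b1 in _merge_candidate_bins(candidate):
            start, end = b0 * bin_size, (b1 + 1) * bin_size
            if end - start < min_span:
                continue
            window = t[b0 : b1 + 1]
            summit_bin = b0 + int(np.argmax(window))  # leftmost on ties
            summit = summit_bin * bin_size + bin_size // 2
            lam = max(i[summit_bin], lam_floor)
            x = t[summit_bin]
            # P(X >= x) under Poisson(lam)
            p = float(stats.poisson.sf(x - 1, lam))
            fold = float(x / lam)
            if p >= p_max:
                continue
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    fold_enrichment=fold,
                    p_value=p,
                    cell_label=cell_label,
                    peak_id=f"peak_{chrom}_{start}",
                )
            )
    return peaks


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2 (name, -log10 p as score, summit, fold)."""
    with open(path, "w") as fh:
        for pk in peaks:
            neglog = -np.log10(pk.p_value) if pk.p_value > 0 else 999.0
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.peak_id}\t"
                f"{neglog:.3f}\t.\t{pk.summit}\t{pk.fold_enrichment:.4f}\n"
            )


def read_peaks_bed(path: str | Path, cell_label: str = "") -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name, score = fields[:5]
            summit = int(fields[6]) if len(fields) > 6 else (int(start) + int(end)) // 2
            fold = float(fields[7]) if len(fields) > 7 else 1.0
            p = 10 ** (-float(score)) if float(score) < 999 else 0.0
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    summit=summit,
                    fold_enrichment=fold,
                    p_value=p,
                    cell_label=cell_label,
                    peak_id=name,
                )
            )
    return peaks
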