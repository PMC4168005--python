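"""Binned coverage tracks with bedGraph round-tripping.

A track stores per-bin tag counts for each chromosome at a fixed bin
width.  bedGraph output run-length-merges consecutive equal-valued bins,
matching how genome browsers expect the format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class CoverageTrack:
    """Per-chromosome binned coverage.

    Parameters
    ----------
    counts : mapping of chromosome name to 1-D array of per-bin counts
    bin_size : width of each bin in base pairs
    """

    def __init__(self, counts: dict[str, np.ndarray], bin_size: int = 10):
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.counts = {
            chrom: np.asarray(arr, dtype=float) for chrom, arr in counts.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def mean(self) -> float:
        n = sum(arr.size for arr in self.counts.values())
        if n == 0:
            raise ValueError("empty track")
        return self.total() / n

    def n_bins(self) -> int:
        return int(sum(arr.size for arr in self.counts.values()))

    def compatible_with(self, other: "CoverageTrack") -> bool:
        if self.bin_size != other.bin_size:
            return False
        if set(self.counts) != set(other.counts):
            return False
        return all(
            self.counts[c].size == other.counts[c].size for c in self.counts
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.counts:
                arr = self.counts[chrom]
                if arr.size == 0:
                    continue
                # run-length merge equal consecutive bins
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    val = arr[s]
                    fh.write(
                        f"{chrom}\t{s * self.bin_size}\t{e * self.bin_size}\t"
                        f"{val:g}\n"
                    )

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, bin_size: int = 10
    ) -> "CoverageTrack":
        """Read a bedGraph whose intervals align to ``bin_size`` boundaries."""
        spans: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")
                s, e = int(start), int(end)
                if s % bin_size or e % bin_size:
                    raise ValueError(
                        f"interval {chrom}:{s}-{e} not aligned to "
                        f"{bin_size} bp bins"
                    )
                spans.setdefault(chrom, []).append((s, e, float(value)))
        counts: dict[str, np.ndarray] = {}
        for chrom, ivs in spans.items():
            n = max(e for _, e, _ in ivs) // bin_size
            arr = np.zeros(n, dtype=float)
            for s, e, v in ivs:
                arr[s // bin_size : e // bin_size] = v
            counts[chrom] = arr
        return cls(counts, bin_size=bin_size)
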