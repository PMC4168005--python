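"""Inverted-repeat dimer scanning and enumerative motif discovery.

SOX9 binds DNA as a homodimer on an inverted repeat: a six-base arm
(consensus ACAAAG), a short spacer (four bases in chondrocyte peaks), and
the reverse complement of the arm (CTTTGT).  This module scans peak-summit
flanks for that structure, reports the fraction of peaks carrying it, and
discovers enriched dimer and k-mer motifs by exhaustive enumeration
against dinucleotide-preserving shuffled backgrounds — the 4^6 arm space
is small enough that enumeration is exact and deterministic.

The dimer pattern arm-N{s}-revcomp(arm) is its own reverse complement, so
a single forward scan covers both strands: a minus-strand occurrence at a
locus is the same plus-strand occurrence with the two arms' mismatch
counts swapped.  Each genomic locus is therefore reported once.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .models import DimerMotif, MotifHit, Peak

CANONICAL_ARM = "ACAAAG"
DEFAULT_FLANK = 100

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("AC"): "M", frozenset("GT"): "K",
    frozenset("AT"): "W", frozenset("CG"): "S",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_fast(seq: str) -> np.ndarray:
    seq = seq.upper()
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -2, dtype=np.int8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    codes = lut[raw]
    if (codes == -2).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes == -2)[:5]})
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return codes


def scan_inverted_repeat(
    sequence: str,
    arm: str = CANONICAL_ARM,
    spacer_range: tuple[int, int] = (4, 4),
    max_mismatch: int = 0,
    peak_id: str = "",
    anchor: int = 0,
) -> list[MotifHit]:
    """Find every arm / spacer / reverse-complement-arm occurrence.

    A position matches when the arm aligns with at most ``max_mismatch``
    mismatches, and ``spacer`` bases later the reverse complement of the
    arm aligns with at most ``max_mismatch`` mismatches.  ``N`` never
    matches.  Offsets are reported relative to ``anchor`` (e.g. pass the
    summit offset within the extracted window to get summit-relative
    coordinates).  ``mismatches`` on each hit is the total over both arms.
    """
    if len(arm) != 6:
        raise ValueError("arm must be a 6-mer")
    if set(arm.upper()) - set("ACGT"):
        raise ValueError("arm must be over the ACGT alphabet")
    lo, hi = spacer_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid spacer range ({lo}, {hi})")

    codes = _encode_fast(sequence)
    arm_codes = _encode_fast(arm)
    arm2_codes = _encode_fast(reverse_complement(arm))
    k = len(arm)
    hits: list[MotifHit] = []
    if codes.size < 2 * k + lo:
        return hits

    windows = sliding_window_view(codes, k)  # (n-k+1, k)
    mism = (windows != arm_codes).sum(axis=1)
    mism2 = (windows != arm2_codes).sum(axis=1)
    # positions with any N never match regardless of budget
    has_n = (windows >= 4).any(axis=1)
    ok1 = (mism <= max_mismatch) & ~has_n
    ok2 = (mism2 <= max_mismatch) & ~has_n

    for spacer in range(lo, hi + 1):
        shift = k + spacer
        n_pos = codes.size - (2 * k + spacer) + 1
        if n_pos <= 0:
            continue
        both = ok1[:n_pos] & ok2[shift : shift + n_pos]
        for i in np.flatnonzero(both):
            i = int(i)
            hits.append(
                MotifHit(
                    peak_id=peak_id,
                    offset=i - anchor,
                    arm1_seq=sequence[i : i + k].upper(),
                    arm2_seq=sequence[i + shift : i + shift + k].upper(),
                    spacer=spacer,
                    mismatches=int(mism[i] + mism2[i + shift]),
                    orientation="forward",
                )
            )
    hits.sort(key=lambda h: (h.offset, h.spacer))
    return hits


def extract_summit_windows(
    peaks: list[Peak],
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> dict[str, tuple[str, int]]:
    """Extract summit ± flank sequence per peak.

    Returns peak_id -> (window sequence, summit offset within the window).
    The window is truncated at chromosome ends; a summit off its
    chromosome raises.
    """
    out: dict[str, tuple[str, int]] = {}
    for pk in peaks:
        if pk.chrom not in genome:
            raise ValueError(f"peak {pk.peak_id} on unknown chromosome {pk.chrom}")
        chrom_seq = genome[pk.chrom]
        if not 0 <= pk.summit < len(chrom_seq):
            raise ValueError(
                f"summit {pk.summit} of {pk.peak_id} outside chromosome "
                f"{pk.chrom} (length {len(chrom_seq)})"
            )
        lo = max(0, pk.summit - flank)
        hi = min(len(chrom_seq), pk.summit + flank + 1)
        out[pk.peak_id] = (str(chrom_seq[lo:hi]), pk.summit - lo)
    return out


def summit_flank_fraction(
    peaks: list[Peak],
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
    *,
    arm: str = CANONICAL_ARM,
    spacer_range: tuple[int, int] = (4, 4),
    max_mismatch: int = 0,
) -> tuple[float, dict[str, bool], list[MotifHit]]:
    """Fraction of peaks with >= 1 dimer hit within ``flank`` of the summit.

    Scans the summit ± flank window (2*flank + 1 bp where the chromosome
    permits); a hit counts when the whole pattern lies inside the window.
    Returns (fraction, per-peak flags, all hits).
    """
    if not peaks:
        raise ValueError("no peaks to scan")
    windows = extract_summit_windows(peaks, genome, flank)
    flags: dict[str, bool] = {}
    all_hits: list[MotifHit] = []
    for pk in peaks:
        seq, offset = windows[pk.peak_id]
        hits = scan_inverted_repeat(
            seq,
            arm=arm,
            spacer_range=spacer_range,
            max_mismatch=max_mismatch,
            peak_id=pk.peak_id,
            anchor=offset,
        )
        flags[pk.peak_id] = bool(hits)
        all_hits.extend(hits)
    fraction = sum(flags.values()) / len(flags)
    return fraction, flags, all_hits


# ---------------------------------------------------------------------------
# backgrounds

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul–Erickson edge shuffling: treat bases as vertices and
    dinucleotides as directed edges, pick a random spanning arborescence
    into the final vertex, shuffle the remaining out-edges, and walk the
    Eulerian path.  Sequences shorter than three bases return unchanged.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | {last})  # sorted: hash-order free

    for _ in range(100):
        # choose a random last out-edge per non-terminal vertex; keep the
        # choice only if those edges form paths that all reach `last`
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v != last and edges[v]:
                last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            cur, seen = v, set()
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - graph is always connectable from a real seq
        return seq

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        outs = list(edges.get(v, []))
        if v in last_edge:
            outs.remove(last_edge[v])
        rng.shuffle(outs)
        if v in last_edge:
            outs.append(last_edge[v])
        shuffled[v] = outs

    walk = [first]
    pos = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def _dimer_occurrences(codes: np.ndarray, arm_len: int, spacer: int) -> list[int]:
    """Start positions of any perfect arm/spacer/rc-arm dimer in ``codes``."""
    total = 2 * arm_len + spacer
    n_pos = codes.size - total + 1
    if n_pos <= 0:
        return []
    comp = 3 - codes  # N (4) maps to -1 and never matches
    acc = np.ones(n_pos, dtype=bool)
    for k in range(arm_len):
        # arm base k must complement the mirrored base of the second arm
        j = total - 1 - k
        acc &= codes[k : k + n_pos] == comp[j : j + n_pos]
        if not acc.any():
            return []
    valid = np.ones(n_pos, dtype=bool)
    win = sliding_window_view(codes, total)[:n_pos]
    valid &= (win[:, :arm_len] < 4).all(axis=1)
    valid &= (win[:, arm_len + spacer :] < 4).all(axis=1)
    return np.flatnonzero(acc & valid).tolist()


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _canonical_arm(arm: str) -> str:
    rc = reverse_complement(arm)
    return min(arm, rc)


def _window_dimer_support(
    windows: list[str], arm_len: int, spacers: range
) -> Counter:
    """Count, per (canonical arm, spacer), the number of windows with >= 1
    perfect dimer occurrence (presence/absence per window)."""
    support: Counter = Counter()
    for seq in windows:
        codes = _encode_fast(seq)
        seen: set[tuple[str, int]] = set()
        for spacer in spacers:
            for i in _dimer_occurrences(codes, arm_len, spacer):
                arm = _decode(codes[i : i + arm_len])
                seen.add((_canonical_arm(arm), spacer))
        support.update(seen)
    return support


def discover_dimers(
    windows: list[str],
    arm_len: int = 6,
    spacer_range: tuple[int, int] = (3, 5),
    n_shuffles: int = 5,
    seed: int = 0,
    top_n: int = 20,
) -> list[DimerMotif]:
    """Exhaustively rank inverted-repeat dimers by shuffle-based enrichment.

    Every arm in the 4^arm_len space is implicitly enumerated through its
    occurrences; support is the number of windows containing at least one
    perfect occurrence of the arm/spacer structure, arms identical under
    reverse complement are collapsed, and the expected support comes from
    ``n_shuffles`` dinucleotide-preserving shuffles of each window.
    Candidates are ranked by binomial upper-tail p-value, then enrichment.
    """
    if not windows:
        raise ValueError("at least one window is required")
    usable = [w for w in windows if set(w.upper()) - {"N"}]
    if not usable:
        raise ValueError("all windows are degenerate (all N)")

    rng = np.random.default_rng(seed)
    spacers = range(spacer_range[0], spacer_range[1] + 1)
    n_windows = len(usable)

    observed = _window_dimer_support(usable, arm_len, spacers)

    shuffle_support: Counter = Counter()
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(w, rng) for w in usable]
        shuffle_support.update(_window_dimer_support(shuffled, arm_len, spacers))

    results: list[DimerMotif] = []
    denom = n_windows * n_shuffles
    for (arm, spacer), support in observed.items():
        # +0.5 pseudo-support keeps never-shuffled-in motifs finite
        rate = (shuffle_support.get((arm, spacer), 0) + 0.5) / (denom + 1)
        rate = min(rate, 1.0)
        expected = rate * n_windows
        p = float(stats.binom.sf(support - 1, n_windows, rate))
        results.append(
            DimerMotif(
                arm_consensus=arm,
                spacer=spacer,
                support=support,
                expected_support=expected,
                background_rate=rate,
                enrichment=float(np.log2(support / expected)),
                p_value=p,
            )
        )
    results.sort(key=lambda m: (m.p_value, -m.enrichment, m.arm_consensus))
    return results[:top_n]


# ---------------------------------------------------------------------------
# contiguous k-mer enrichment

def _window_kmer_support(windows: list[str], k: int) -> Counter:
    support: Counter = Counter()
    for seq in windows:
        seq = seq.upper()
        seen = {
            seq[i : i + k]
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        }
        support.update(seen)
    return support


_IUPAC_EXPAND = {code: bases for bases, code in _IUPAC.items()}


def _merge_iupac(a: str, b: str) -> str:
    """Positionwise union of two (possibly already degenerate) motifs."""
    out = []
    for ca, cb in zip(a, b):
        if ca == cb:
            out.append(ca)
        else:
            union = _IUPAC_EXPAND[ca] | _IUPAC_EXPAND[cb]
            out.append(_IUPAC[frozenset(union)])
    return "".join(out)


def kmer_enrichment(
    windows: list[str],
    k: int = 8,
    n_shuffles: int = 5,
    seed: int = 0,
    top_n: int = 20,
    collapse: bool = True,
) -> list[DimerMotif]:
    """Rank contiguous k-mers by shuffle-based enrichment.

    Uses the same presence/absence support and dinucleotide-shuffle
    background as dimer discovery.  With ``collapse`` enabled, pairs of
    top-ranked k-mers differing at a single position are merged into an
    IUPAC consensus when the joint support lowers the binomial p-value.
    Returned motifs reuse the dimer record with ``spacer=0`` and the
    k-mer (or IUPAC consensus) as the arm.
    """
    if not windows:
        raise ValueError("at least one window is required")
    usable = [w for w in windows if set(w.upper()) - {"N"}]
    if not usable:
        raise ValueError("all windows are degenerate (all N)")
    if any(len(w) < k for w in usable):
        raise ValueError(f"k={k} exceeds the shortest window length")

    rng = np.random.default_rng(seed)
    n_windows = len(usable)
    observed = _window_kmer_support(usable, k)
    shuffle_support: Counter = Counter()
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(w, rng) for w in usable]
        shuffle_support.update(_window_kmer_support(shuffled, k))

    denom = n_windows * n_shuffles

    def binom_p(support: int, rate: float) -> float:
        return float(stats.binom.sf(support - 1, n_windows, min(rate, 1.0)))

    scored: list[tuple[str, int, float]] = []  # (kmer, support, rate)
    for kmer, support in observed.items():
        rate = (shuffle_support.get(kmer, 0) + 0.5) / (denom + 1)
        scored.append((kmer, support, rate))
    scored.sort(key=lambda t: (binom_p(t[1], t[2]), -t[1], t[0]))
    scored = scored[: max(top_n * 4, 50)]

    if collapse:
        merged: list[tuple[str, int, float]] = []
        used = [False] * len(scored)
        kmer_support = {kmer: s for kmer, s, _ in scored}
        for i, (kmer, support, rate) in enumerate(scored):
            if used[i]:
                continue
            best = (kmer, support, rate)
            for j in range(i + 1, len(scored)):
                if used[j]:
                    continue
                other, osup, orate = scored[j]
                if sum(a != b for a, b in zip(kmer, other)) != 1:
                    continue
                joint_rate = rate + orate
                # union support over windows bounded by the sum
                joint_support = min(support + osup, n_windows)
                if binom_p(joint_support, joint_rate) < binom_p(
                    best[1], best[2]
                ):
                    best = (_merge_iupac(best[0], other), joint_support, joint_rate)
                    used[j] = True
            merged.append(best)
        scored = merged

    results = [
        DimerMotif(
            arm_consensus=kmer,
            spacer=0,
            support=support,
            expected_support=rate * n_windows,
            background_rate=min(rate, 1.0),
            enrichment=float(np.log2(support / (rate * n_windows))),
            p_value=binom_p(support, rate),
        )
        for kmer, support, rate in scored
    ]
    results.sort(key=lambda m: (m.p_value, -m.enrichment, m.arm_consensus))
    return results[:top_n]
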