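"""Inverted-repeat scanner vs exhaustive oracle; discovery recovery."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from soxtarget.motif import (
    dinucleotide_shuffle,
    discover_dimers,
    kmer_enrichment,
    reverse_complement,
    scan_inverted_repeat,
    summit_flank_fraction,
)
from soxtarget.models import Peak


def oracle_scan(seq: str, arm: str, spacers, max_mismatch: int):
    """Brute-force re-scan: check every offset and spacer by character."""
    seq = seq.upper()
    arm2 = reverse_complement(arm)
    hits = []
    for spacer in spacers:
        total = len(arm) * 2 + spacer
        for i in range(len(seq) - total + 1):
            a1 = seq[i : i + len(arm)]
            a2 = seq[i + len(arm) + spacer : i + total]
            if "N" in a1 or "N" in a2:
                continue
            m1 = sum(x != y for x, y in zip(a1, arm))
            m2 = sum(x != y for x, y in zip(a2, arm2))
            if m1 <= max_mismatch and m2 <= max_mismatch:
                hits.append((i, spacer, m1 + m2))
    return sorted(hits)


def random_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


class TestScanner:
    def test_canonical_dimer_matched_once(self):
        hits = scan_inverted_repeat("ACAAAGTGCACTTTGT")
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.spacer, hit.mismatches, hit.offset) == (4, 0, 0)
        assert hit.arm1_seq == "ACAAAG" and hit.arm2_seq == "CTTTGT"

    def test_structure_is_self_complementary(self):
        seq = "TTACAAAGTGCACTTTGTCC"
        assert len(scan_inverted_repeat(seq)) == \
            len(scan_inverted_repeat(reverse_complement(seq)))

    def test_n_never_matches(self):
        assert scan_inverted_repeat("ACAAANTGCACTTTGT", max_mismatch=1) == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            scan_inverted_repeat("ACAAAGXXXACTTTGT")

    @pytest.mark.parametrize("max_mismatch,spacer_range",
                             [(0, (4, 4)), (1, (3, 5)), (2, (0, 6))])
    def test_equals_exhaustive_oracle_on_random_sequences(
        self, rng, max_mismatch, spacer_range
    ):
        spacers = range(spacer_range[0], spacer_range[1] + 1)
        for trial in range(20):
            seq = random_seq(rng, 2000)
            if trial % 3 == 0:  # make hits likely
                pos = int(rng.integers(0, 1900))
                seq = seq[:pos] + "ACAAAGTGCACTTTGT" + seq[pos + 16 :]
            hits = scan_inverted_repeat(
                seq, spacer_range=spacer_range, max_mismatch=max_mismatch
            )
            got = sorted((h.offset, h.spacer, h.mismatches) for h in hits)
            assert got == oracle_scan(seq, "ACAAAG", spacers, max_mismatch)

    @given(hst.text(alphabet="ACGTN", min_size=16, max_size=300),
           hst.integers(min_value=0, max_value=1))
    @settings(max_examples=100, deadline=None)
    def test_hit_count_invariant_under_reverse_complement(self, seq, mm):
        forward = scan_inverted_repeat(seq, max_mismatch=mm)
        backward = scan_inverted_repeat(reverse_complement(seq), max_mismatch=mm)
        assert len(forward) == len(backward)


class TestSummitFlankFraction:
    def _peaks_and_genome(self, rng, n_peaks, n_with_motif, flank=100):
        chrom_len = n_peaks * 600
        seq = list(random_seq(rng, chrom_len))
        peaks = []
        for i in range(n_peaks):
            summit = i * 600 + 300
            if i < n_with_motif:
                start = summit - 20
                seq[start : start + 16] = list("ACAAAGTGCACTTTGT")
            peaks.append(Peak("chr1", summit - 100, summit + 100, summit,
                              3.0, 1e-9, peak_id=f"p{i:03d}"))
        genome = {"chr1": "".join(seq)}
        # scrub chance dimers near summits that should be negative
        for i in range(n_with_motif, n_peaks):
            summit = i * 600 + 300
            window = genome["chr1"][summit - 116 : summit + 116]
            for h in scan_inverted_repeat(window):
                pos = summit - 116 + h.offset
                genome["chr1"] = (genome["chr1"][:pos] + "C"
                                  + genome["chr1"][pos + 1 :])
        return peaks, genome

    def test_planted_fraction_recovered_exactly(self, rng):
        peaks, genome = self._peaks_and_genome(rng, 50, 37)
        fraction, flags, _ = summit_flank_fraction(peaks, genome)
        assert sum(flags.values()) == 37
        assert fraction == pytest.approx(0.74)

    def test_zero_flank_counts_only_summit_spanning_patterns(self, rng):
        peaks, genome = self._peaks_and_genome(rng, 10, 10)
        fraction, flags, hits = summit_flank_fraction(peaks, genome, flank=0)
        assert fraction == 0.0  # planted 20 bp away from each summit

    def test_motif_free_genome_fraction_near_analytic_background(self, rng):
        """Expected dimer rate in a 201-bp window is ~1.1e-5 (186 positions
        x 4^-12), so 200 windows should essentially never hit."""
        peaks, genome = self._peaks_and_genome(rng, 200, 0)
        fraction, _, _ = summit_flank_fraction(peaks, genome)
        assert fraction == 0.0

    def test_off_chromosome_summit_rejected(self, rng):
        peaks, genome = self._peaks_and_genome(rng, 5, 0)
        bad = Peak("chr1", 0, 10**7, 10**6 - 1, 3.0, 1e-9, peak_id="bad")
        with pytest.raises(ValueError, match="outside chromosome"):
            summit_flank_fraction(peaks + [bad], genome)


class TestShuffle:
    def test_dinucleotide_counts_preserved(self, rng):
        gen = np.random.default_rng(5)
        for _ in range(20):
            seq = random_seq(rng, 150)
            shuf = dinucleotide_shuffle(seq, gen)
            assert len(shuf) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_shuffle_actually_permutes(self, rng):
        gen = np.random.default_rng(6)
        seq = random_seq(rng, 300)
        assert any(dinucleotide_shuffle(seq, gen) != seq for _ in range(5))


class TestDiscovery:
    def _windows(self, rng, n, planted_fraction, pattern="ACAAAGTGCACTTTGT"):
        windows = []
        n_planted = int(round(planted_fraction * n))
        for i in range(n):
            w = random_seq(rng, 201)
            if i < n_planted:
                pos = int(rng.integers(0, 201 - len(pattern)))
                w = w[:pos] + pattern + w[pos + len(pattern) :]
            windows.append(w)
        return windows

    def test_planted_dimer_ranks_first(self, rng):
        windows = self._windows(rng, 200, 0.74)
        motifs = discover_dimers(windows, n_shuffles=3, seed=11)
        top = motifs[0]
        assert top.arm_consensus == "ACAAAG"
        assert top.spacer == 4
        assert top.support >= 0.7 * 200

    def test_two_planted_dimers_both_rank_high(self, rng):
        a = self._windows(rng, 100, 1.0, pattern="ACAAAGTGCACTTTGT")
        b = self._windows(rng, 100, 1.0, pattern="TTGCCAAGGATGGCAA")  # TTGCCA arm, spacer 4
        motifs = discover_dimers(a + b, n_shuffles=3, seed=12)
        top5 = {(m.arm_consensus, m.spacer) for m in motifs[:5]}
        assert ("ACAAAG", 4) in top5
        assert (min("TTGCCA", reverse_complement("TTGCCA")), 4) in top5

    def test_pure_random_windows_show_no_bonferroni_hit(self, rng):
        n_arms = 4**6 / 2 * 3  # rc-collapsed arms x spacers tested
        for seed in range(5):
            windows = self._windows(np.random.default_rng(100 + seed), 150, 0.0)
            motifs = discover_dimers(windows, n_shuffles=5, seed=seed)
            significant = [m for m in motifs if m.p_value < 0.05 / n_arms]
            assert not significant

    def test_all_n_windows_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            discover_dimers(["N" * 50, "N" * 50])


class TestKmerEnrichment:
    def test_planted_8mer_recovered_in_top_ranks(self, rng):
        pattern = "ACTGTGGT"  # RUNX-like core embedded in an 8-mer
        windows = []
        for i in range(300):
            w = random_seq(rng, 120)
            if i < 51:  # 17% of windows
                pos = int(rng.integers(0, 120 - 8))
                w = w[:pos] + pattern + w[pos + 8 :]
            windows.append(w)
        motifs = kmer_enrichment(windows, k=8, n_shuffles=3, seed=21,
                                 collapse=False)
        assert pattern in [m.arm_consensus for m in motifs[:10]]

    def test_degenerate_collapsing_merges_single_mismatch_variants(self, rng):
        windows = []
        for i in range(200):
            w = random_seq(rng, 100)
            pattern = "ATGAATGG" if i % 2 else "CTGAATGG"
            pos = int(rng.integers(0, 100 - 8))
            windows.append(w[:pos] + pattern + w[pos + 8 :])
        motifs = kmer_enrichment(windows, k=8, n_shuffles=3, seed=22)
        top = motifs[0]
        assert top.arm_consensus == "MTGAATGG"  # M = A/C
        assert top.support == 200

    def test_k_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmer_enrichment(["ACGTACGT"], k=20)

    def test_uniform_random_windows_calibrated(self, rng):
        windows = [random_seq(rng, 100) for _ in range(150)]
        motifs = kmer_enrichment(windows, k=8, n_shuffles=5, seed=23,
                                 collapse=False)
        n_kmers = 4**8
        assert all(m.p_value >= 0.05 / n_kmers for m in motifs)
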