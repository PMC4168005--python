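"""Tag-count differential expression: normalization, z, floor, fold bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from soxtarget import SyntheticConfig, generate_count_table, generate_genome
from soxtarget.expression import (
    apply_floor,
    bin_by_fold,
    differential_expression,
    normalize,
    z_score,
)


class TestNormalize:
    def test_reference_gene_maps_to_unity(self, small_counts):
        out = normalize(small_counts, "Actb")
        ref = out[out["gene_id"] == "Actb"].iloc[0]
        assert ref["norm_control"] == 1.0 and ref["norm_treated"] == 1.0

    def test_simple_arithmetic(self, small_counts):
        out = normalize(small_counts, "Actb")
        gene = out[out["gene_id"] == "geneA"].iloc[0]
        assert gene["norm_control"] == pytest.approx(0.8)
        assert gene["norm_treated"] == pytest.approx(0.1)

    @given(scale=hst.integers(min_value=1, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_normalized_ratio_invariant_under_library_scaling(self, scale):
        """Multiplying every count in one condition by a constant leaves
        reference-normalized values of that condition unchanged."""
        table = pd.DataFrame(
            {
                "gene_id": ["ref", "a", "b"],
                "tags_control": [1000, 800, 50],
                "tags_treated": [2000, 100, 75],
            }
        )
        scaled = table.copy()
        scaled["tags_treated"] *= scale
        base = normalize(table, "ref")
        after = normalize(scaled, "ref")
        np.testing.assert_allclose(
            base["norm_treated"], after["norm_treated"], rtol=1e-12
        )
        np.testing.assert_allclose(
            base["norm_control"], after["norm_control"], rtol=1e-12
        )

    def test_missing_or_zero_reference_rejected(self, small_counts):
        with pytest.raises(ValueError, match="not in table"):
            normalize(small_counts, "nope")
        zero = small_counts.copy()
        zero.loc[zero["gene_id"] == "Actb", "tags_control"] = 0
        with pytest.raises(ValueError, match="positive tags"):
            normalize(zero, "Actb")


class TestZScore:
    def test_equal_proportions_give_zero(self):
        assert z_score(100, 200, 1000, 2000) == 0.0
        assert z_score(0, 0, 1000, 2000) == 0.0

    def test_total_loss_of_an_expressed_gene_is_significant(self):
        assert abs(z_score(100, 0, 1_000_000, 1_000_000)) > 4.0

    def test_matches_pooled_two_proportion_oracle_on_grid(self):
        """Against statsmodels' pooled two-proportion z on a small grid."""
        from statsmodels.stats.proportion import proportions_ztest

        for x1 in (1, 5, 20, 100):
            for x2 in (0, 3, 50):
                if x1 == x2:
                    continue
                n1, n2 = 10_000, 20_000
                expected, _ = proportions_ztest(
                    [x1, x2], [n1, n2], alternative="two-sided"
                )
                assert z_score(x1, x2, n1, n2) == pytest.approx(
                    expected, abs=1e-12
                )


class TestFloor:
    def test_absolute_mode_requires_strictly_more_than_100_tags(self, small_counts):
        out = apply_floor(small_counts, "Col2a1", mode="absolute")
        flags = dict(zip(out["gene_id"], out["passes_floor"]))
        assert not flags["geneC"]  # exactly 100 tags: not strictly greater
        assert flags["geneB"]  # 101 tags passes
        assert flags["Col2a1"]

    def test_fraction_mode_threshold_tracks_marker(self, small_counts):
        # 0.06% of 158,000 = 94.8; genes at 100 and 101 both pass
        out = apply_floor(small_counts, "Col2a1", mode="fraction")
        assert out.attrs["floor_threshold"] == pytest.approx(94.8)
        flags = dict(zip(out["gene_id"], out["passes_floor"]))
        assert flags["geneC"] and flags["geneB"]

    def test_missing_marker_rejected(self, small_counts):
        with pytest.raises(ValueError, match="marker"):
            apply_floor(small_counts, "nope")


class TestFoldBins:
    def _results(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "fold_change": [8.2, 5.0, 3.5, 9.0, 2.5],
                "direction": ["decrease", "decrease", "increase",
                              "decrease", "decrease"],
                "z": [10.0, 8.0, 6.0, 3.0, -7.0],
                "passes_floor": [True, True, True, True, False],
            }
        )

    def test_high_fold_gene_enters_every_bin_of_its_direction(self):
        bins = bin_by_fold(self._results())
        for t in (2.0, 3.0, 4.0, 6.0, 8.0):
            assert "a" in bins[("decrease", t)]

    def test_intermediate_fold_stops_at_its_threshold(self):
        bins = bin_by_fold(self._results())
        assert "b" in bins[("decrease", 4.0)]
        assert "b" not in bins[("decrease", 6.0)]

    def test_z_and_floor_gates_exclude(self):
        bins = bin_by_fold(self._results())
        # d fails |z| > 4, e fails the floor (note |z| of -7 passes)
        for members in bins.values():
            assert "d" not in members and "e" not in members

    def test_bins_nest_and_directions_are_disjoint(self, default_sim):
        de = differential_expression(default_sim["counts"], "g0000", "g0001")
        bins = bin_by_fold(de)
        for direction in ("decrease", "increase"):
            sizes = [len(bins[(direction, t)]) for t in (2, 3, 4, 6, 8)]
            assert sizes == sorted(sizes, reverse=True)
            for t in (3.0, 4.0, 6.0, 8.0):
                assert set(bins[(direction, t)]) <= set(bins[(direction, 2.0)])
        assert not set(bins[("decrease", 2.0)]) & set(bins[("increase", 2.0)])

    def test_bin_counts_equal_brute_force_recount(self, default_sim):
        de = differential_expression(default_sim["counts"], "g0000", "g0001")
        bins = bin_by_fold(de)
        for (direction, t), members in bins.items():
            brute = [
                row.gene_id
                for row in de.itertuples(index=False)
                if row.fold_change >= t
                and row.direction == direction
                and abs(row.z) > 4.0
                and row.passes_floor
            ]
            assert sorted(members) == sorted(brute)


class TestPlantedRecovery:
    def test_planted_fold8_decrease_measured_near_its_level(self, default_sim):
        """A gene planted in the fold-8 decrease bin shows an empirical
        normalized fold inside a 4-SD sampling interval around its planted
        ratio (delta-method SD on the log fold from the four tag counts)."""
        de = differential_expression(default_sim["counts"], "g0000", "g0001")
        truth = default_sim["truth"]
        ref = de[de["gene_id"] == "g0000"].iloc[0]
        planted = [
            gid for gid, (level, d) in truth.gene_fold.items()
            if level == 8.0 and d == "decrease"
        ]
        assert planted
        for gid in planted:
            row = de[de["gene_id"] == gid].iloc[0]
            assert row["direction"] == "decrease"
            sd = np.sqrt(
                1 / row["tags_control"] + 1 / row["tags_treated"]
                + 1 / ref["tags_control"] + 1 / ref["tags_treated"]
            )
            ratio = truth.gene_ratio[gid]
            assert abs(np.log(row["fold_change"] / ratio)) < 4 * sd
            # and the fold remains unambiguously in the 8-fold regime
            assert row["fold_change"] >= 8.0

    def test_reference_gene_fold_near_unity(self, default_sim):
        de = differential_expression(default_sim["counts"], "g0000", "g0001")
        ref = de[de["gene_id"] == "g0000"].iloc[0]
        assert ref["fold_change"] == pytest.approx(1.0, abs=1e-9)

    def test_null_tables_exceed_z4_at_most_nominal_rate(self):
        """Without planted effects the |z| > 4 rate stays within the
        two-sided normal tail at 4, up to Monte-Carlo error."""
        from scipy.stats import norm

        config = SyntheticConfig(
            seed=7, planted_fold_levels=(), genes_per_level=0, n_genes=30
        )
        _, genes = generate_genome(config)
        n_tests = 0
        n_hits = 0
        for seed in range(25):
            cfg = SyntheticConfig(
                seed=seed, planted_fold_levels=(), genes_per_level=0, n_genes=30
            )
            table, truth = generate_count_table(genes, cfg)
            assert not truth.gene_fold
            de = differential_expression(table, "g0000", "g0001")
            n_tests += len(de)
            n_hits += int((de["z"].abs() > 4.0).sum())
        nominal = 2 * norm.sf(4.0)
        bound = nominal + 3 * np.sqrt(nominal / n_tests)
        assert n_hits / n_tests <= bound
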