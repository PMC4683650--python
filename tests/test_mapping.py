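"""Segregation testing, recombinant counting and interval delimitation."""

import numpy as np
import pandas as pd
import pytest

from indelmark.mapping import (
    F2LinkageModel,
    count_recombinant_gametes,
    delimit_interval,
    deletion_span,
    detect_deletion,
    linkage_scan,
    segregation_chi_square,
)
from indelmark.simulate import F2SimSpec, simulate_f2, simulate_mutant_class


class TestSegregation:
    def test_published_f2_statistic(self):
        test = segregation_chi_square(124, 511)
        assert test.chi_square == pytest.approx(0.147, abs=0.001)
        assert test.consistent and test.p_value > 0.5

    def test_exact_three_to_one_is_zero(self):
        assert segregation_chi_square(128, 512).chi_square == 0.0

    def test_hand_evaluated_example(self):
        # (90-100)^2/100 + (310-300)^2/300 = 1 + 1/3
        assert segregation_chi_square(90, 400).chi_square == pytest.approx(4 / 3)

    def test_inconsistent_when_far_from_ratio(self):
        assert not segregation_chi_square(250, 400).consistent

    def test_obs_exp_swap_is_not_symmetric_in_general(self):
        """Swapping observed and expected in each class changes the statistic
        except in the balanced half-half case."""
        n_mut, n_tot = 90, 400
        exp_mut, exp_wild = n_tot / 4, 3 * n_tot / 4
        obs_wild = n_tot - n_mut
        forward = (n_mut - exp_mut) ** 2 / exp_mut + (obs_wild - exp_wild) ** 2 / exp_wild
        swapped = (exp_mut - n_mut) ** 2 / n_mut + (exp_wild - obs_wild) ** 2 / obs_wild
        assert forward != pytest.approx(swapped)
        # balanced case: observed equals expected at n/2 each, both sides zero
        balanced = segregation_chi_square(200, 400, expected_ratio=(1, 1))
        assert balanced.chi_square == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            segregation_chi_square(10, 5)


class TestRecombinantCounting:
    def test_all_homozygous_mutant_parent(self):
        rec, inf = count_recombinant_gametes(["A"] * 22)
        assert (rec, inf) == (0, 44)

    def test_per_gamete_enumeration(self):
        assert count_recombinant_gametes(["A", "H", "B"]) == (3, 6)

    def test_six_het_plants_give_six_recombinants(self):
        codes = ["H"] * 6 + ["A"] * 16
        assert count_recombinant_gametes(codes) == (6, 44)

    def test_missing_uninformative(self):
        assert count_recombinant_gametes(["A", np.nan, "B"]) == (2, 4)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            count_recombinant_gametes(["A", "X"])


@pytest.fixture(scope="module")
def f2_scenario():
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"M{i:02d}" for i in range(21)],
            "chrom": "chr01",
            "pos": np.arange(21) * 500_000 + 1,
        }
    )
    spec = F2SimSpec(
        marker_map=marker_map, causal_chrom="chr01", causal_pos=5_230_000,
        chrom_lengths={"chr01": 10_500_001}, cm_per_mb=2.5, n_plants=511, seed=17,
    )
    return simulate_f2(spec)


class TestLinkageScan:
    def test_counts_equal_brute_force_recount(self, f2_scenario):
        mutants = f2_scenario.genotypes[f2_scenario.phenotypes == "mutant"]
        scan = linkage_scan(mutants, f2_scenario.marker_map)
        per_code = {"A": 0, "H": 1, "B": 2}
        for _, row in scan.iterrows():
            codes = mutants[row["marker_id"]].dropna()
            assert row["recombinants"] == sum(per_code[c] for c in codes)
            assert row["informative"] == 2 * len(codes)

    def test_unlinked_marker_near_half(self):
        marker_map = pd.DataFrame({"marker_id": ["U"], "chrom": ["chr02"], "pos": [1_000_000]})
        spec = F2SimSpec(
            marker_map=marker_map, causal_chrom="chr01", causal_pos=500_000,
            chrom_lengths={"chr01": 1_000_000, "chr02": 2_000_000},
            n_plants=4_000, seed=19,
        )
        scenario = simulate_mutant_class(spec, 4_000)
        scan = linkage_scan(scenario.genotypes, marker_map)
        frac = scan.loc[0, "fraction"]
        sigma = np.sqrt(0.25 / scan.loc[0, "informative"])
        assert abs(frac - 0.5) <= 3 * sigma

    def test_marker_at_locus_fraction_zero(self, f2_scenario):
        mutants = f2_scenario.genotypes[f2_scenario.phenotypes == "mutant"]
        scan = linkage_scan(mutants, f2_scenario.marker_map).set_index("marker_id")
        # M10 and M11 bracket the locus tightly; the nearest marker has near-zero fraction
        assert scan["fraction"].min() <= scan.loc["M10", "fraction"]


class TestDelimitInterval:
    def _scan(self, counts, positions):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(counts))],
                "chrom": "c",
                "pos": positions,
                "recombinants": counts,
                "informative": [44] * len(counts),
                "fraction": [c / 44 for c in counts],
            }
        )

    def test_rule_evaluation_by_hand(self):
        scan = self._scan([5, 2, 0, 3], [1_000_000, 2_000_000, 3_000_000, 4_000_000])
        interval = delimit_interval(scan, "c")
        assert (interval.left_marker, interval.right_marker) == ("m1", "m3")
        assert interval.length == 2_000_000

    def test_all_zero_open_both_sides(self):
        scan = self._scan([0, 0, 0], [1, 2, 3])
        interval = delimit_interval(scan, "c")
        assert interval.open_left and interval.open_right
        assert np.isnan(interval.length)

    def test_minimum_at_edge_open_one_side(self):
        scan = self._scan([0, 1, 4], [1, 2, 3])
        interval = delimit_interval(scan, "c")
        assert interval.open_left and not interval.open_right
        assert interval.right_marker == "m1"

    def test_simulated_interval_contains_true_locus(self, f2_scenario):
        mutants = f2_scenario.genotypes[f2_scenario.phenotypes == "mutant"]
        scan = linkage_scan(mutants, f2_scenario.marker_map)
        interval = delimit_interval(scan, "chr01")
        assert interval.left_pos <= 5_230_000 <= interval.right_pos

    def test_interval_recovery_rate_over_replicates(self):
        """On 124-mutant populations with markers every ~500 kb at 2.5 cM/Mb,
        the delimited interval contains the true locus in >= 95% of runs."""
        marker_map = pd.DataFrame(
            {"marker_id": [f"M{i:02d}" for i in range(21)], "chrom": "chr01",
             "pos": np.arange(21) * 500_000 + 1}
        )
        spec = F2SimSpec(
            marker_map=marker_map, causal_chrom="chr01", causal_pos=5_230_000,
            chrom_lengths={"chr01": 10_500_001}, cm_per_mb=2.5, n_plants=496, seed=0,
        )
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            scenario = simulate_mutant_class(spec, 124, seed=10_000 + rep)
            scan = linkage_scan(scenario.genotypes, marker_map)
            interval = delimit_interval(scan, "chr01")
            if not (interval.open_left or interval.open_right):
                if interval.left_pos <= 5_230_000 <= interval.right_pos:
                    hits += 1
        assert hits / n_reps >= 0.95

    def test_recombinants_monotone_in_distance(self):
        """Mean recombinant count at 20 cM exceeds the mean at 5 cM (200 replicates)."""
        marker_map = pd.DataFrame(
            {"marker_id": ["near", "far"], "chrom": "c", "pos": [3_000_000, 13_000_000]}
        )
        spec = F2SimSpec(
            marker_map=marker_map, causal_chrom="c", causal_pos=5_000_000,
            chrom_lengths={"c": 14_000_000}, cm_per_mb=2.5, n_plants=100, seed=0,
        )
        near_means, far_means = [], []
        for rep in range(200):
            scenario = simulate_mutant_class(spec, 25, seed=20_000 + rep)
            scan = linkage_scan(scenario.genotypes, marker_map).set_index("marker_id")
            near_means.append(scan.loc["near", "recombinants"])
            far_means.append(scan.loc["far", "recombinants"])
        assert np.mean(far_means) > np.mean(near_means)


class TestDeletion:
    def test_span_arithmetic(self):
        assert deletion_span(2_118_557, 2_371_744) == (253_187, 253)

    def test_identical_boundaries_zero_span(self):
        assert deletion_span(5, 5) == (0, 0)

    def test_no_failed_markers_no_candidate(self):
        markers = pd.DataFrame(
            {"marker_id": ["a", "b"], "chrom": "c", "pos": [1, 2], "failed": [False, False]}
        )
        assert detect_deletion(markers) is None

    def test_longest_consecutive_run_reported(self):
        markers = pd.DataFrame(
            {
                "marker_id": list("abcdefg"),
                "chrom": "c",
                "pos": range(1, 8),
                "failed": [True, False, True, True, True, False, True],
            }
        )
        candidate = detect_deletion(markers, boundaries=(2_118_557, 2_371_744))
        assert candidate.marker_ids == ["c", "d", "e"]
        assert candidate.span_bp == 253_187 and candidate.span_kb == 253


class TestModel:
    def test_fit_recovers_locus_and_reports(self, f2_scenario):
        results = F2LinkageModel(f2_scenario.table(), f2_scenario.marker_map).fit()
        assert results.best_chromosome == "chr01"
        assert results.segregation.consistent
        assert results.interval.left_pos <= 5_230_000 <= results.interval.right_pos
        text = results.summary()
        assert "delimited interval" in text

    def test_requires_mutants(self, f2_scenario):
        table = f2_scenario.table().copy()
        table["phenotype"] = "wild-type"
        with pytest.raises(ValueError):
            F2LinkageModel(table, f2_scenario.marker_map)

    def test_tsv_round_trip(self, f2_scenario, tmp_path):
        from indelmark import io as iio

        pop_path = tmp_path / "pop.tsv"
        map_path = tmp_path / "map.tsv"
        iio.write_tsv(f2_scenario.table(), pop_path)
        f2_scenario.marker_map.to_csv(map_path, sep="\t", index=False)
        results = F2LinkageModel.from_tsv(pop_path, map_path).fit()
        direct = F2LinkageModel(f2_scenario.table(), f2_scenario.marker_map).fit()
        pd.testing.assert_frame_equal(results.scan, direct.scan)
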