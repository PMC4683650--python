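"""Generator contracts: determinism, declared sizes, rate calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from indelmark.simulate import (
    F2SimSpec,
    GenomeModel,
    PanelScenario,
    SimulationConfig,
    haldane_r,
    inject_deletion,
    simulate_f2,
    simulate_mutant_class,
    simulate_panel,
    simulate_reference,
    simulate_variant_calls,
)


class TestReference:
    def test_declared_lengths(self):
        model = GenomeModel(lengths={"a": 50_000, "b": 20_000})
        ref = simulate_reference(model, seed=0)
        assert {name: len(seq) for name, seq in ref.items()} == {"a": 50_000, "b": 20_000}

    def test_same_seed_identical(self, small_genome):
        a = simulate_reference(small_genome, seed=3)
        b = simulate_reference(small_genome, seed=3)
        assert a == b

    def test_different_seed_differs(self, small_genome):
        assert simulate_reference(small_genome, seed=3) != simulate_reference(small_genome, seed=4)

    def test_gc_within_binomial_bound(self):
        # 1 Mb at GC 0.5: 3 sigma of a binomial mean is well under +-0.01
        model = GenomeModel(lengths={"a": 1_000_000}, gc=0.5)
        seq = simulate_reference(model, seed=5)["a"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeModel(lengths={"a": 0})

    def test_pericentromere_must_fit(self):
        with pytest.raises(ValueError):
            GenomeModel(lengths={"a": 100}, pericentromere={"a": (50, 200)})


class TestVariantCalls:
    def test_zero_indel_rate(self, reference):
        sim = simulate_variant_calls(reference, SimulationConfig(indel_rate=0.0, snp_rate=1e-4, seed=1))
        assert not (sim.ledger["kind"] != "snp").any()

    def test_zero_het_fraction(self, reference):
        sim = simulate_variant_calls(reference, SimulationConfig(het_fraction=0.0, seed=1))
        assert (sim.ledger["genotype"] == "hom").all()

    def test_indel_count_poisson_bound(self):
        # 10 Mb at 5e-5 per bp: expect ~500 INDELs within 3 sigma
        model = GenomeModel(lengths={"a": 10_000_000})
        ref = simulate_reference(model, seed=2)
        sim = simulate_variant_calls(ref, SimulationConfig(indel_rate=5e-5, snp_rate=0.0, seed=2))
        n = int((sim.ledger["kind"] != "snp").sum())
        assert abs(n - 500) <= 3 * np.sqrt(500)

    def test_ledger_matches_brute_force_recount(self, sim_variants):
        """Ledger counts equal recounts of the emitted records per category."""
        calls, ledger = sim_variants
        assert len(calls) == len(ledger)
        assert int(ledger["unanchored"].sum()) == sum(c.unanchored for c in calls)
        assert int((ledger["genotype"] == "het").sum()) == sum(c.genotype == "het" for c in calls)
        is_indel = [len(c.ref) != max(len(a) for a in c.alts) or
                    any(len(a) != len(c.ref) for a in c.alts) for c in calls]
        assert int((ledger["kind"] != "snp").sum()) == sum(is_indel)

    def test_same_seed_byte_identical(self, reference):
        cfg = SimulationConfig(seed=9)
        a = simulate_variant_calls(reference, cfg)
        b = simulate_variant_calls(reference, cfg)
        assert a.calls == b.calls
        pd.testing.assert_frame_equal(a.ledger, b.ledger)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(indel_rate=1.5)


class TestPanel:
    def test_no_third_allele_no_missing(self, marker_table):
        panel = simulate_panel(marker_table, n_cultivars=6, third_allele_rate=0.0,
                               missing_rate=0.0, seed=1)
        n_alleles = panel.genotypes.apply(lambda r: r.dropna().nunique(), axis=1)
        assert (n_alleles == 2).all()
        assert not panel.genotypes.isna().any().any()

    def test_all_missing(self, marker_table):
        panel = simulate_panel(marker_table, n_cultivars=4, missing_rate=1.0, seed=1)
        assert panel.genotypes.isna().all().all()

    def test_third_allele_binomial_calibration(self, marker_table):
        # 165 markers at the default third-allele rate: expect ~14 +- 3 sigma
        markers = pd.concat([marker_table] * 5, ignore_index=True).iloc[:165].copy()
        markers["marker_id"] = [f"T{i}" for i in range(165)]
        panel = simulate_panel(markers, n_cultivars=14, third_allele_rate=14 / 165,
                               missing_rate=0.0, seed=4)
        n3 = int(panel.truth["has_third_allele"].sum())
        sigma = np.sqrt(165 * (14 / 165) * (1 - 14 / 165))
        assert abs(n3 - 14) <= 3 * sigma

    def test_rejects_single_cultivar(self, marker_table):
        with pytest.raises(ValueError):
            simulate_panel(marker_table, n_cultivars=1)


@pytest.fixture(scope="module")
def f2_spec():
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"M{i:02d}" for i in range(11)],
            "chrom": "chr01",
            "pos": np.arange(11) * 1_000_000 + 1,
        }
    )
    return F2SimSpec(
        marker_map=marker_map, causal_chrom="chr01", causal_pos=5_000_001,
        chrom_lengths={"chr01": 11_000_000}, cm_per_mb=2.5, n_plants=511, seed=6,
    )


class TestF2:
    def test_mutant_fraction_binomial(self, f2_spec):
        scenario = simulate_f2(f2_spec)
        n_mut = int((scenario.phenotypes == "mutant").sum())
        sigma = np.sqrt(511 * 0.25 * 0.75)
        assert abs(n_mut - 127.75) <= 3 * sigma

    def test_marker_at_locus_zero_recombinants(self, f2_spec):
        scenario = simulate_f2(f2_spec)
        mutants = scenario.genotypes[scenario.phenotypes == "mutant"]
        # M05 sits exactly at the causal locus
        assert (mutants["M05"] == "A").all()

    def test_haldane_fraction_at_10cM(self):
        # marker 4 Mb from the locus at 2.5 cM/Mb = 10 cM -> r = (1 - e^-0.2)/2
        marker_map = pd.DataFrame({"marker_id": ["MX"], "chrom": ["c"], "pos": [1_000_000]})
        spec = F2SimSpec(marker_map=marker_map, causal_chrom="c", causal_pos=5_000_000,
                         chrom_lengths={"c": 6_000_000}, cm_per_mb=2.5, n_plants=10_000, seed=8)
        scenario = simulate_mutant_class(spec, 10_000)
        codes = scenario.genotypes["MX"].map({"A": 0, "H": 1, "B": 2})
        frac = codes.sum() / (2 * len(codes))
        r = (1 - np.exp(-0.2)) / 2
        sigma = np.sqrt(r * (1 - r) / (2 * len(codes)))
        assert abs(frac - r) <= 3 * sigma

    def test_haldane_closed_form(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(np.inf) == pytest.approx(0.5)
        assert haldane_r(0.1) == pytest.approx((1 - np.exp(-0.2)) / 2)

    def test_rejects_offchromosome_locus(self, f2_spec):
        with pytest.raises(ValueError):
            F2SimSpec(marker_map=f2_spec.marker_map, causal_chrom="c99", causal_pos=1,
                      chrom_lengths={"chr01": 11_000_000}, n_plants=10)

    def test_determinism(self, f2_spec):
        a = simulate_f2(f2_spec)
        b = simulate_f2(f2_spec)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)


class TestInjectDeletion:
    def _panel(self, marker_table) -> PanelScenario:
        panel = simulate_panel(marker_table, n_cultivars=5, third_allele_rate=0.0,
                               missing_rate=0.0, seed=2)
        panel.markers["footprint_start"] = panel.markers["pos"] - 100
        panel.markers["footprint_end"] = panel.markers["pos"] + 100
        return panel

    def test_empty_region_unchanged(self, marker_table):
        panel = self._panel(marker_table)
        modified, failed = inject_deletion(panel, "chr01", 10, 5)
        assert failed == []
        pd.testing.assert_frame_equal(modified.genotypes, panel.genotypes)

    def test_exact_containment(self, marker_table):
        panel = self._panel(marker_table)
        covered = panel.markers.iloc[3:6]
        start = int(covered["footprint_start"].min())
        end = int(covered["footprint_end"].max())
        modified, failed = inject_deletion(panel, "chr01", start, end, carrier="cultivar03")
        inside = set(covered["marker_id"])
        assert set(failed) == inside
        assert modified.genotypes.loc[list(inside), "cultivar03"].isna().all()
        untouched = modified.genotypes.drop(index=list(inside))
        pd.testing.assert_frame_equal(untouched, panel.genotypes.drop(index=list(inside)))

    def test_footprints_fit_sequenced_span(self, marker_table):
        # a deletion with sequenced boundaries 2,118,557-2,371,744 spans 253,187 bp;
        # every failing footprint must lie inside that span
        panel = self._panel(marker_table)
        shift = 2_118_557
        panel.markers["footprint_start"] += shift
        panel.markers["footprint_end"] += shift
        modified, failed = inject_deletion(panel, "chr01", 2_118_557, 2_371_744)
        footprints = panel.markers.set_index("marker_id").loc[failed]
        assert (footprints["footprint_start"] >= 2_118_557).all()
        assert (footprints["footprint_end"] <= 2_371_744).all()
        assert (footprints["footprint_end"] - footprints["footprint_start"] <= 253_187).all()
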