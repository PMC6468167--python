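"""Generator contracts: genomes, planted events, profiles, assays."""

import math

import numpy as np
import pytest

import oxloh as ox
from oxloh.synthetic_data import (
    InvalidConfigError,
    InvalidEventError,
    dosage_centroid,
    sample_events,
)


class TestBuildGenome:
    def test_two_chromosome_config(self):
        g = ox.build_genome(
            {"chromosomes": [("c1", 1000.0, 400.0), ("c2", 1000.0, 500.0)],
             "markers_per_chrom": 100},
            seed=0,
        )
        assert g.n_markers == 200
        for chrom in ("c1", "c2"):
            pos = g.marker_positions(chrom)
            assert len(pos) == 100
            assert np.all(np.diff(pos) > 0)

    def test_default_preset_marker_count_and_size(self, full_genome):
        assert full_genome.n_markers == 15_000
        assert len(full_genome.chromosomes) == 16
        assert full_genome.total_kb == pytest.approx(12_000, rel=0.05)
        # rDNA is one interval and a ~7.6% genome fraction
        assert len(full_genome.features["rDNA"]) == 1
        assert full_genome.rdna_fraction() == pytest.approx(0.076, abs=0.002)

    def test_determinism(self):
        a = ox.build_genome("default", seed=5)
        b = ox.build_genome("default", seed=5)
        assert np.array_equal(a.markers["pos_kb"], b.markers["pos_kb"])

    @pytest.mark.parametrize("bad", [
        {"chromosomes": [("c1", -5.0, 1.0)], "markers_per_chrom": 10},
        {"chromosomes": [("c1", 100.0, 500.0)], "markers_per_chrom": 10},
        {"chromosomes": [("c1", 100.0, 50.0)], "n_markers": 0},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            ox.build_genome(bad, seed=0)


class TestPlantEvent:
    @pytest.fixture()
    def genome(self, small_genome):
        return small_genome

    def test_g1_co_merged_tract_has_40_and_31(self, genome):
        spec = ox.PlantedEvent("G1_DSB_CO", "chrA", break_kb=600,
                               tract_d1=12, tract_d2=20, donor="W")
        d1, d2 = ox.plant_event(genome, spec, seed=0)
        idx = genome.marker_index("chrA")
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        distal = pos > 600
        # both daughters altered distal of the break, reciprocally
        assert np.all(d1.cnW[idx][distal] == 2) and np.all(d1.cnY[idx][distal] == 0)
        assert np.all(d2.cnW[idx][distal] == 0) and np.all(d2.cnY[idx][distal] == 2)
        # merged tract: 4:0 core (both hom donor) and 3:1 flank
        in40 = (pos >= 588) & (pos <= 600)
        in31 = (pos >= 580) & (pos < 588)
        assert np.all(d1.cnW[idx][in40] + d2.cnW[idx][in40] == 4)
        assert np.all(d1.cnW[idx][in31] + d2.cnW[idx][in31] == 3)

    def test_con_only_has_no_terminal_loh(self, genome):
        spec = ox.PlantedEvent("CON_only", "chrA", break_kb=400, end_kb=430, donor="Y")
        d1, d2 = ox.plant_event(genome, spec, seed=0)
        idx = genome.marker_index("chrA")
        last = idx[-1]
        assert d1.state(last) == (1, 1) and d2.state(last) == (1, 1)

    def test_bir_is_nonreciprocal(self, genome):
        spec = ox.PlantedEvent("BIR", "chrA", break_kb=700, donor="W")
        d1, d2 = ox.plant_event(genome, spec, seed=0)
        ref = ox.DaughterGenotype.diploid(genome)
        assert np.array_equal(d2.cnW, ref.cnW) and np.array_equal(d2.cnY, ref.cnY)
        idx = genome.marker_index("chrA")
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        distal = pos >= 700
        assert np.all(d1.cnW[idx][distal] == 2) and np.all(d1.cnY[idx][distal] == 0)

    @pytest.mark.parametrize("mech", [
        "G1_DSB_CO", "G2_DSB_CO", "BIR", "CON_only", "UPD",
    ])
    def test_copy_conservation_copy_neutral_mechanisms(self, genome, mech):
        """Per-marker haplotype copies summed over both daughters equal 4."""
        kw = dict(break_kb=500.0, donor="W")
        if mech in ("G1_DSB_CO", "G2_DSB_CO"):
            kw.update(tract_d1=15.0, tract_d2=10.0)
        if mech == "CON_only":
            kw.update(end_kb=540.0)
        d1, d2 = ox.plant_event(genome, ox.PlantedEvent(mech, "chrA", **kw), seed=0)
        total = d1.cnW + d1.cnY + d2.cnW + d2.cnY
        assert np.all(total == 4)

    @pytest.mark.parametrize("mech", ["G1_DSB_CO", "G2_DSB_CO"])
    def test_reciprocity_distal_of_tract(self, genome, mech):
        spec = ox.PlantedEvent(mech, "chrA", break_kb=500, tract_d1=15,
                               tract_d2=10, donor="Y")
        d1, d2 = ox.plant_event(genome, spec, seed=0)
        idx = genome.marker_index("chrA")
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        distal = pos > 500
        d1_states = np.stack([d1.cnW[idx][distal], d1.cnY[idx][distal]], axis=1)
        d2_states = np.stack([d2.cnW[idx][distal], d2.cnY[idx][distal]], axis=1)
        assert np.all(d1_states == [0, 2]) and np.all(d2_states == [2, 0])

    @pytest.mark.parametrize("mech,total", [("trisomy", 3), ("monosomy", 1)])
    def test_aneuploidy_copy_sums(self, genome, mech, total):
        d1, _ = ox.plant_event(genome, ox.PlantedEvent(mech, "chrB", donor="W"), seed=0)
        idx = genome.marker_index("chrB")
        assert np.all(d1.cnW[idx] + d1.cnY[idx] == total)

    def test_invalid_event_rejected(self, genome):
        with pytest.raises(InvalidEventError):
            ox.plant_event(genome, ox.PlantedEvent("BIR", "chrA", break_kb=5000), seed=0)
        with pytest.raises(InvalidEventError):
            ox.PlantedEvent("no_such_mechanism", "chrA")
        with pytest.raises(InvalidEventError):
            ox.plant_event(
                genome, ox.PlantedEvent("CON_only", "chrA", break_kb=400), seed=0)


class TestRenderProfile:
    def test_noiseless_centroids(self, small_genome):
        d = ox.DaughterGenotype.diploid(small_genome)
        p = ox.render_profile(d, 0.0, seed=0)
        assert np.all(p.ratio_W == 1.0) and np.all(p.ratio_Y == 1.0)
        d.cnW[:], d.cnY[:] = 2, 0
        p = ox.render_profile(d, 0.0, seed=0)
        assert np.all(p.ratio_W == 1.5) and np.all(p.ratio_Y == 0.3)

    def test_amplification_centroids_extrapolate(self):
        assert dosage_centroid(3) == pytest.approx(1.9)
        assert dosage_centroid(4) == pytest.approx(2.3)

    def test_reproducible_and_nonnegative(self, small_genome):
        d = ox.DaughterGenotype.diploid(small_genome)
        a = ox.render_profile(d, 0.1, seed=42)
        b = ox.render_profile(d, 0.1, seed=42)
        assert np.array_equal(a.ratio_W, b.ratio_W)
        assert np.all(a.ratio_W >= 0) and np.all(a.ratio_Y >= 0)

    def test_negative_noise_rejected(self, small_genome):
        d = ox.DaughterGenotype.diploid(small_genome)
        with pytest.raises(InvalidConfigError):
            ox.render_profile(d, -0.1, seed=0)


class TestFluctuationSimulator:
    def test_zero_rate_all_zero(self):
        counts = ox.simulate_fluctuation_cultures(0.0, 1e6, 20, seed=0)
        assert np.all(counts == 0)

    def test_jackpot_skew_mean_exceeds_median(self):
        counts = ox.simulate_fluctuation_cultures(1e-5, 1e7, 1000, seed=0)
        assert counts.mean() > np.median(counts)

    def test_zero_count_probability_matches_poisson(self):
        """P(no resistant colonies) ~ exp(-m) for the number of events m."""
        rate, n_final, n_cult = 2e-7, 1e7, 1000
        m = rate * (n_final - 1)
        counts = ox.simulate_fluctuation_cultures(rate, n_final, n_cult, seed=0)
        p0 = (counts == 0).mean()
        se = math.sqrt(math.exp(-m) * (1 - math.exp(-m)) / n_cult)
        assert abs(p0 - math.exp(-m)) <= 3 * se

    def test_rate_recovered_by_median_estimator(self):
        counts = ox.simulate_fluctuation_cultures(1e-5, 1e7, 1000, seed=0)
        est = ox.estimate_rate_median(counts, 1e7)
        assert est.estimate == pytest.approx(1e-5, rel=0.30)

    def test_rate_above_one_rejected(self):
        with pytest.raises(InvalidConfigError):
            ox.simulate_fluctuation_cultures(1.5, 1e6, 10, seed=0)


class TestCircularBreakage:
    def test_zero_rate(self):
        assert ox.simulate_circular_breakage(0.0, 320, 1000, seed=0) == 0.0

    def test_half_linearized_at_lambda_l_ln2(self):
        f = ox.simulate_circular_breakage(math.log(2) / 320, 320, 200_000, seed=0)
        assert f == pytest.approx(0.5, abs=0.01)

    def test_within_3se_of_closed_form(self):
        n = 10_000
        f = ox.simulate_circular_breakage(1 / 320, 320, n, seed=1)
        expect = 1 - math.exp(-1)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(f - expect) <= 3 * se


class TestGenerateMutations:
    def test_concentrated_probs(self):
        probs = [1, 0, 0, 0, 0, 0, 0]
        recs = ox.generate_mutations(probs, 50, seed=0)
        assert (recs["mutation_class"] == "C>A").all()

    def test_uniform_counts_within_4sd(self):
        probs = [1 / 6] * 6 + [0]
        recs = ox.generate_mutations(probs, 600, seed=0)
        sd = math.sqrt(600 * (1 / 6) * (5 / 6))
        for cls in ox.SUBSTITUTION_CLASSES:
            assert abs((recs["mutation_class"] == cls).sum() - 100) <= 4 * sd

    def test_empty_and_invalid(self):
        assert len(ox.generate_mutations([1, 0, 0, 0, 0, 0, 0], 0, seed=0)) == 0
        with pytest.raises(InvalidConfigError):
            ox.generate_mutations([0.5, 0.5], 10, seed=0)
        with pytest.raises(InvalidConfigError):
            ox.generate_mutations([0.5] * 7, 10, seed=0)


class TestSampleEvents:
    def test_specs_are_valid_and_plantable(self, full_genome):
        specs = sample_events(full_genome, 40, seed=3)
        assert len(specs) == 40
        for i, s in enumerate(specs):
            d1, d2 = ox.plant_event(full_genome, s, seed=i)
            assert d1.cnW.shape == (full_genome.n_markers,)

    def test_deterministic(self, full_genome):
        a = sample_events(full_genome, 10, seed=4)
        b = sample_events(full_genome, 10, seed=4)
        assert a == b
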