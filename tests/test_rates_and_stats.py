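"""Rate estimators, corrections, positional statistics, spectra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxloh as ox
from oxloh.event_classification import RecombinationEvent, TractInterval
from oxloh.rates_and_stats import (
    DegenerateInputError,
    _lc_solve_m,
    compare_spectra,
    correct_co_con_counts,
    crossover_rate_from_sectors,
    estimate_rate_median,
    events_per_genome,
    feature_enrichment,
    fraction_g1_initiated,
    hotspot_test,
    per_isolate_summary,
    rdna_expectation,
    sector_frequency,
    tract_length_stats,
)


class TestSectorFrequency:
    def test_aerobic_iscei_frequency(self):
        r = sector_frequency(197, 39417)
        assert r.estimate == pytest.approx(5.0e-3, rel=0.01)
        assert r.cl_lo == pytest.approx(4.4e-3, rel=0.05)
        assert r.cl_hi == pytest.approx(5.7e-3, rel=0.05)

    def test_anaerobic_iscei_frequency(self):
        r = sector_frequency(118, 36403)
        assert r.estimate == pytest.approx(3.2e-3, rel=0.02)

    def test_zero_successes(self):
        r = sector_frequency(0, 1000)
        assert r.estimate == 0.0 and r.cl_lo == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateInputError):
            sector_frequency(0, 0)


class TestMedianMethod:
    def test_lea_coulson_equation_satisfied(self):
        m = _lc_solve_m(25.0)
        assert 25.0 / m - math.log(m) == pytest.approx(1.24, abs=1e-8)

    def test_monotone_in_counts(self):
        counts = ox.simulate_fluctuation_cultures(1e-5, 1e7, 60, seed=2)
        a = estimate_rate_median(counts, 1e7)
        b = estimate_rate_median(counts * 2, 1e7)
        assert b.estimate > a.estimate

    def test_all_zero_counts_flagged_upper_bound(self):
        r = estimate_rate_median([0] * 20, 1e7)
        assert r.estimate == 0.0 and "upper_bound" in r.flags
        assert r.cl_hi == pytest.approx(math.log(2) / 1e7)

    def test_median_unbiased_against_continuous_ld_oracle(self):
        """Estimator recovers m within 10% (median over experiments) when
        counts follow the continuous Luria-Delbrueck model it assumes:
        mutations uniform over the n divisions, clone from division k
        having final size n/k."""
        rng = np.random.default_rng(0)
        n, m = 10**7, 20.0
        rel = []
        for _ in range(300):
            counts = []
            for nm in rng.poisson(m, size=30):
                k = rng.integers(1, n + 1, size=nm)
                counts.append(np.floor(n / k).sum())
            est = estimate_rate_median(np.array(counts), n)
            rel.append(est.estimate * n / m)
        assert abs(np.median(rel) - 1) <= 0.10

    def test_confidence_limits_bracket_estimate(self):
        counts = ox.simulate_fluctuation_cultures(1e-5, 1e7, 60, seed=3)
        r = estimate_rate_median(counts, 1e7)
        assert r.cl_lo <= r.estimate <= r.cl_hi


class TestCrossoverCorrections:
    def test_rate_is_twice_frequency(self):
        assert crossover_rate_from_sectors(2.8e-2) == pytest.approx(5.6e-2)
        assert crossover_rate_from_sectors(0.0) == 0.0

    def test_segregation_ratio_by_simulation(self, small_genome):
        """Random chromatid segregation hides half of G2 crossovers."""
        rng = np.random.default_rng(0)
        spec = ox.PlantedEvent("G2_DSB_CO", "chrA", break_kb=600, tract_d1=15)
        n = 10_000
        sectored = sum(
            ox.segregate_g2_crossover(small_genome, spec, seed=int(s))[2]
            for s in rng.integers(0, 2**31, n)
        )
        assert n / sectored == pytest.approx(2.0, abs=0.04)

    def test_viability_corrections(self):
        low = events_per_genome(crossovers_per_genome=4.2e-2, viability=0.9)
        assert low.estimate == pytest.approx(5.2e-2, rel=0.01)
        high = events_per_genome(crossovers_per_genome=7.3e-1, viability=0.1)
        assert high.estimate == pytest.approx(73.0, rel=0.001)
        both = events_per_genome(crossovers_per_genome=7.3e-1, viability=0.1,
                                 include_noncrossover=True)
        assert both.estimate == pytest.approx(146.0, rel=0.001)

    def test_frequency_route_matches_direct_route(self):
        via_freq = events_per_genome(freq=2.8e-2, interval_fraction=0.08,
                                     viability=0.1)
        direct = events_per_genome(
            crossovers_per_genome=crossover_rate_from_sectors(2.8e-2) / 0.08,
            viability=0.1)
        assert via_freq.estimate == pytest.approx(direct.estimate)

    @settings(max_examples=30, deadline=None)
    @given(f=st.floats(1e-5, 0.5), frac=st.floats(0.01, 1.0),
           v=st.floats(0.05, 1.0))
    def test_corrections_multiplicative(self, f, frac, v):
        base = events_per_genome(freq=f, interval_fraction=frac, viability=v)
        doubled = events_per_genome(freq=f, interval_fraction=frac, viability=v,
                                    include_noncrossover=True)
        assert doubled.estimate == pytest.approx(2 * base.estimate)
        assert base.estimate == pytest.approx(2 * f / frac / v**2)

    @pytest.mark.parametrize("co,con,expect", [
        (26, 61, (52, 35)),
        (0, 5, (0, 5)),
        (10, 10, (20, 0)),
    ])
    def test_co_con_correction(self, co, con, expect):
        c, n, flags = correct_co_con_counts(co, con)
        assert (c, n) == expect and flags == ()

    def test_co_exceeding_con_flagged_not_clamped(self):
        c, n, flags = correct_co_con_counts(12, 10)
        assert (c, n) == (24, -2)
        assert "negative-corrected-conversions" in flags


class TestTractLengths:
    def test_single_tract(self):
        med, cl = tract_length_stats([10.0], seed=0)
        assert med == 10.0 and cl == (10.0, 10.0)

    def test_permutation_invariant_and_bracketing(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(math.log(13), 1.0, 50)
        m1, cl1 = tract_length_stats(x, n_boot=2000, seed=5)
        m2, cl2 = tract_length_stats(x[::-1].copy(), n_boot=2000, seed=5)
        assert m1 == m2
        assert cl1[0] <= m1 <= cl1[1]

    def test_bootstrap_coverage_of_lognormal_median(self):
        """95% CL covers the true 13 kb median in >= 93/100 repetitions."""
        rng = np.random.default_rng(0)
        hits = 0
        for r in range(100):
            x = rng.lognormal(math.log(13), 1.0, 200)
            _, (lo, hi) = tract_length_stats(x, n_boot=1000, seed=r)
            hits += lo <= 13.0 <= hi
        assert hits >= 93

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            tract_length_stats([])


class TestFractionG1:
    def test_counts_from_unselected_events(self):
        r = fraction_g1_initiated(n_40=74, n_conversions=87)
        assert r.estimate == pytest.approx(0.85, abs=0.005)

    def test_three_quarters_of_sectored_crossovers(self):
        r = fraction_g1_initiated(n_40=55, n_conversions=73)
        assert r.estimate == pytest.approx(0.75, abs=0.01)

    def test_from_event_objects(self):
        evs = [
            RecombinationEvent("CO", "c", [TractInterval(0, 1, "4:0")]),
            RecombinationEvent("CON", "c", [TractInterval(0, 1, "3:1")]),
            RecombinationEvent("BIR", "c"),  # no tract: not a conversion
        ]
        r = fraction_g1_initiated(events=evs)
        assert r.estimate == pytest.approx(0.5)

    def test_zero_conversions_rejected(self):
        with pytest.raises(DegenerateInputError):
            fraction_g1_initiated(n_40=0, n_conversions=0)


def _events_over_isolates(n_events, n_isolates, genome):
    rng = np.random.default_rng(0)
    chroms = genome.chromosome_names
    return [
        RecombinationEvent("CON", chroms[rng.integers(len(chroms))],
                           isolate=f"iso{i % n_isolates:02d}",
                           start_kb=10.0, end_kb=25.0)
        for i in range(n_events)
    ]


class TestPerIsolateSummary:
    def test_mean_events_per_isolate(self, full_genome):
        s = per_isolate_summary(_events_over_isolates(101, 14, full_genome),
                                full_genome)
        assert s["mean_per_isolate"] == pytest.approx(101 / 14, abs=0.05)
        s = per_isolate_summary(_events_over_isolates(347, 30, full_genome),
                                full_genome)
        assert s["mean_per_isolate"] == pytest.approx(11.6, abs=0.05)

    def test_no_events(self, full_genome):
        s = per_isolate_summary([], full_genome)
        assert s["mean_per_isolate"] == 0.0

    def test_kb_under_loh(self, full_genome):
        evs = _events_over_isolates(10, 2, full_genome)
        s = per_isolate_summary(evs, full_genome)
        assert s["by_isolate"]["loh_kb"].sum() == pytest.approx(10 * 15.0)


class TestHotspotTest:
    def test_uniform_events_rarely_significant(self):
        rng = np.random.default_rng(0)
        iv = [(i * 10.0, (i + 1) * 10.0) for i in range(10)]
        clean = 0
        for _ in range(100):
            out = hotspot_test(rng.uniform(0, 100, 100), iv)
            clean += not (out["p_adj"] < 0.05).any()
        assert clean >= 95

    def test_concentrated_events_detected(self):
        iv = [(i * 10.0, (i + 1) * 10.0) for i in range(10)]
        out = hotspot_test(np.full(20, 5.0), iv)
        assert out.loc[0, "p_adj"] < 1e-6

    def test_single_interval_p_one(self):
        out = hotspot_test([1.0, 2.0, 3.0], [(0.0, 10.0)])
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            hotspot_test([], [(0.0, 1.0)])


class TestFeatureEnrichment:
    def test_whole_genome_feature_p_one(self):
        g = ox.build_genome(
            {"chromosomes": [("chrA", 1000.0, 300.0)], "markers_per_chrom": 50,
             "features": {"all": [("chrA", 0.0, 1000.0, "all")]}}, seed=0)
        evs = [RecombinationEvent("CON", "chrA", start_kb=s, end_kb=s + 5)
               for s in (100.0, 400.0, 800.0)]
        out = feature_enrichment(evs, g, n_perm=500, seed=0)
        assert out.loc[0, "observed"] == 3
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_events_planted_inside_sparse_feature(self):
        """50/50 events inside a 5% feature: strong enrichment signal."""
        feats = [("chrA", s, s + 5.0, "f") for s in np.arange(0, 1000, 100.0)]
        g = ox.build_genome(
            {"chromosomes": [("chrA", 1000.0, 300.0)], "markers_per_chrom": 50,
             "features": {"f": feats}}, seed=0)
        evs = [RecombinationEvent("CON", "chrA", start_kb=float(s) + 1,
                                  end_kb=float(s) + 4)
               for s in np.tile(np.arange(0, 1000, 100.0), 5)]
        out = feature_enrichment(evs, g, n_perm=10_000, seed=0)
        assert out.loc[0, "p_raw"] <= 0.001

    def test_empty_track_skipped(self):
        g = ox.build_genome(
            {"chromosomes": [("chrA", 1000.0, 300.0)], "markers_per_chrom": 50,
             "features": {"empty": []}}, seed=0)
        evs = [RecombinationEvent("CON", "chrA", start_kb=10.0, end_kb=20.0)]
        out = feature_enrichment(evs, g, n_perm=100, seed=0)
        assert out.empty


class TestRdnaExpectation:
    def test_terminal_events_expected_in_rdna(self):
        expected, p0 = rdna_expectation(105, 0.0762)
        assert expected == pytest.approx(8.0, abs=0.01)
        assert p0 == pytest.approx(math.exp(-expected))
        assert p0 < 0.01  # observing zero is significant

    def test_zero_terminal_events(self):
        assert rdna_expectation(0, 0.5) == (0.0, 1.0)


class TestCompareSpectra:
    def test_identical_spectra(self):
        s = ox.MutationSpectrum((10, 20, 30, 10, 5, 25))
        out = compare_spectra(s, s)
        assert out["chi2_stat"] == 0.0 and out["chi2_p"] == 1.0

    def test_disjoint_spectra_highly_significant(self):
        a = ox.MutationSpectrum((100, 0, 0, 0, 0, 0))
        b = ox.MutationSpectrum((0, 100, 0, 0, 0, 0))
        assert compare_spectra(a, b)["chi2_p"] < 1e-10

    def test_per_class_symmetric(self):
        a = ox.MutationSpectrum((30, 10, 25, 5, 20, 10))
        b = ox.MutationSpectrum((12, 18, 9, 21, 6, 14))
        pa = compare_spectra(a, b)["per_class"]["p"].to_numpy()
        pb = compare_spectra(b, a)["per_class"]["p"].to_numpy()
        assert np.allclose(pa, pb)

    def test_spectrum_from_generated_records(self):
        probs = [0.4, 0.1, 0.2, 0.1, 0.1, 0.05, 0.05]
        recs = ox.generate_mutations(probs, 141, seed=0)
        spec = ox.MutationSpectrum.from_records(recs)
        assert spec.total_substitutions + spec.indels == 141

    def test_empty_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_spectra(ox.MutationSpectrum((0,) * 6),
                            ox.MutationSpectrum((1, 0, 0, 0, 0, 0)))
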