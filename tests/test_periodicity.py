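import numpy as np
import pandas as pd
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from perilesion.genome_io import GenomeSequence, trinucleotide_at
from perilesion.periodicity import (
    ContextRates,
    DyadMap,
    PositionProfile,
    RotationalConfig,
    classify_rotational,
    count_relative_to_dyads,
    enrichment_profile,
    expected_profile,
    genomewide_context_rates,
    lomb_scargle_periodogram,
    ratio_profile,
    rotational_summary,
    smooth_profile,
)
from perilesion.experiments import sinusoid_fit_oracle_peak


def events(*rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def dyads(*pos, chrom="c1"):
    return DyadMap({chrom: np.array(pos)})


class TestCounting:
    def test_combined_mode_uses_signed_offset(self):
        p = count_relative_to_dyads(events(("c1", 1005, "+")), dyads(1000), 10)
        assert p.values[10 + 5] == 1 and p.values.sum() == 1

    def test_strand_aligned_inverts_minus_strand(self):
        p = count_relative_to_dyads(
            events(("c1", 1005, "-")), dyads(1000), 10, "strand_aligned"
        )
        assert p.values[10 - 5] == 1

    def test_event_outside_window_not_counted(self):
        p = count_relative_to_dyads(events(("c1", 2500, "+")), dyads(1000), 1000)
        assert p.values.sum() == 0

    def test_event_near_two_dyads_counts_toward_each(self):
        p = count_relative_to_dyads(events(("c1", 1000, "+")), dyads(995, 1005), 10)
        assert p.values.sum() == 2

    def test_total_equals_event_dyad_pairs_within_window(self, rng):
        pos = rng.integers(0, 5000, 300)
        ev = events(*[("c1", int(p), "+") for p in pos])
        dy = dyads(*range(500, 4500, 191))
        hw = 300
        profile = count_relative_to_dyads(ev, dy, hw)
        brute = sum(
            1
            for p in pos
            for d in range(500, 4500, 191)
            if abs(int(p) - d) <= hw
        )
        assert profile.values.sum() == brute

    def test_empty_dyad_map_is_error(self):
        with pytest.raises(ValueError):
            count_relative_to_dyads(events(("c1", 1, "+")), DyadMap({}), 10)

    def test_strand_symmetric_input_gives_symmetric_profile(self):
        rows = [("c1", 1000 + k, "+") for k in (-7, -3, 2)]
        rows += [("c1", 1000 - k, "-") for k in (-7, -3, 2)]
        p = count_relative_to_dyads(events(*rows), dyads(1000), 10)
        assert np.array_equal(p.values, p.values[::-1])


class TestContextRates:
    def test_single_context_genome(self):
        g = GenomeSequence({"c1": "G" * 100})
        ev = events(*[("c1", p, "+") for p in range(10, 20)])
        rates, _ = genomewide_context_rates(ev, g)
        # N = 98 eligible GGG sites (plus strand only; the minus strand
        # reads CCC), n = 10 events -> m_GGG = n/N
        assert set(rates.rates) == {"GGG", "CCC"}
        assert rates.rates["GGG"] == pytest.approx(10 / 98)
        assert rates.rates["CCC"] == 0.0

    def test_zero_events_all_rates_zero(self):
        g = GenomeSequence({"c1": "ACGTACGTAC"})
        rates, _ = genomewide_context_rates(events(), g)
        assert all(v == 0 for v in rates.rates.values())

    def test_doubling_events_doubles_rates(self):
        g = GenomeSequence({"c1": "ACGTACGTACGTACGT"})
        ev1 = events(("c1", 2, "+"), ("c1", 6, "+"))
        ev2 = events(*(list(map(tuple, ev1.values)) * 2))
        r1, _ = genomewide_context_rates(ev1, g)
        r2, _ = genomewide_context_rates(ev2, g)
        for tri, v in r1.rates.items():
            assert r2.rates[tri] == pytest.approx(2 * v)

    def test_minus_strand_event_uses_reverse_complement_context(self):
        g = GenomeSequence({"c1": "AACGTT"})
        # minus-strand event at pos 3 (plus-strand CGT -> minus ACG)
        rates, _ = genomewide_context_rates(events(("c1", 3, "-")), g)
        nonzero = {t for t, v in rates.rates.items() if v > 0}
        assert nonzero == {"ACG"}


class TestExpectedProfile:
    def test_brute_force_oracle_small_genome(self, rng):
        """E_i from the vectorized path equals direct summation of
        f_t(i) * m_t using trinucleotide_at."""
        seq = "".join(rng.choice(list("ACGT"), 400))
        g = GenomeSequence({"c1": seq})
        dy = dyads(50, 120, 200, 260, 330)
        rates = ContextRates(
            {tri: float(rng.random()) for tri in {"ACG", "GGA", "TTT", "CGT", "GAT"}}
        )
        hw = 10
        fast = expected_profile(dy, g, rates, hw)
        brute = np.zeros(2 * hw + 1)
        for d in dy.by_chrom["c1"]:
            for k, i in enumerate(range(-hw, hw + 1)):
                for strand in "+-":
                    tri = trinucleotide_at(g, "c1", int(d + i), strand)
                    brute[k] += rates.rates.get(tri, 0.0)
        np.testing.assert_allclose(fast.values, brute, rtol=1e-12)

    def test_strand_aligned_mirrors_minus_contribution(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        g = GenomeSequence({"c1": seq})
        dy = dyads(100, 180)
        rates = ContextRates({"ACG": 1.0, "TTA": 0.5})
        hw = 8
        fast = expected_profile(dy, g, rates, hw, "strand_aligned")
        brute = np.zeros(2 * hw + 1)
        for d in dy.by_chrom["c1"]:
            for k, i in enumerate(range(-hw, hw + 1)):
                plus = trinucleotide_at(g, "c1", int(d + i), "+")
                minus = trinucleotide_at(g, "c1", int(d + i), "-")
                brute[k] += rates.rates.get(plus, 0.0)
                brute[2 * hw - k] += rates.rates.get(minus, 0.0)
        np.testing.assert_allclose(fast.values, brute, rtol=1e-12)

    def test_zero_rates_rejected_and_doubling_dyads_doubles(self):
        g = GenomeSequence({"c1": "ACGT" * 100})
        rates = ContextRates({"ACG": 0.5})
        e1 = expected_profile(dyads(100), g, rates, 5)
        e2 = expected_profile(dyads(100, 200), g, rates, 5)
        # dyads 100 and 200 see identical contexts on this periodic genome
        np.testing.assert_allclose(e2.values, 2 * e1.values)
        with pytest.raises(ValueError):
            expected_profile(dyads(100), g, ContextRates({}), 5)


class TestNormalization:
    def test_enrichment_identity_and_scaling(self):
        o = PositionProfile(2, [2, 4, 6, 4, 2])
        e = PositionProfile(2, [2, 4, 6, 4, 2], kind="expected")
        assert np.allclose(enrichment_profile(o, e).values, 1)
        e2 = PositionProfile(2, [1, 2, 3, 2, 1], kind="expected")
        assert np.allclose(enrichment_profile(o, e2).values, 2)

    def test_enrichment_masks_zero_expected(self):
        o = PositionProfile(1, [1, 1, 1])
        e = PositionProfile(1, [1, 0, 1], kind="expected")
        enr = enrichment_profile(o, e)
        assert list(enr.mask) == [False, True, False]

    def test_ratio_identity(self):
        a = PositionProfile(2, [1, 2, 3, 2, 1])
        assert np.allclose(ratio_profile(a, a).values, 1)

    def test_ratio_matches_stated_formula_on_toy(self):
        n = np.array([1.0, 1, 2, 1, 1])
        d = np.array([1.0, 1, 1, 1, 1])
        r = ratio_profile(PositionProfile(2, n), PositionProfile(2, d))
        expected = (n / n.sum()) / (d / d.sum())
        np.testing.assert_allclose(r.values, expected)
        assert r.values[2] == pytest.approx(2 * (5 / 6))

    def test_ratio_masks_zero_denominator_and_rejects_all_zero(self):
        n = PositionProfile(1, [1, 1, 1])
        d = PositionProfile(1, [1, 0, 1])
        assert list(ratio_profile(n, d).mask) == [False, True, False]
        with pytest.raises(ValueError):
            ratio_profile(n, PositionProfile(1, [0, 0, 0]))


class TestSmoothing:
    def test_constant_profile_unchanged_including_edges(self):
        p = PositionProfile(10, np.full(21, 3.0))
        assert np.allclose(smooth_profile(p).values, 3.0)

    def test_unit_impulse_spreads_over_window(self):
        v = np.zeros(41)
        v[20] = 11.0
        sm = smooth_profile(PositionProfile(20, v))
        assert np.allclose(sm.values[15:26], 1.0)
        assert sm.values[14] == 0

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(PositionProfile(5, np.ones(11)), width=10)

    def test_masked_positions_excluded_from_local_mean(self):
        v = np.array([1.0, 100.0, 1, 1, 1])
        mask = np.array([False, True, False, False, False])
        sm = smooth_profile(PositionProfile(2, v, mask=mask), width=3)
        assert sm.values[2] == pytest.approx(1.0)


class TestPeriodogram:
    def test_planted_rotational_sinusoid_recovered(self):
        i = np.arange(-60, 61)
        y = 1 + 0.2 * np.cos(2 * np.pi * i / 10.0)
        pg = lomb_scargle_periodogram(PositionProfile(60, y), (5, 25))
        step = np.abs(np.diff(pg.periods)).max()
        assert abs(pg.peak_period - 10.0) <= step

    def test_constant_profile_flagged_with_zero_power(self):
        pg = lomb_scargle_periodogram(PositionProfile(60, np.ones(121)), (5, 25))
        assert pg.degenerate and pg.power.max() < 1e-8

    def test_two_component_translational_peak_matches_lsq_oracle(self):
        i = np.arange(-1000, 1001)
        y = 1 + 0.1 * np.cos(2 * np.pi * i / 191) + 0.05 * np.cos(2 * np.pi * i / 10.2)
        profile = PositionProfile(1000, y)
        pg = lomb_scargle_periodogram(profile, (100, 250))
        oracle = sinusoid_fit_oracle_peak(i.astype(float), y, pg.periods)
        step = np.abs(np.diff(pg.periods)).max()
        assert abs(pg.peak_period - oracle) <= step
        assert abs(pg.peak_period - 191) <= step

    def test_agrees_with_scipy_classic_lombscargle_on_centered_data(self, rng):
        i = np.arange(-500, 501).astype(float)
        y = 1 + 0.3 * np.cos(2 * np.pi * i / 170) + rng.normal(0, 0.05, i.size)
        pg = lomb_scargle_periodogram(PositionProfile(500, y), (100, 250), 501)
        freqs = 2 * np.pi / pg.periods
        ref = scipy_lombscargle(i, y - y.mean(), freqs)
        assert pg.periods[int(np.argmax(ref))] == pytest.approx(
            pg.peak_period, abs=np.abs(np.diff(pg.periods)).max()
        )

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle_periodogram(PositionProfile(3, np.ones(7)), (2, 5))


class TestRotationalClassification:
    CFG = RotationalConfig(helical_period=10.2, phase=0.0)

    @pytest.mark.parametrize(
        "i,label",
        [
            (0, "minor_out"),
            (5, "minor_in"),
            (2, "out_to_in"),
            (3, "out_to_in"),
            (-2, "in_to_out"),
            (10, "minor_out"),
        ],
    )
    def test_examples(self, i, label):
        assert classify_rotational(i, self.CFG) == label

    def test_quarter_bins_by_enumeration(self):
        """Each label covers a quarter cycle; enumeration over one
        period reproduces the piecewise assignment."""
        period, phase = 10.2, 0.0
        for i in range(-10, 11):
            c = ((i - phase) % period) / period
            if c < 1 / 8 or c >= 7 / 8:
                want = "minor_out"
            elif c < 3 / 8:
                want = "out_to_in"
            elif c < 5 / 8:
                want = "minor_in"
            else:
                want = "in_to_out"
            assert classify_rotational(i, self.CFG) == want

    def test_out_of_core_position_rejected(self):
        with pytest.raises(ValueError):
            classify_rotational(61, self.CFG)

    def test_phase_shifts_the_minor_out_center(self):
        cfg = RotationalConfig(10.2, phase=5.0)
        assert classify_rotational(5, cfg) == "minor_out"
        assert classify_rotational(0, cfg) == "minor_in"


class TestRotationalSummary:
    def test_planted_cosine_orders_groups(self):
        cfg = RotationalConfig(10.2, 0.0)
        i = np.arange(-60, 61)
        y = 1 + 0.3 * np.cos(2 * np.pi * i / 10.2)
        rs = rotational_summary(PositionProfile(60, y), cfg).set_index("label")
        assert rs.loc["minor_out", "mean_value"] > rs.loc["minor_in", "mean_value"]

    def test_constant_profile_equal_means(self):
        cfg = RotationalConfig(10.2, 0.0)
        rs = rotational_summary(PositionProfile(60, np.ones(121)), cfg)
        assert np.allclose(rs["mean_value"], 1.0)

    def test_negated_amplitude_inverts_ordering(self):
        cfg = RotationalConfig(10.2, 0.0)
        i = np.arange(-60, 61)
        y = 1 - 0.3 * np.cos(2 * np.pi * i / 10.2)
        rs = rotational_summary(PositionProfile(60, y), cfg).set_index("label")
        assert rs.loc["minor_in", "mean_value"] > rs.loc["minor_out", "mean_value"]
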