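"""Skylines, rCCR, split brackets, TMRCA concordance, theta, SFS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from argdemog.coalsim import TmrcaTrack, VariantTable
from argdemog.metrics import (CoalescenceRateProfile, SplitBracket,
                              rccr, skyline_from_rates, split_time_from_rccr,
                              tmrca_concordance, unfolded_sfs, watterson_theta)
from argdemog.smc import TimeGrid, make_time_grid


def profile(rates, grid=None, label=""):
    rates = np.asarray(rates, dtype=float)
    if grid is None:
        grid = make_time_grid(len(rates), 5e-5)
    return CoalescenceRateProfile(grid, rates, label)


class TestSkyline:
    def test_inverse_of_twice_rate(self):
        sk = skyline_from_rates(profile(np.full(4, 5e-5)))
        assert np.allclose(sk.ne, 10_000)

    def test_constant_rate_gives_flat_skyline(self):
        sk = skyline_from_rates(profile(np.full(8, 1e-6)))
        assert np.all(sk.ne == sk.ne[0])

    def test_round_trip_from_known_ne(self):
        ne = np.array([1e4, 2e5, 3e3, 7e4])
        sk = skyline_from_rates(profile(1.0 / (2.0 * ne)))
        assert np.allclose(sk.ne, ne)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            profile([1e-5, -1e-5, 1e-5, 1e-5])


class TestRccr:
    def test_identical_profiles_give_one(self):
        g = make_time_grid(6, 5e-5)
        p = profile(np.linspace(1e-5, 9e-5, 6), g)
        assert np.allclose(rccr(p, p, p), 1.0)

    def test_zero_cross_rate_gives_zero(self):
        g = make_time_grid(4, 5e-5)
        ab = profile(np.full(4, 1e-12), g)
        aa = profile(np.full(4, 5e-5), g)
        assert np.allclose(rccr(ab, aa, aa), 0.0, atol=1e-6)

    def test_values_not_clipped_above_one(self):
        g = make_time_grid(3, 5e-5)
        ab = profile([2e-5, 2e-5, 2e-5], g)
        aa = profile([1e-5, 1e-5, 1e-5], g)
        assert np.allclose(rccr(ab, aa, aa), 2.0)

    def test_grid_mismatch_rejected(self):
        a = profile(np.full(4, 1e-5), make_time_grid(4, 5e-5))
        b = profile(np.full(4, 1e-5), make_time_grid(4, 6e-5))
        with pytest.raises(ValueError):
            rccr(a, a, b)


class TestSplitBracket:
    def toy_grid(self):
        return TimeGrid(np.array([0.0, 1e3, 1e4, 1e5, np.inf]), anchor_rate=1e-4)

    def test_toy_crossing_bracket(self):
        # recent -> old: 0.05, 0.2, 0.8, 1.0; crossing between epochs 1 and 2
        br = split_time_from_rccr([0.05, 0.2, 0.8, 1.0], self.toy_grid())
        assert br.status == "ok"
        assert (br.lower_gen, br.upper_gen) == (1e3, 1e5)
        assert br.midpoint == pytest.approx(1e4)
        assert br.contains(10_000)

    def test_all_above_threshold(self):
        br = split_time_from_rccr([1.0, 1.0, 1.0, 1.0], self.toy_grid())
        assert br.status == "no_split"

    def test_all_below_threshold(self):
        br = split_time_from_rccr([0.0, 0.0, 0.0, 0.0], self.toy_grid())
        assert br.status == "older_than_grid"

    def test_multiple_crossings_warn(self):
        with pytest.warns(UserWarning, match="multiple"):
            split_time_from_rccr([0.05, 0.9, 0.1, 1.0], self.toy_grid())


def _rank_average(values):
    """Independent average-rank computation (brute force)."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestTmrcaConcordance:
    def test_discretized_order_preserving_truth_gives_one(self):
        truth = TmrcaTrack([0, 100, 200], [100, 200, 300], [500.0, 9000.0, 30000.0])
        inferred = TmrcaTrack([0, 100, 200], [100, 200, 300], [0.0, 3.0, 7.0],
                              "epoch-index")
        assert tmrca_concordance(truth, inferred) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        truth = TmrcaTrack([0, 100, 200], [100, 200, 300], [1.0, 2.0, 3.0])
        inferred = TmrcaTrack([0, 100, 200], [100, 200, 300], [9.0, 5.0, 2.0])
        assert tmrca_concordance(truth, inferred) == pytest.approx(-1.0)

    def test_toy_with_ties_matches_brute_force_ranks(self):
        truth = TmrcaTrack([0, 100], [100, 200], [5.0, 1.0])
        inferred = TmrcaTrack([0, 150], [150, 200], [2.0, 1.0], "epoch-index")
        # intersected units: (0,100)->(5,2), (100,150)->(1,2), (150,200)->(1,1)
        expected = _pearson(_rank_average([5, 1, 1]), _rank_average([2, 2, 1]))
        assert expected == pytest.approx(0.5)
        assert tmrca_concordance(truth, inferred) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        edges = np.sort(rng.choice(np.arange(1, 100), size=8, replace=False))
        t1 = TmrcaTrack(np.r_[0, edges[:4]], np.r_[edges[:4], 100], rng.random(5))
        t2 = TmrcaTrack(np.r_[0, edges[4:]], np.r_[edges[4:], 100], rng.random(5))
        assert tmrca_concordance(t1, t2) == pytest.approx(tmrca_concordance(t2, t1))

    def test_invariance_to_monotone_transform(self):
        t1 = TmrcaTrack([0, 10, 30], [10, 30, 60], [4.0, 9.0, 2.0])
        t2 = TmrcaTrack([0, 20, 40], [20, 40, 60], [1.0, 8.0, 3.0])
        base = tmrca_concordance(t1, t2)
        t1b = TmrcaTrack(t1.starts, t1.ends, np.exp(t1.values))
        t2b = TmrcaTrack(t2.starts, t2.ends, t2.values ** 3)
        assert tmrca_concordance(t1b, t2b) == pytest.approx(base)

    def test_disjoint_tracks_rejected(self):
        t1 = TmrcaTrack([0], [10], [1.0])
        t2 = TmrcaTrack([20], [30], [1.0])
        with pytest.raises(ValueError):
            tmrca_concordance(t1, t2)


class TestWattersonTheta:
    def test_zero_sites(self):
        assert watterson_theta(0, 10, 1e6) == 0.0

    def test_pairwise_case_reduces_to_s_over_l(self):
        assert watterson_theta(37, 2, 1000.0) == pytest.approx(37 / 1000.0)

    def test_four_haplotypes_example(self):
        # a = 1 + 1/2 + 1/3 = 11/6
        assert watterson_theta(7, 4, 1000.0) == pytest.approx(7 / (11 / 6 * 1000.0))
        assert watterson_theta(7, 4, 1000.0) == pytest.approx(0.0038182, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1, 1000.0)
        with pytest.raises(ValueError):
            watterson_theta(5, 4, 0.0)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), n_hap=st.integers(2, 20))
    def test_matches_brute_force_tally(self, seed, n_hap):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(1, 50))
        geno = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.uint8)
        seg = int(np.sum((geno.sum(1) > 0) & (geno.sum(1) < n_hap)))
        a = sum(1.0 / i for i in range(1, n_hap))
        assert watterson_theta(seg, n_hap, 1e4) == pytest.approx(seg / (a * 1e4))


def _toy_table(counts_per_site, n_hap=4):
    rows = []
    for c in counts_per_site:
        row = np.zeros(n_hap, dtype=np.uint8)
        row[:c] = 1
        rows.append(row)
    geno = np.asarray(rows, dtype=np.uint8)
    n = len(counts_per_site)
    return VariantTable(
        positions=np.arange(1, n + 1, dtype=np.int64) * 10,
        ancestral=np.full(n, "A"),
        derived=np.full(n, "T"),
        genotypes=geno,
        sample_populations=np.zeros(n_hap, dtype=np.int8),
        population_names=["pop1"],
        chrom_length=1e4,
    )


class TestUnfoldedSfs:
    def test_hand_counted_example(self):
        sfs = unfolded_sfs(_toy_table([1, 1, 2, 3]))
        assert list(sfs.counts) == [2, 1, 1]
        assert sfs.n_segregating == 4

    def test_sum_equals_segregating_sites(self, small_sim):
        _, vt = small_sim
        sfs = unfolded_sfs(vt, "pop1")
        seg = np.sum((vt.derived_counts() > 0) & (vt.derived_counts() < vt.n_haplotypes))
        assert sfs.n_segregating == seg

    def test_fixed_sites_reported_separately(self):
        sfs = unfolded_sfs(_toy_table([0, 4, 2]))
        assert sfs.n_fixed_ancestral == 1
        assert sfs.n_fixed_derived == 1
        assert sfs.n_segregating == 1

    def test_all_ancestral_gives_empty_sfs(self):
        sfs = unfolded_sfs(_toy_table([0, 0]))
        assert sfs.n_segregating == 0

    def test_unpolarized_site_rejected(self):
        vt = _toy_table([1, 2])
        vt.ancestral = np.array(["A", "N"])
        with pytest.raises(ValueError):
            unfolded_sfs(vt)

    def test_one_line_format(self):
        assert unfolded_sfs(_toy_table([1, 1, 2, 3])).to_line() == "2 1 1"
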