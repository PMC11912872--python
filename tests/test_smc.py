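"""Pairwise SMC HMM: grid, transitions, emissions, EM, decoding."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from argdemog import _hmm
from argdemog.smc import (HmmParams, ObservationSequence, PairwiseSMC,
                          emission_probs, fit_em, make_time_grid,
                          observations_from_variants, posterior_decode,
                          disjoint_pairs, transition_matrix)

MU = 4.6e-9


def flat_params(ne=10_000.0, n_epochs=32, rho=4.6e-10):
    grid = make_time_grid(n_epochs, 1.0 / (2.0 * ne))
    lam = np.full(n_epochs, 1.0 / (2.0 * ne))
    return HmmParams(grid, lam, rho, MU)


class TestTimeGrid:
    def test_two_epochs_split_at_exponential_median(self):
        g = make_time_grid(2, 1.0)
        assert g.boundaries[1] == pytest.approx(np.log(2))
        assert g.boundaries[0] == 0.0 and np.isinf(g.boundaries[-1])

    def test_edges_strictly_increasing(self):
        g = make_time_grid(32, 5e-5)
        assert np.all(np.diff(g.boundaries[:-1]) > 0)

    def test_equal_prior_mass_per_epoch(self):
        g = make_time_grid(8, 2e-4)
        lam = np.full(8, 2e-4)
        pi = _hmm.prior_mass(g.boundaries, lam)
        assert np.allclose(pi, 1.0 / 8, atol=1e-12)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            make_time_grid(1, 1.0)

    def test_representative_times_inside_epochs(self):
        g = make_time_grid(16, 1e-4)
        tt = g.representative_times
        assert np.all(tt > g.boundaries[:-1])
        assert np.all(tt[:-1] < g.boundaries[1:-1])


class TestTransitionMatrix:
    def test_zero_rho_gives_identity(self):
        P = transition_matrix(flat_params(rho=0.0), bin_width=100)
        assert np.allclose(P, np.eye(32))

    def test_rows_sum_to_one(self):
        P = transition_matrix(flat_params(), bin_width=100)
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10

    def test_prior_is_stationary(self):
        p = flat_params()
        P = transition_matrix(p, bin_width=1)
        pi = p.prior()
        assert np.max(np.abs(pi @ P - pi)) < 1e-6

    @settings(deadline=None, max_examples=20)
    @given(
        seed=st.integers(0, 10_000),
        log_rho=st.floats(min_value=-10, max_value=-7),
    )
    def test_stationarity_property_random_rates(self, seed, log_rho):
        rng = np.random.default_rng(seed)
        grid = make_time_grid(16, 5e-5)
        lam = np.exp(rng.normal(np.log(5e-5), 1.0, 16))
        p = HmmParams(grid, lam, 10.0**log_rho, MU)
        P = transition_matrix(p, bin_width=1)
        pi = p.prior()
        assert np.max(np.abs(pi @ P - pi)) < 1e-6

    def test_extreme_rates_stay_finite(self):
        grid = make_time_grid(8, 5e-5)
        for lam_val in (1e-9, 1e-1):
            p = HmmParams(grid, np.full(8, lam_val), 1e-8, MU)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                P = transition_matrix(p, bin_width=100)
            assert np.all(np.isfinite(P))
            assert np.allclose(P.sum(axis=1), 1.0)


class TestEmissions:
    def test_heterozygosity_probability_formula(self):
        p = flat_params()
        tt = p.grid.representative_times
        e = emission_probs(p, called_sites=1, het_count=1)
        assert np.allclose(e, -np.expm1(-2.0 * tt * MU))

    def test_value_at_ten_thousand_generations(self):
        # p(t) = 1 - exp(-2 t mu) evaluated directly
        assert 1.0 - np.exp(-2.0 * 10_000 * MU) == pytest.approx(9.199577e-5, rel=1e-6)

    def test_recent_epoch_penalizes_het(self):
        p = flat_params()
        e = emission_probs(p, called_sites=100, het_count=1)
        assert e[0] < e[-1]  # het much less likely for tiny TMRCA

    def test_masked_bin_uniform(self):
        p = flat_params()
        assert np.allclose(emission_probs(p, 0, 0), 1.0)

    def test_het_exceeding_called_rejected(self):
        with pytest.raises(ValueError):
            emission_probs(flat_params(), 2, 3)

    def test_binomial_variant_uses_counts(self):
        p = flat_params()
        e1 = emission_probs(p, 100, 1, emission="binomial")
        e2 = emission_probs(p, 100, 2, emission="binomial")
        assert not np.allclose(e1 / e1.max(), e2 / e2.max())


def _sim_observations(n_chrom=4, length=1e6, seed0=500):
    from argdemog.coalsim import drop_mutations, simulate_arg
    from argdemog.scenarios import make_uniform_map

    from conftest import constant_demography

    demog = constant_demography(10_000.0)
    m = make_uniform_map(MU, 0.1, chrom_length=length)
    obs = []
    for i in range(n_chrom):
        ts = simulate_arg(demog, m, {"pop1": 8}, seed=seed0 + i)
        vt = drop_mutations(ts, MU, seed=seed0 + 100 + i)
        obs += observations_from_variants(
            vt, [(0, 1), (2, 3), (4, 5), (6, 7)], bin_width=100)
    return obs


@pytest.fixture(scope="module")
def fitted():
    obs = _sim_observations(n_chrom=6)
    est = PairwiseSMC(mu=MU, rho=4.6e-10, n_iter=10).fit(obs)
    return est, obs


class TestFitEm:

    def test_loglik_nondecreasing(self, fitted):
        est, _ = fitted
        ll = est.log_likelihood_path_
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_constant_ne_recovered_in_covered_epochs(self, fitted):
        est, _ = fitted
        T = est.grid_.boundaries
        sel = (T[:-1] >= 5_000) & (T[1:] <= 60_000)
        med = np.median(est.ne_[sel])
        assert med == pytest.approx(10_000, rel=0.25)

    def test_forward_backward_loglik_agreement(self, fitted):
        est, obs = fitted
        from argdemog.smc import _emis_matrix

        P = transition_matrix(est.params_, est.bin_width)
        pi = est.params_.prior()
        emis = _emis_matrix(obs[0], est.params_, "bernoulli")
        ll_f, _, _ = _hmm.fb_em(emis, P, pi)
        ll_b = _hmm.backward_loglik(emis, P, pi)
        assert ll_f == pytest.approx(ll_b, rel=1e-8)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            PairwiseSMC().fit([])

    def test_all_masked_input_rejected(self):
        obs = [ObservationSequence(np.zeros(100, int), np.zeros(100, int), 100)]
        with pytest.raises(ValueError):
            PairwiseSMC(mu=MU).fit(obs)

    def test_zero_het_input_hits_clamp_without_nan(self):
        called = np.full(2000, 100)
        het = np.zeros(2000, dtype=int)
        obs = [ObservationSequence(called, het, 100)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = PairwiseSMC(mu=MU, rho=4.6e-10, n_iter=3, ne_anchor=10_000).fit(obs)
        assert np.all(np.isfinite(est.lambdas_))
        assert np.all(np.isfinite(est.log_likelihood_path_))
        # zero heterozygosity drives recent coalescence rates toward the
        # upper clamp (all TMRCA pushed to the most recent epochs)
        assert est.lambdas_.max() > 1e-3

    def test_fit_em_wrapper_matches_estimator(self):
        obs = _sim_observations(n_chrom=1)
        init = flat_params(ne=12_000.0)
        params, path = fit_em(obs, init, n_iter=2)
        assert len(path) == 2
        assert params.grid is init.grid

    def test_scaling_round_trip(self):
        lam = np.array([1e-5, 5e-4, 2e-6])
        ne = 1.0 / (2.0 * lam)
        assert np.allclose(1.0 / (2.0 * ne), lam)


class TestPosteriorDecode:
    def test_posterior_rows_sum_to_one(self):
        p = flat_params(n_epochs=8)
        obs = _sim_observations(n_chrom=1)[0]
        from argdemog.smc import _emis_matrix

        P = transition_matrix(p, 100)
        emis = _emis_matrix(obs, p, "bernoulli")
        _, gamma = _hmm.fb_posterior(emis, P, p.prior())
        assert np.max(np.abs(gamma.sum(axis=1) - 1.0)) < 1e-10

    def test_uniform_emissions_decode_to_prior_mode(self):
        grid = make_time_grid(8, 5e-5)
        lam = np.full(8, 5e-5)
        lam[2] = 3e-4  # unique prior mode at epoch 2
        p = HmmParams(grid, lam, 4.6e-10, MU)
        obs = ObservationSequence(np.zeros(50, int), np.zeros(50, int), 100)
        track = posterior_decode(obs, p)
        modal = int(np.argmax(p.prior()))
        assert modal == 2
        assert np.all(track.values == modal)

    def test_track_covers_all_bins(self):
        p = flat_params(n_epochs=8)
        obs = _sim_observations(n_chrom=1)[0]
        track = posterior_decode(obs, p)
        assert track.span == (0.0, obs.n_bins * 100.0)


class TestObservations:
    def test_het_counts_match_pair_differences(self, small_sim):
        _, vt = small_sim
        obs = observations_from_variants(vt, [(0, 1)], bin_width=100)[0]
        expected = np.sum(vt.genotypes[:, 0] != vt.genotypes[:, 1])
        assert obs.het.sum() == expected

    def test_mask_removes_called_sites_and_variants(self, small_sim):
        _, vt = small_sim
        mask = [(0, 5e5)]
        obs = observations_from_variants(vt, [(0, 1)], mask=mask, bin_width=100)[0]
        assert np.all(obs.called[:5000] == 0)
        assert np.all(obs.het[:5000] == 0)
        assert np.all(obs.called[5000:] == 100)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ObservationSequence(np.array([100]), np.array([101]), 100)
        with pytest.raises(ValueError):
            ObservationSequence(np.array([200]), np.array([0]), 100)


class TestSklearnProtocol:
    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = PairwiseSMC(mu=1e-8, n_iter=3)
        params = est.get_params()
        assert params["mu"] == 1e-8 and params["n_iter"] == 3
        est2 = clone(est).set_params(n_iter=5)
        assert est2.n_iter == 5 and est2.mu == 1e-8


class TestSmcPrimeKernel:
    def test_rows_sum_to_one(self):
        from argdemog.smc import transition_matrix

        P = transition_matrix(flat_params(n_epochs=8), bin_width=1, kernel="smc_prime")
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.all(P >= 0)

    def test_zero_rho_gives_identity(self):
        from argdemog.smc import transition_matrix

        P = transition_matrix(flat_params(n_epochs=8, rho=0.0), kernel="smc_prime")
        assert np.allclose(P, np.eye(8))

    def test_self_coalescence_increases_stay_probability(self):
        from argdemog.smc import transition_matrix

        p = flat_params(n_epochs=8, rho=1e-8)
        P_smc = transition_matrix(p, kernel="smc")
        P_prime = transition_matrix(p, kernel="smc_prime")
        assert np.all(np.diag(P_prime) >= np.diag(P_smc) - 1e-12)

    def test_unknown_kernel_rejected(self):
        from argdemog.smc import transition_matrix

        with pytest.raises(ValueError):
            transition_matrix(flat_params(n_epochs=8), kernel="bogus")


class TestCrossPopulationRates:
    def test_panmictic_control_rccr_centers_on_one(self):
        """Two halves of one panmictic sample: rCCR has no split signal."""
        from argdemog.coalsim import VariantTable, drop_mutations, simulate_arg
        from argdemog.metrics import rccr
        from argdemog.scenarios import make_uniform_map
        from argdemog.smc import cross_population_rates

        from conftest import constant_demography

        demog = constant_demography(10_000.0)
        m = make_uniform_map(MU, 0.1, chrom_length=1e6)
        vts = []
        for i in range(6):
            ts = simulate_arg(demog, m, {"pop1": 8}, seed=900 + i)
            vt = drop_mutations(ts, MU, seed=950 + i)
            vts.append(VariantTable(
                vt.positions, vt.ancestral, vt.derived, vt.genotypes,
                np.array([0, 0, 0, 0, 1, 1, 1, 1], np.int8), ["A", "B"],
                vt.chrom_length))
        prof = cross_population_rates(vts, "A", "B", n_pairs=2, n_iter=6)
        r = rccr(prof["AB"], prof["AA"], prof["BB"])
        # per-epoch values scatter at this data size; the well-covered
        # central epochs must center on 1 (no cross-population structure)
        assert 0.8 <= np.median(r[6:27]) <= 1.25
        # shared grid across the three fits
        assert prof["AA"].grid is prof["AB"].grid

    def test_insufficient_haplotypes_rejected(self, small_sim):
        from argdemog.coalsim import VariantTable
        from argdemog.smc import cross_population_rates

        _, vt = small_sim
        bad = VariantTable(vt.positions, vt.ancestral, vt.derived, vt.genotypes,
                           np.array([0, 0, 0, 1], np.int8), ["A", "B"],
                           vt.chrom_length)
        with pytest.raises(ValueError):
            cross_population_rates(bad, "A", "B")
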