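import numpy as np
import pytest

from fitbench import (SimulationConfig, sample_landscape, simulate_replicates,
                      infer_couplings_nmf, infer_fields_nmf, infer_fij,
                      infer_fi, infer_additive_only, aggregate_fi, infer_tqle)
from fitbench.tqle import IsingParameters
from conftest import exact_ising_moments, momentset_from_freqs


class TestCouplingInversion:
    def test_independent_loci_give_zero_couplings(self):
        ms = momentset_from_freqs([0.3, 0.5, 0.8])
        J = infer_couplings_nmf(ms)
        np.testing.assert_allclose(J, 0.0, atol=1e-12)

    def test_two_spin_closed_form(self):
        # exact chi_12 = tanh(J); nMF inverts to t / (1 - t^2)
        J_true = 0.05
        ms = exact_ising_moments(np.zeros(2), np.array([[0, J_true], [J_true, 0]]))
        t = np.tanh(J_true)
        J_est = infer_couplings_nmf(ms)
        assert J_est[0, 1] == pytest.approx(t / (1 - t ** 2), rel=1e-10)
        assert abs(J_est[0, 1] - J_true) / J_true < 0.002

    def test_weak_coupling_recovery_from_enumeration(self, rng):
        # L=5 Boltzmann enumeration: |J| <= 0.05 recovered within 0.01
        L = 5
        J = np.zeros((L, L))
        iu = np.triu_indices(L, 1)
        J[iu] = rng.uniform(-0.05, 0.05, size=iu[0].size)
        J = J + J.T
        ms = exact_ising_moments(np.zeros(L), J)
        J_est = infer_couplings_nmf(ms)
        assert np.max(np.abs(J_est - J)) < 0.01

    def test_symmetric_zero_diagonal(self, rng):
        ms = exact_ising_moments(rng.normal(0, 0.1, 4),
                                 np.zeros((4, 4)))
        J = infer_couplings_nmf(ms)
        assert np.array_equal(J, J.T)
        assert np.all(np.diag(J) == 0)


class TestFieldInversion:
    def test_zero_moments_zero_fields(self):
        ms = momentset_from_freqs([0.5, 0.5, 0.5])
        h = infer_fields_nmf(ms, np.zeros((3, 3)))
        np.testing.assert_allclose(h, 0.0, atol=1e-15)

    def test_atanh_identity_without_couplings(self):
        ms = momentset_from_freqs([(np.tanh(0.3) + 1) / 2] * 4)
        h = infer_fields_nmf(ms, np.zeros((4, 4)))
        np.testing.assert_allclose(h, 0.3, atol=1e-12)

    def test_field_recovery_from_enumeration(self):
        h_true = np.array([0.1, -0.1, 0.2])
        J = np.array([[0, 0.02, -0.02], [0.02, 0, 0.02], [-0.02, 0.02, 0]])
        ms = exact_ising_moments(h_true, J)
        h_est = infer_fields_nmf(ms, infer_couplings_nmf(ms))
        assert np.max(np.abs(h_est - h_true)) < 0.02

    def test_saturated_magnetization_rejected(self):
        ms = momentset_from_freqs([1.0, 0.5])
        with pytest.raises(ValueError):
            infer_fields_nmf(ms, np.zeros((2, 2)))


class TestEpistasisMapping:
    def test_zero_couplings_give_zero_epistasis(self):
        ms = momentset_from_freqs([0.4, 0.6])
        for variant in ("rc", "rc_4mu"):
            fij = infer_fij(0.5, 0.5, 0.01, variant, J=np.zeros((2, 2)))
            assert np.all(fij == 0.0)
        fij = infer_fij(0.5, 0.5, 0.01, "gaussian_closure", ms=ms)
        off = fij[~np.eye(2, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_printed_rate_arithmetic(self):
        # r c = 0.25, mu = 0.01, J_12 = 0.1: rates 0.25 and 0.25 + 0.04
        J = np.zeros((2, 2))
        J[0, 1] = J[1, 0] = 0.1
        assert infer_fij(0.5, 0.5, 0.01, "rc", J=J)[0, 1] == pytest.approx(0.025)
        assert infer_fij(0.5, 0.5, 0.01, "rc_4mu", J=J)[0, 1] == pytest.approx(0.029)

    def test_gaussian_closure_formula(self):
        chi = np.array([0.2, -0.4])
        ms = momentset_from_freqs((chi + 1) / 2)
        ms.chi_ij[0, 1] = ms.chi_ij[1, 0] = 0.03
        fij = infer_fij(0.5, 0.5, 0.01, "gaussian_closure", ms=ms)
        expected = 0.29 * 0.03 / ((1 - 0.04) * (1 - 0.16))
        assert fij[0, 1] == pytest.approx(expected)

    def test_invalid_variant_and_rate(self):
        with pytest.raises(ValueError):
            infer_fij(0.5, 0.5, 0.01, "bogus", J=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            infer_fij(0.0, 0.5, 0.0, "rc", J=np.zeros((2, 2)))


class TestAdditiveEstimator:
    def test_constant_fields_give_zero(self):
        ms = momentset_from_freqs([0.6, 0.4])
        h = IsingParameters(0, np.array([0.3, -0.1]), np.zeros((2, 2)))
        h2 = IsingParameters(1, np.array([0.3, -0.1]), np.zeros((2, 2)))
        fi = infer_fi(h, h2, np.zeros((2, 2)), ms, 1)
        np.testing.assert_allclose(fi, 0.0, atol=1e-15)

    def test_field_jump_arithmetic(self):
        ms = momentset_from_freqs([0.5, 0.5])
        h = IsingParameters(0, np.zeros(2), np.zeros((2, 2)))
        h2 = IsingParameters(1, np.array([0.02, 0.0]), np.zeros((2, 2)))
        fi = infer_fi(h, h2, np.zeros((2, 2)), ms, 1)
        np.testing.assert_allclose(fi, [0.02, 0.0], atol=1e-15)

    def test_generation_mismatch_rejected(self):
        ms = momentset_from_freqs([0.5])
        h = IsingParameters(0, np.zeros(1), np.zeros((1, 1)))
        h2 = IsingParameters(5, np.zeros(1), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            infer_fi(h, h2, np.zeros((1, 1)), ms, 1)

    def test_stationary_series_gives_zero(self):
        series = [momentset_from_freqs([0.3, 0.7], generation=g) for g in range(5)]
        est = infer_additive_only(series)
        np.testing.assert_allclose(est.fi_star, 0.0, atol=1e-14)
        assert est.fij_star is None

    def test_recovers_deterministic_selection_mutation_recursion(self):
        # iterate m' = sel(m) then mutation; additive-only estimate within 15%
        f, mu, m = 0.05, 0.003, 0.3
        series = []
        for g in range(31):
            series.append(momentset_from_freqs([m, 0.5], generation=g))
            m_sel = m * np.exp(2 * f) / (m * np.exp(2 * f) + 1 - m)
            m = m_sel * (1 - mu) + (1 - m_sel) * mu
        est = infer_additive_only(series)
        assert est.fi_star[0] == pytest.approx(f, rel=0.15)

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError):
            infer_additive_only([momentset_from_freqs([0.5])])


class TestAggregation:
    def test_single_interval_identity(self):
        fi, spread = aggregate_fi([np.array([0.1, -0.2])])
        np.testing.assert_array_equal(fi, [0.1, -0.2])
        np.testing.assert_array_equal(spread, [0.0, 0.0])

    def test_alternating_estimates_cancel(self):
        a = np.array([0.3, -0.3])
        fi, spread = aggregate_fi([a, -a, a, -a])
        np.testing.assert_allclose(fi, 0.0, atol=1e-15)
        np.testing.assert_allclose(spread, np.abs(a))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_fi([])


class TestEndToEnd:
    def test_additive_reduction_consistency(self, tiny_trajectory):
        # full estimator with a zero coupling feedback reduces to additive-only
        tr, _ = tiny_trajectory
        from fitbench.freqstats import pooled_frequency_trajectory
        series = pooled_frequency_trajectory([tr], 0.5)
        add = infer_additive_only(series)
        per_interval = []
        for k in range(len(series) - 1):
            h0 = IsingParameters(k, np.arctanh(series[k].chi_i), np.zeros((6, 6)))
            h1 = IsingParameters(k + 1, np.arctanh(series[k + 1].chi_i), np.zeros((6, 6)))
            per_interval.append(infer_fi(h0, h1, np.zeros((6, 6)), series[k], 1))
        fi, _ = aggregate_fi(per_interval)
        np.testing.assert_allclose(fi, add.fi_star, atol=1e-13)

    def test_null_simulation_no_spurious_signal(self):
        # neutral landscape at benchmark scale: mean |fi*| below noise floor
        fl = sample_landscape(25, 0.0, 0.0, seed=0)
        cfg = SimulationConfig(N=1000, L=25, T=30, r=0.5, mu=0.01,
                               n_replicates=10, seed=31)
        trajs = simulate_replicates(fl, cfg)
        est = infer_tqle(trajs, variant="additive_only")
        assert np.mean(np.abs(est.fi_star)) < 0.01

    def test_single_replicate_additive_recovery(self):
        # strong-selection single replicate: Pearson(fi*, fi) >= 0.7
        fl = sample_landscape(25, 0.05, 0.0, seed=8)
        cfg = SimulationConfig(N=1000, L=25, T=30, r=0.5, mu=0.01, seed=12)
        trajs = simulate_replicates(fl, cfg)
        est = infer_tqle(trajs, variant="additive_only")
        from scipy.stats import pearsonr
        assert pearsonr(fl.fi, est.fi_star).statistic >= 0.7

    def test_epistasis_recovery_positive(self):
        # pooled replicates in the epistasis-dominated regime
        fl = sample_landscape(25, 0.005, 0.002, seed=14)
        cfg = SimulationConfig(N=1000, L=25, T=30, r=0.5, mu=0.01,
                               n_replicates=30, seed=15)
        trajs = simulate_replicates(fl, cfg)
        est = infer_tqle(trajs, variant="rc_4mu")
        from scipy.stats import spearmanr
        iu = np.triu_indices(25, 1)
        rho = spearmanr(fl.fij[iu], est.fij_star[iu]).statistic
        assert rho >= 0.3

    def test_estimate_metadata(self, tiny_trajectory):
        tr, _ = tiny_trajectory
        est = infer_tqle([tr], variant="rc_4mu")
        inf = est.as_inferred()
        assert inf.method == "tqle"
        assert inf.hyperparams["variant"] == "rc_4mu"
        assert est.fi_per_interval.shape == (5, 6)


class TestUnidentifiableSites:
    def test_monomorphic_sites_flagged_and_zeroed(self):
        # locus 1 fixed at -1 throughout: unidentifiable, reported as 0
        from test_freqstats import make_traj
        recs = [(g, [[1, -1, 1], [-1, -1, 1]], [6, 4]) for g in range(4)]
        tr = make_traj(recs)
        est = infer_tqle([tr], variant="additive_only")
        assert est.unidentifiable.tolist() == [False, True, True]
        assert est.fi_star[1] == 0.0 and est.fi_star[2] == 0.0

    def test_polymorphic_sites_not_flagged(self, tiny_trajectory):
        tr, _ = tiny_trajectory
        est = infer_tqle([tr], variant="rc_4mu")
        assert not est.unidentifiable.any()
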