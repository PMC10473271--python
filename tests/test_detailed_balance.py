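import numpy as np
import pytest

from arrowtime import detailed_balance as db
from arrowtime import synthetic as syn
from arrowtime.signal_io import ParcelTimeSeries


class TestLaggedFC:
    def test_zero_lag_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        fc = db.lagged_fc(rng.standard_normal((4, 50)), 0)
        assert np.allclose(fc, fc.T, atol=1e-12)
        assert np.allclose(np.diag(fc), 1.0)

    def test_iid_noise_off_diagonal_vanishes(self):
        rng = np.random.default_rng(1)
        fc = db.lagged_fc(rng.standard_normal((3, 100_000)), 3)
        off = fc[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_entries_are_correlations(self):
        rng = np.random.default_rng(2)
        fc = db.lagged_fc(rng.standard_normal((5, 40)), 2)
        assert np.abs(fc).max() <= 1.0 + 1e-12

    def test_zero_variance_region_named(self):
        x = np.random.default_rng(3).standard_normal((3, 30))
        x[1] = 5.0
        with pytest.raises(ValueError, match="rB"):
            db.lagged_fc(x, 2, region_ids=["rA", "rB", "rC"])

    def test_window_too_short_for_lag(self):
        with pytest.raises(ValueError, match="too short"):
            db.lagged_fc(np.random.default_rng(4).standard_normal((2, 5)), 3)

    def test_ou_empirical_matches_oracle(self, ou_family):
        sysm = ou_family[3]  # kappa = 1
        s = syn.simulate_ou(sysm, 100_000, seed=6)
        emp = db.global_asymmetry(db.lagged_fc(s.values, 3))
        oracle = db.global_asymmetry(
            syn.lagged_cov_oracle(sysm, 3 * sysm.dt, normalize=True))
        assert emp == pytest.approx(oracle, rel=0.10)


class TestChooseTau:
    def test_white_noise_gives_one(self):
        rng = np.random.default_rng(0)
        s = ParcelTimeSeries(rng.standard_normal((4, 2000)), 1.0)
        assert db.choose_tau(s) == 1

    def test_slower_dynamics_need_longer_lag(self, ou_family):
        # scaling the drift down stretches the correlation time ~ 1/||A||
        sysm = ou_family[0]
        slow_drift = sysm.drift * 0.25
        slow_sys = syn.OUSystem(
            slow_drift, sysm.diffusion, sysm.asymmetry_strength,
            syn.stationary_covariance(slow_drift, sysm.diffusion),
            sysm.dt, sysm.seed)
        fast_series = syn.simulate_ou(sysm, 20_000, seed=1)
        slow_series = syn.simulate_ou(slow_sys, 20_000, seed=1)
        assert db.choose_tau(slow_series, max_tau=40) > \
            db.choose_tau(fast_series, max_tau=40)

    def test_cap_with_warning(self):
        t = np.arange(500, dtype=float)
        s = ParcelTimeSeries(np.vstack([np.sin(t / 400), np.cos(t / 400)]), 1.0)
        with pytest.warns(UserWarning, match="cap"):
            assert db.choose_tau(s, max_tau=5) == 5


class TestGlobalAsymmetry:
    def test_symmetric_matrix_zero(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((5, 5))
        assert db.global_asymmetry(M + M.T) == 0.0

    def test_worked_two_by_two(self):
        fc = np.array([[1.0, 0.5], [0.1, 1.0]])
        assert db.global_asymmetry(fc) == pytest.approx(0.4)
        assert db.global_asymmetry(fc, mode="squared") == pytest.approx(0.16)

    def test_signed_mean_identically_zero(self):
        # the raw mean of FC - FC^T vanishes for *any* matrix; only
        # nonnegative functionals of the antisymmetric part carry signal
        rng = np.random.default_rng(2)
        for _ in range(10):
            M = rng.standard_normal((6, 6))
            assert np.mean(M - M.T) == pytest.approx(0.0, abs=1e-15)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((7, 7))
        perm = rng.permutation(7)
        assert db.global_asymmetry(M[np.ix_(perm, perm)]) == pytest.approx(
            db.global_asymmetry(M))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            db.global_asymmetry(np.zeros((2, 3)))


class TestNodeAsymmetry:
    def test_flows_balance_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            f_in, f_out = db.node_flows(rng.standard_normal((6, 6)))
            assert np.sum(f_out - f_in) == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_by_two(self):
        fc = np.array([[1.0, 0.5], [0.1, 1.0]])
        vals = db.node_asymmetry([fc])
        assert np.allclose(vals, [0.4, 0.4])

    def test_symmetric_windows_give_zero(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((4, 4))
        assert np.allclose(db.node_asymmetry([M + M.T, 2 * (M + M.T)]), 0.0)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(6)
        M = rng.standard_normal((5, 5))
        assert np.allclose(db.node_asymmetry([M]), db.node_asymmetry([M.T]))

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            db.node_asymmetry([np.zeros((3, 3)), np.zeros((4, 4))])


def _asym_matrix(rng, strength, n=6):
    M = rng.standard_normal((n, n)) * 0.1
    A = rng.standard_normal((n, n))
    return M + M.T + strength * (A - A.T)


class TestConditionOnR:
    def test_high_R_windows_show_stronger_asymmetry(self):
        # windows whose R is large carry more broken detailed balance
        rng = np.random.default_rng(0)
        R = rng.uniform(0, 1, 200)
        fcs = [_asym_matrix(rng, r) for r in R]
        res = db.condition_on_R(R, fcs, quantile=0.25)
        assert res.high_asym.mean() > res.low_asym.mean()
        assert res.p_value < 1e-6
        assert res.node_delta.mean() > 0

    def test_shuffled_alignment_destroys_contrast(self):
        rng = np.random.default_rng(1)
        R = rng.uniform(0, 1, 200)
        fcs = [_asym_matrix(rng, r) for r in R]
        shuffled = [fcs[i] for i in rng.permutation(200)]
        res = db.condition_on_R(R, shuffled, quantile=0.25)
        aligned = db.condition_on_R(R, fcs, quantile=0.25)
        assert abs(res.statistic) < abs(aligned.statistic)
        assert res.p_value > 1e-4

    def test_constant_trace_rejected(self):
        rng = np.random.default_rng(2)
        fcs = [_asym_matrix(rng, 0.5) for _ in range(50)]
        with pytest.raises(ValueError, match="constant"):
            db.condition_on_R(np.full(50, 0.3), fcs)

    def test_too_few_windows_rejected(self):
        rng = np.random.default_rng(3)
        fcs = [_asym_matrix(rng, 0.5) for _ in range(8)]
        with pytest.raises(ValueError, match="too few"):
            db.condition_on_R(rng.uniform(0, 1, 8), fcs)
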