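import numpy as np
import pytest
from scipy import stats

from arrowtime import synthetic as syn
from arrowtime import detailed_balance as db


class TestStationaryCovariance:
    def test_identity_system(self):
        assert np.allclose(syn.stationary_covariance(np.eye(3), np.eye(3)),
                           np.eye(3))

    def test_diagonal_closed_form(self):
        # scalar decoupled modes: Sigma_ii = D_ii / A_ii
        sigma = syn.stationary_covariance(np.diag([1.0, 2.0]), np.eye(2))
        assert np.allclose(sigma, np.diag([1.0, 0.5]))

    def test_lyapunov_residual_small(self):
        rng = np.random.default_rng(3)
        Q = rng.standard_normal((6, 6))
        A = Q.T @ Q / 6 + np.eye(6)
        D = np.eye(6)
        sigma = syn.stationary_covariance(A, D)
        assert np.linalg.norm(A @ sigma + sigma @ A.T - 2 * D) < 1e-8
        assert np.allclose(sigma, sigma.T)

    def test_unstable_drift_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            syn.stationary_covariance(-np.eye(2), np.eye(2))

    def test_non_spd_diffusion_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            syn.stationary_covariance(np.eye(2), np.diag([1.0, -1.0]))


class TestMakeOUSystem:
    def test_reversible_iff_kappa_zero(self):
        sysm = syn.make_ou_system(4, 0.0, seed=1)
        AS = sysm.drift @ sysm.stationary_cov
        assert np.allclose(AS, AS.T, atol=1e-10)

    def test_kappa_breaks_detailed_balance(self):
        sysm = syn.make_ou_system(3, 0.5, seed=1)
        AS = sysm.drift @ sysm.stationary_cov
        assert np.linalg.norm(AS - AS.T) > 1e-3

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValueError):
            syn.make_ou_system(1, 0.5, seed=0)

    def test_stable_for_large_kappa(self):
        sysm = syn.make_ou_system(5, 10.0, seed=2)
        assert np.min(np.linalg.eigvals(sysm.drift).real) > 0

    def test_family_shares_symmetric_part(self):
        fam = syn.make_ou_family(4, [0.0, 1.0], seed=5)
        S0 = (fam[0].drift + fam[0].drift.T) / 2
        S1 = (fam[1].drift + fam[1].drift.T) / 2
        assert np.allclose(S0, S1)


class TestLaggedCovOracle:
    def test_zero_lag_is_stationary_cov(self, ou_family):
        sysm = ou_family[2]
        assert np.allclose(syn.lagged_cov_oracle(sysm, 0.0),
                           sysm.stationary_cov)

    def test_reversible_system_symmetric_at_all_lags(self, ou_family):
        sysm = ou_family[0]
        for tau in (0.1, 0.5, 2.0):
            C = syn.lagged_cov_oracle(sysm, tau)
            assert np.allclose(C, C.T, atol=1e-10)

    def test_asymmetry_strictly_increasing_in_kappa(self, ou_family):
        asyms = [db.global_asymmetry(
            syn.lagged_cov_oracle(s, 3 * s.dt, normalize=True))
            for s in ou_family]
        assert all(b > a for a, b in zip(asyms, asyms[1:]))
        kappas = [s.asymmetry_strength for s in ou_family]
        assert stats.spearmanr(kappas, asyms).statistic == pytest.approx(1.0)


class TestSimulateOU:
    def test_deterministic_under_seed(self, ou_family):
        a = syn.simulate_ou(ou_family[3], 500, seed=9)
        b = syn.simulate_ou(ou_family[3], 500, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_empirical_covariance_converges(self, ou_family):
        sysm = ou_family[1]
        s = syn.simulate_ou(sysm, 200_000, seed=4)
        emp = np.cov(s.values)
        scale = np.abs(sysm.stationary_cov).max()
        assert np.abs(emp - sysm.stationary_cov).max() < 0.05 * scale

    def test_reversible_null_has_symmetric_lagged_cov(self, ou_family):
        s = syn.simulate_ou(ou_family[0], 100_000, seed=5)
        fc = db.lagged_fc(s.values, 3)
        assert db.global_asymmetry(fc) < 1e-2

    def test_too_short_rejected(self, ou_family):
        with pytest.raises(ValueError):
            syn.simulate_ou(ou_family[0], 1, seed=0)


class TestWindowDirectionKL:
    def test_zero_for_reversible_system(self, ou_family):
        assert abs(syn.window_direction_kl(ou_family[0], 20)) < 1e-8

    def test_increasing_in_kappa(self, ou_family):
        kls = [syn.window_direction_kl(s, 20) for s in ou_family]
        assert all(b > a for a, b in zip(kls, kls[1:]))


class TestRampSeries:
    def test_noise_free_windows_strictly_monotone(self):
        s = syn.make_ramp_series(3, 50, 0.0, seed=0)
        assert np.all(np.diff(s.values, axis=1) > 0)

    def test_last_minus_first_separates_directions(self):
        s = syn.make_ramp_series(3, 50, 0.0, seed=0)
        win = s.values[:, 10:20]
        assert np.all(win[:, -1] - win[:, 0] > 0)
        rev = win[:, ::-1]
        assert np.all(rev[:, -1] - rev[:, 0] < 0)

    def test_heavy_noise_degrades_separability(self):
        # sign of (last - first) over a 6-sample window: exact at zero
        # noise, close to chance once noise dwarfs the per-step drift
        rng = np.random.default_rng(1)
        accs = {}
        for noise in (0.0, 10.0):
            feats, labels = [], []
            for i in range(300):
                s = syn.make_ramp_series(1, 6, noise, seed=1000 + i)
                direction = rng.integers(2)
                w = s.values if direction else s.values[:, ::-1]
                feats.append(w[0, -1] - w[0, 0])
                labels.append(direction)
            accs[noise] = np.mean((np.asarray(feats) > 0).astype(int)
                                  == np.asarray(labels))
        assert accs[0.0] == 1.0
        assert accs[10.0] < 0.75


class TestCohort:
    def test_reproducible_under_seed(self):
        spec = syn.CohortSpec([syn.GroupSpec("a", 3, 0.5, 4, 50)], seed=11)
        c1, c2 = syn.make_cohort(spec), syn.make_cohort(spec)
        assert all(np.array_equal(x.values, y.values)
                   for x, y in zip(c1, c2))

    def test_single_group_valid(self):
        cohort = syn.make_cohort(
            syn.CohortSpec([syn.GroupSpec("only", 2, 0.0, 3, 40)], seed=0))
        assert len(cohort) == 2
        assert {s.condition for s in cohort} == {"only"}

    def test_series_length_guard(self):
        with pytest.raises(ValueError, match="series_length"):
            syn.CohortSpec([syn.GroupSpec("a", 2, 0.0, 3, 10)],
                           seed=0, min_series_length=20)

    def test_roundtrip_through_disk(self, tmp_path):
        from arrowtime.signal_io import load_cohort
        cohort = syn.make_cohort(
            syn.CohortSpec([syn.GroupSpec("g", 2, 1.0, 3, 30)], seed=3))
        manifest = syn.write_cohort(cohort, tmp_path)
        loaded = load_cohort(manifest)
        assert len(loaded) == 2
        for a, b in zip(cohort, loaded):
            assert np.allclose(a.values, b.values)
            assert a.participant_id == b.participant_id


class TestEntropyProduction:
    def test_symmetric_chain_near_zero(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 2, size=20_000)  # iid: detailed balance
        assert syn.entropy_production_discrete(seq, 2) < 1e-3

    def test_deterministic_cycle_large(self):
        seq = np.tile([0, 1, 2], 100)
        hp = syn.entropy_production_discrete(seq, 3, pseudocount=1e-6)
        assert hp > 5.0

    def test_reversed_sequence_same_value(self):
        rng = np.random.default_rng(7)
        seq = rng.integers(0, 4, size=100)
        fwd = syn.entropy_production_discrete(seq, 4, pseudocount=1e-3)
        bwd = syn.entropy_production_discrete(seq[::-1], 4, pseudocount=1e-3)
        # KL(P||P^T) is invariant under transposing P, and the reversed
        # sequence's transition counts are the transpose of the original's
        assert fwd == pytest.approx(bwd, rel=1e-6)

    def test_nonnegative_on_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = rng.integers(0, 3, size=rng.integers(10, 200))
            assert syn.entropy_production_discrete(seq, 3) >= 0

    def test_pseudocount_required(self):
        with pytest.raises(ValueError, match="pseudocount"):
            syn.entropy_production_discrete([0, 1, 0], 2, pseudocount=0.0)

    def test_quantile_binning_balanced(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(9000) * 17 + 3
        states = syn.quantile_discretize(x, 3)
        counts = np.bincount(states, minlength=3)
        assert counts.min() > 2500

    def test_discretized_reversible_projection_near_zero(self, ou_family):
        # oracle consistency: kappa = 0 chains produce ~no entropy production
        s = syn.simulate_ou(ou_family[0], 50_000, seed=13)
        states = syn.quantile_discretize(s.values[0], 4)
        assert syn.entropy_production_discrete(states, 4) < 5e-3
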