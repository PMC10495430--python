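import numpy as np
import pytest

from flywide.behavior import Ethogram
from flywide.residual import (
    binarize_mode,
    cv_dimensionality,
    ljung_box_scan,
    pairwise_state_correlations,
    participation,
    pca_modes,
    split_time_blocks,
    state_subspaces,
    transition_triggered_average,
)


def make_ethogram(labels, rate=10.0):
    return Ethogram(labels=np.asarray(labels, dtype=object),
                    states=("quiescent", "run"), sampling_rate=rate)


def alternating_ethogram(T, period=200, rate=10.0):
    labels = np.where((np.arange(T) // period) % 2 == 0, "quiescent", "run")
    return make_ethogram(labels, rate)


class TestLjungBox:
    def test_white_noise_pvalues_uniform(self):
        """On i.i.d. Gaussian residuals the per-cell p-values at a fixed lag
        are uniform (KS test not rejected at 0.01 over 200 cells)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        R = rng.normal(0, 1, (200, 700))
        p = ljung_box_scan(R, lag_min=10, lag_max=60)
        for col in (0, 25, 50):
            assert kstest(p[:, col], "uniform").pvalue > 0.01

    def test_strong_ar_rejected_at_all_lags(self):
        rng = np.random.default_rng(1)
        T = 1500
        R = np.empty((3, T))
        for i in range(3):
            x = np.zeros(T)
            eps = rng.normal(0, 1, T)
            for t in range(1, T):
                x[t] = 0.9 * x[t - 1] + eps[t]
            R[i] = x
        p = ljung_box_scan(R, lag_min=10, lag_max=610)
        assert np.all(p < 1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        R = rng.normal(0, 1, (5, 800))
        p1 = ljung_box_scan(R, lag_min=10, lag_max=50)
        p2 = ljung_box_scan(10.0 * R, lag_min=10, lag_max=50)
        assert np.allclose(p1, p2)

    def test_short_series_truncates_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="truncating"):
            p = ljung_box_scan(rng.normal(0, 1, (1, 300)), lag_min=10, lag_max=610)
        assert p.shape[1] == 290  # lags 10..299


class TestDimensionality:
    def _factor_data(self, rng, n_cells, k, T, noise=0.3, sparse_frac=0.2):
        load = rng.normal(0, 1, (n_cells, k)) * (rng.random((n_cells, k)) < sparse_frac)
        fac = rng.normal(0, 1, (k, T))
        return load @ fac + noise * rng.normal(0, 1, (n_cells, T))

    def test_recovers_planted_factor_count(self):
        rng = np.random.default_rng(4)
        X = self._factor_data(rng, 80, 5, 2000)
        assert cv_dimensionality(X, max_modes=30).m == 5

    def test_pure_noise_gives_zero_or_one(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (40, 800))
            if cv_dimensionality(X, max_modes=15).m <= 1:
                hits += 1
        assert hits >= 45  # >= 90% of seeds

    def test_curve_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(6)
        X = self._factor_data(rng, 30, 3, 900)
        d1 = cv_dimensionality(X, max_modes=10)
        d2 = cv_dimensionality(X[rng.permutation(30)], max_modes=10)
        assert np.allclose(d1.loglik, d2.loglik)
        assert d1.m == d2.m

    def test_eigenvalues_conserve_total_variance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (25, 600))
        p = pca_modes(X)
        total = np.sum(np.var(X, axis=1))
        assert np.sum(p.eigenvalues) == pytest.approx(total, rel=1e-10)

    def test_split_blocks_are_contiguous_and_disjoint(self):
        train, test = split_time_blocks(1000, n_blocks=5)
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(1000))
        assert np.all(np.diff(test) == 1)
        assert test.size == 200


class TestParticipation:
    def test_one_hot_and_uniform_limits(self):
        N = 64
        one_hot = np.zeros((1, N))
        one_hot[0, 3] = 1.0
        uniform = np.full((1, N), 1.0 / np.sqrt(N))
        s1 = participation(one_hot)
        s2 = participation(uniform)
        assert s1.pr[0] == pytest.approx(1.0)
        assert s1.fraction[0] == pytest.approx(1.0 / N)
        assert s2.pr[0] == pytest.approx(N)
        assert s2.fraction[0] == pytest.approx(1.0)

    def test_gaussian_vector_one_third(self):
        rng = np.random.default_rng(8)
        V = rng.normal(0, 1, (200, 1000))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        s = participation(V)
        assert np.mean(s.fraction) == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_invariances(self):
        rng = np.random.default_rng(9)
        v = rng.normal(0, 1, (1, 50))
        s = participation(v)
        s_scaled = participation(3.7 * v)
        s_permuted = participation(v[:, rng.permutation(50)])
        assert s.pr[0] == pytest.approx(s_scaled.pr[0])
        assert s.pr[0] == pytest.approx(s_permuted.pr[0])

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            participation(np.zeros((1, 10)))


class TestBinarize:
    def test_gaussian_mode_selects_nothing(self):
        rng = np.random.default_rng(10)
        assert binarize_mode(rng.normal(0, 1, 1000)).size == 0

    def test_planted_outliers_selected_exactly(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0, 0.01, 500)
        planted = [3, 100, 250, 499]
        v[planted] = 0.5
        assert sorted(binarize_mode(v, sd_thresh=5.0)) == planted

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(12)
        v = rng.normal(0, 0.02, 300)
        v[[5, 7]] = 1.0
        assert np.array_equal(binarize_mode(v), binarize_mode(-v))


class TestStateSubspaces:
    def test_self_projection_is_one(self):
        rng = np.random.default_rng(13)
        R = rng.normal(0, 1, (20, 2000))
        eth = alternating_ethogram(2000)
        res = state_subspaces(R, eth, max_modes=10)
        for b in ("quiescent", "run"):
            assert np.allclose(res.e_curves[(b, b)], 1.0, atol=1e-10)

    def test_state_independent_residuals_share_subspace(self):
        """When residual factors are active regardless of state, each state's
        modes explain >= 90% of the other's variance at m = 2."""
        rng = np.random.default_rng(14)
        T, N = 4000, 40
        load = rng.normal(0, 1, (N, 3)) * (rng.random((N, 3)) < 0.3)
        X = load @ rng.normal(0, 1, (3, T)) + 0.1 * rng.normal(0, 1, (N, T))
        eth = alternating_ethogram(T)
        res = state_subspaces(X, eth, max_modes=10)
        assert res.e_curves[("quiescent", "run")][1] >= 0.9
        assert res.e_curves[("run", "quiescent")][1] >= 0.9

    def test_run_only_factors_invisible_from_quiescence(self):
        """A factor active only during running leaves ~no variance for
        quiescent-fit modes to explain in the run state beyond noise."""
        rng = np.random.default_rng(15)
        T, N = 4000, 200
        eth = alternating_ethogram(T)
        run_mask = (eth.labels == "run").astype(float)
        load = np.zeros((N, 1))
        load[:6, 0] = 1.0
        noise_sd = 0.05
        X = load @ (rng.normal(0, 1, (1, T)) * run_mask) + noise_sd * rng.normal(0, 1, (N, T))
        q = np.where(eth.labels == "quiescent")[0]
        r = np.where(eth.labels == "run")[0]
        q_modes = pca_modes(X[:, q])
        run_pca = pca_modes(X[:, r])
        Xr = X[:, r] - X[:, r].mean(axis=1, keepdims=True)
        proj_var = np.sum((q_modes.modes[:5] @ Xr).var(axis=1))
        # quiescent modes are noise directions: they capture only a noise-
        # floor share of the run state's variance
        assert proj_var < 0.1 * np.sum(run_pca.eigenvalues[:5])

    def test_absent_state_raises(self):
        rng = np.random.default_rng(16)
        labels = np.full(500, "quiescent", dtype=object)
        eth = make_ethogram(labels)
        with pytest.raises(ValueError, match="absent"):
            state_subspaces(rng.normal(0, 1, (10, 500)), eth)


class TestPairwiseCorrelations:
    def test_state_independent_diffs_near_zero(self):
        rng = np.random.default_rng(17)
        T, N = 6000, 25
        load = rng.normal(0, 1, (N, 4))
        X = load @ rng.normal(0, 1, (4, T)) + 0.5 * rng.normal(0, 1, (N, T))
        eth = alternating_ethogram(T)
        _, _, diffs = pairwise_state_correlations(X, eth)
        assert abs(np.mean(diffs)) < 0.02
        assert np.std(diffs) < 0.1

    def test_identical_cells_and_antisymmetry(self):
        rng = np.random.default_rng(18)
        T = 2000
        base = rng.normal(0, 1, T)
        X = np.vstack([base, base, rng.normal(0, 1, T)])
        eth = alternating_ethogram(T)
        cq, cr, diffs = pairwise_state_correlations(X, eth)
        assert cq[0, 1] == pytest.approx(1.0)
        assert cr[0, 1] == pytest.approx(1.0)
        _, _, diffs_swapped = pairwise_state_correlations(
            X, eth, states=("run", "quiescent")
        )
        assert np.allclose(diffs, -diffs_swapped)

    def test_zero_variance_cell_excluded(self):
        rng = np.random.default_rng(19)
        T = 1000
        X = rng.normal(0, 1, (3, T))
        eth = alternating_ethogram(T)
        X[2, eth.labels == "run"] = 0.0  # flat within the run state
        cq, cr, diffs = pairwise_state_correlations(X, eth)
        assert np.isnan(cr[2, 0]) and np.isnan(cr[0, 2])
        assert diffs.size == 1  # only the (0,1) pair survives


class TestTransitionTriggered:
    def _eth(self, T, bout=120):
        return alternating_ethogram(T, period=bout)

    def test_null_residuals_flat_around_transition(self):
        rng = np.random.default_rng(20)
        T = 12000
        X = rng.normal(0, 1, (50, T))
        eth = self._eth(T)
        out = transition_triggered_average(X, eth, "quiescent", "run", window_s=3.0)
        pre = out["mean"][: out["mean"].size // 2]
        assert np.all(np.abs(pre.mean()) <= 2.0 * out["sem"].mean() + 1e-12)

    def test_planted_pre_transition_ramp_detected(self):
        rng = np.random.default_rng(21)
        T = 12000
        N = 50
        X = rng.normal(0, 1, (N, T))
        eth = self._eth(T)
        W = 30  # 3 s at 10 Hz
        for label, start, stop in eth.bouts():
            if label == "quiescent" and stop < T and eth.labels[stop] == "run":
                ramp = np.linspace(0, 3.0, W)
                X[: N // 10, stop - W : stop] += ramp[None, :]
        out = transition_triggered_average(X, eth, "quiescent", "run", window_s=3.0)
        pre_end = out["mean"][out["mean"].size // 2 - 5 : out["mean"].size // 2]
        sem = out["sem"][out["mean"].size // 2 - 5 : out["mean"].size // 2]
        assert np.all(pre_end > 2.0 * sem)

    def test_window_exceeding_bouts_excludes_and_errors(self):
        rng = np.random.default_rng(22)
        T = 3000
        X = rng.normal(0, 1, (5, T))
        eth = self._eth(T, bout=40)  # 4 s bouts
        with pytest.raises(ValueError, match="transitions"):
            transition_triggered_average(X, eth, "quiescent", "run", window_s=10.0)
        out = transition_triggered_average(X, eth, "quiescent", "run", window_s=1.5)
        assert out["n_transitions"] >= 3
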