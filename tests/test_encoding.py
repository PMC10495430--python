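import numpy as np
import pytest

from flywide.behavior import Ethogram, MarkerTimeSeries, StateProbabilities, ethogram_from_probs
from flywide.encoding import (
    PopulationEncoder,
    behavior_kernel,
    convolve_state,
    fit_cell,
    marker_principal_components,
    markers_model_fit,
    max_crosscorr,
    variance_rate_by_behavior,
)
from flywide.synthetic import BehaviorSimConfig, NeuralSimConfig, generate_activity, generate_behavior, generate_cells


class TestKernel:
    def test_unit_mass_and_symmetry(self):
        k = behavior_kernel(tau=2.0, phi=1.0, dt=0.1)
        assert k.weights.sum() == pytest.approx(1.0)
        # symmetric about phi
        center = np.argmax(k.weights)
        assert k.offsets[center] * k.dt == pytest.approx(1.0, abs=0.1)
        assert np.allclose(k.weights, k.weights[::-1])

    def test_delta_limit_reproduces_input(self):
        rng = np.random.default_rng(0)
        b = rng.random(500)
        y = convolve_state(b, tau=0.01, phi=0.0, dt=0.1)
        assert np.max(np.abs(y - b)) < 1e-6

    def test_constant_input_preserved(self):
        y = convolve_state(np.full(800, 0.37), tau=3.0, phi=2.0, dt=0.1)
        assert np.allclose(y, 0.37)

    def test_impulse_peaks_at_phi_with_symmetric_decay(self):
        T, dt = 2000, 0.1
        b = np.zeros(T)
        b[1000] = 1.0
        tau, phi = 1.5, 2.0
        y = convolve_state(b, tau=tau, phi=phi, dt=dt)
        peak = int(np.argmax(y))
        assert peak == 1000 + int(round(phi / dt))
        # e-folding on both sides at lag tau
        k = int(round(tau / dt))
        assert y[peak + k] / y[peak] == pytest.approx(np.exp(-1), rel=0.05)
        assert y[peak - k] / y[peak] == pytest.approx(np.exp(-1), rel=0.05)

    def test_oversized_kernel_rejected_without_truncation(self):
        b = np.zeros(100)
        with pytest.raises(ValueError, match="exceeds series length"):
            convolve_state(b, tau=60.0, phi=0.0, dt=0.1)
        # truncation caps the support instead
        y = convolve_state(np.ones(100), tau=60.0, phi=0.0, dt=0.1, truncate=True)
        assert np.allclose(y, 1.0)


class TestFitCell:
    def test_exact_recovery_noiseless(self, behavior_short, coarse_grids):
        """A synthetic cell with known (gamma, tau, phi) and no noise is
        recovered exactly (r^2 = 1) after grid + polish."""
        probs = behavior_short.state_probs
        dt = 1.0 / probs.sampling_rate
        tau_true, phi_true = 2.0, 1.0
        gam = {"run": 0.3, "front_groom": 0.1, "back_groom": -0.05, "abdomen_bend": 0.0}
        f = 0.02 + sum(
            g * convolve_state(probs.row(b), tau_true, phi_true, dt)
            for b, g in gam.items()
        )
        tau_grid, phi_grid = coarse_grids
        fit = fit_cell(f, probs, tau_grid=tau_grid, phi_grid=phi_grid, polish=True)
        assert fit.r2 > 0.9999
        assert fit.tau == pytest.approx(tau_true, abs=0.05)
        assert fit.phi == pytest.approx(phi_true, abs=0.05)
        for b, g in gam.items():
            assert fit.gamma[b] == pytest.approx(g, abs=1e-3)

    def test_r2_nondecreasing_with_wider_phi_grid(self, behavior_short):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, behavior_short.state_probs.n_frames)
        tau_grid = np.geomspace(0.5, 10.0, 4)
        narrow = fit_cell(f, behavior_short.state_probs, tau_grid=tau_grid,
                          phi_grid=np.linspace(-2, 2, 3), polish=False)
        wide = fit_cell(f, behavior_short.state_probs, tau_grid=tau_grid,
                        phi_grid=np.linspace(-8, 8, 9), polish=False)
        assert wide.r2 >= narrow.r2 - 1e-12

    def test_constant_behavior_flagged_unidentifiable(self):
        T = 1000
        p = np.zeros((2, T))
        p[0] = 1.0  # "always" state: constant regressor
        probs = StateProbabilities(probs=p, states=("always", "never"), sampling_rate=10.0)
        enc = PopulationEncoder(probs, behaviors=("always", "never"),
                                tau_grid=np.array([1.0]), phi_grid=np.array([0.0]))
        assert "always" in enc.unidentifiable and "never" in enc.unidentifiable

    def test_population_tau_histogram_bimodal(self, behavior_10min):
        """Fitted kernel time constants on a bimodal-tau population fall into
        the two generating ranges."""
        cfg = NeuralSimConfig(n_cells=60, seed=6, n_residual_clusters=0,
                              n_motion_cells=0, noise_sd=0.03, cell_dynamics_sd=0.0,
                              tau_fast_range=(0.5, 2.0), tau_slow_range=(15.0, 40.0))
        cells = generate_cells(cfg)
        act = generate_activity(behavior_10min, cells, cfg)
        enc = PopulationEncoder(behavior_10min.state_probs,
                                tau_grid=np.geomspace(0.3, 50.0, 10),
                                phi_grid=np.linspace(-10.0, 25.0, 8))
        fits = enc.fit(act.dff)
        taus = np.array([f.tau for f in fits])
        frac_fast = np.mean(taus < 4.0)
        frac_slow = np.mean(taus > 10.0)
        assert frac_fast == pytest.approx(cfg.frac_fast_tau, abs=0.15)
        assert frac_slow == pytest.approx(cfg.frac_slow_tau, abs=0.15)
        assert np.mean((taus > 4.0) & (taus < 10.0)) < 0.15  # a gap between modes


class TestShiftSignificance:
    def test_noiseless_behavior_driven_cell_significant(self, behavior_short, coarse_grids):
        probs = behavior_short.state_probs
        dt = 1.0 / probs.sampling_rate
        f = 0.3 * convolve_state(probs.row("run"), 1.5, 1.0, dt)
        tau_grid, phi_grid = coarse_grids
        enc = PopulationEncoder(probs, tau_grid=tau_grid, phi_grid=phi_grid, polish=True)
        fit = enc.fit_with_significance(f, seed=0)[0]
        assert fit.significant
        assert fit.r2 > 0.999
        assert fit.shifted_r2.shape == (5,)
        assert fit.r2 > fit.shifted_r2.max()

    def test_white_noise_false_positive_rate_calibrated(self, behavior_short):
        """Under exchangeability the true fit ranks first among {true + 5
        nulls} with probability ~1/6; the observed significant fraction over
        200 white-noise cells stays within [0.05, 0.30]."""
        rng = np.random.default_rng(11)
        F = rng.normal(0, 1, (200, behavior_short.state_probs.n_frames))
        enc = PopulationEncoder(behavior_short.state_probs,
                                tau_grid=np.geomspace(0.3, 30.0, 8),
                                phi_grid=np.linspace(-10.0, 20.0, 7))
        fits = enc.fit_with_significance(F, seed=7)
        rate = np.mean([f.significant for f in fits])
        assert 0.05 <= rate <= 0.30

    def test_session_too_short_raises(self, behavior_short):
        p = behavior_short.state_probs
        short = StateProbabilities(probs=p.probs[:, :10], states=p.states,
                                   sampling_rate=p.sampling_rate)
        enc = PopulationEncoder(short, tau_grid=np.array([0.1]), phi_grid=np.array([0.0]))
        with pytest.raises(ValueError, match="too short"):
            enc.fit_with_significance(np.zeros((1, 10)))


class TestMarkersModel:
    def test_markers_nest_states_when_linearly_related(self, behavior_short, coarse_grids):
        """If the marker coordinates are an invertible linear function of the
        state probabilities, the markers model explains at least as much
        variance as the states model."""
        probs = behavior_short.state_probs
        T = probs.n_frames
        rng = np.random.default_rng(3)
        mix = rng.normal(0, 1, (16, len(probs.states)))
        xy = (mix @ probs.probs).T.reshape(T, 8, 2) + rng.normal(0, 1e-6, (T, 8, 2))
        markers = MarkerTimeSeries(xy=xy, sampling_rate=probs.sampling_rate)
        dt = 1.0 / probs.sampling_rate
        f = 0.4 * convolve_state(probs.row("run"), 1.0, 0.5, dt) + 0.05
        tau_grid, phi_grid = coarse_grids
        states_fit = fit_cell(f, probs, tau_grid=tau_grid, phi_grid=phi_grid, polish=False)
        markers_fit, _ = markers_model_fit(f, markers, tau_grid=tau_grid,
                                           phi_grid=phi_grid, seed=0)
        assert markers_fit.r2 >= states_fit.r2 - 0.01

    def test_zero_variance_marker_dropped(self, behavior_short):
        T = behavior_short.state_probs.n_frames
        rng = np.random.default_rng(5)
        xy = rng.normal(0, 1, (T, 8, 2))
        xy[:, 0, 0] = 4.2  # frozen coordinate
        markers = MarkerTimeSeries(xy=xy, sampling_rate=10.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = marker_principal_components(markers)
        assert scores.shape[0] == 15

    def test_excess_variance_near_zero_for_noise_cells(self, behavior_short):
        """Excess variance (r^2 minus mean shifted null r^2) of white-noise
        cells averages to ~0."""
        probs = behavior_short.state_probs
        T = probs.n_frames
        rng = np.random.default_rng(9)
        xy = np.cumsum(rng.normal(0, 1, (T, 8, 2)), axis=0)
        markers = MarkerTimeSeries(xy=xy, sampling_rate=probs.sampling_rate)
        scores = marker_principal_components(markers)
        names = tuple(f"pc{k}" for k in range(scores.shape[0]))
        probs_like = StateProbabilities.__new__(StateProbabilities)
        probs_like.probs, probs_like.states, probs_like.sampling_rate = (
            scores, names, probs.sampling_rate)
        enc = PopulationEncoder(probs_like, behaviors=names,
                                tau_grid=np.geomspace(0.5, 10.0, 4),
                                phi_grid=np.linspace(-5.0, 5.0, 3))
        F = rng.normal(0, 1, (100, T))
        fits = enc.fit_with_significance(F, seed=2)
        excess = [f.r2 - f.shifted_r2.mean() for f in fits]
        assert abs(np.mean(excess)) <= 0.05


class TestCrossCorrelation:
    def test_identity_peaks_at_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 2000)
        cc, lag = max_crosscorr(x, x, max_lag_s=5.0, sampling_rate=10.0)
        assert cc == pytest.approx(1.0)
        assert lag == 0.0

    def test_delayed_copy_peaks_at_delay(self):
        rng = np.random.default_rng(2)
        run = (rng.random(3000) < 0.2).astype(float)
        delay = 30  # frames = 3 s
        f = np.concatenate([np.zeros(delay), run[:-delay]])
        cc, lag = max_crosscorr(f, run, max_lag_s=6.0, sampling_rate=10.0)
        assert lag == pytest.approx(3.0)
        assert cc > 0.9

    def test_anticorrelated_cell_low_max(self):
        rng = np.random.default_rng(3)
        run = (rng.random(5000) < 0.2).astype(float)
        f = -run + 1e-6 * rng.normal(size=5000)
        cc, _ = max_crosscorr(f, run, max_lag_s=5.0, sampling_rate=10.0)
        assert cc < 0.2  # max of an anticorrelated pair is noise-level

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            max_crosscorr(np.ones(100), np.random.default_rng(0).random(100),
                          max_lag_s=1.0, sampling_rate=10.0)


class TestVarianceRate:
    def _setup(self, behavior_short, coarse_grids, gammas):
        probs = behavior_short.state_probs
        dt = 1.0 / probs.sampling_rate
        f = sum(
            g * convolve_state(probs.row(b), 1.0, 0.5, dt) for b, g in gammas.items()
        ) + 0.01
        tau_grid, phi_grid = coarse_grids
        fit = fit_cell(f, probs, tau_grid=tau_grid, phi_grid=phi_grid, polish=False)
        eth = ethogram_from_probs(probs)
        return [fit], probs, eth

    def test_running_rate_is_one_and_zero_weight_zero(self, behavior_short, coarse_grids):
        gammas = {"run": 0.3, "front_groom": 0.1, "back_groom": 0.05, "abdomen_bend": 0.02}
        fits, probs, eth = self._setup(behavior_short, coarse_grids, gammas)
        table = variance_rate_by_behavior(fits, probs, eth)
        run_rows = table[(table.behavior == "run") & (table.n_cells > 0)]
        assert np.allclose(run_rows.rate_mean.dropna(), 1.0)
        # a behavior with zero fitted weight has rate 0
        fits[0].gamma["front_groom"] = 0.0
        table2 = variance_rate_by_behavior(fits, probs, eth)
        fg = table2[(table2.behavior == "front_groom") & (table2.n_cells > 0)]
        assert np.allclose(fg.rate_mean.dropna(), 0.0)

    def test_equal_weights_shorter_bouts_give_rate_above_one(self):
        """A behavior with the same weight as running but less total time has
        a higher variance rate (the normalization rewards brevity)."""
        rng = np.random.default_rng(12)
        T = 6000
        run = np.zeros(T)
        flail = np.zeros(T)
        # running 30% of the time, flailing 10%, same weight
        run[: int(0.3 * T)] = 1.0
        rng.shuffle(run)
        flail[: int(0.1 * T)] = 1.0
        rng.shuffle(flail)
        flail[run == 1] = 0.0
        quiet = 1.0 - run - flail
        probs = StateProbabilities(probs=np.vstack([quiet, run, flail]),
                                   states=("quiescent", "run", "flail"), sampling_rate=10.0)
        labels = np.where(run == 1, "run", np.where(flail == 1, "flail", "quiescent")).astype(object)
        eth = Ethogram(labels=labels, states=probs.states, sampling_rate=10.0)
        dt = 0.1
        f = 0.2 * convolve_state(run, 1.0, 0.0, dt) + 0.2 * convolve_state(flail, 1.0, 0.0, dt)
        fit = fit_cell(f, probs, behaviors=("run", "flail"),
                       tau_grid=np.geomspace(0.5, 4.0, 4),
                       phi_grid=np.array([0.0]), polish=False)
        table = variance_rate_by_behavior([fit], probs, eth)
        flail_rate = table[(table.behavior == "flail") & (table.n_cells > 0)].rate_mean.dropna()
        assert (flail_rate > 1.0).all()

    def test_absent_behavior_excluded(self, behavior_short, coarse_grids):
        gammas = {"run": 0.3, "front_groom": 0.1, "back_groom": 0.05, "abdomen_bend": 0.02}
        fits, probs, eth = self._setup(behavior_short, coarse_grids, gammas)
        # relabel all abdomen_bend frames so the behavior is absent
        eth.labels[eth.labels == "abdomen_bend"] = "quiescent"
        table = variance_rate_by_behavior(fits, probs, eth)
        assert "abdomen_bend" not in set(table.behavior)
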