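"""Synthetic data generator with known ground truth.

Emulates the statistical structure of brainwide single-cell recordings in a
behaving fly:

* **Behavior** -- a semi-Markov state process. Running switches on and off as
  a fast telegraph process whose entry rate is modulated by a slow
  Ornstein-Uhlenbeck "tendency" signal, so the run-state autocorrelation is
  a sum of two exponentials (a fast bout timescale and a slow tendency
  timescale). Non-running frames cycle among quiescence, grooming, and
  abdomen bending with occupancies matching configured targets. Soft state
  probabilities come from boxcar-smoothed one-hot labels sharpened by a
  temperature parameter. Synthetic marker coordinates and a ball
  motion-energy signal are constructed to be consistent with the heuristic
  labeling rules (ball ME is high exactly during running, limb markers move
  during the corresponding grooming states, and so on).

* **Cells** -- 3D somata in a box with a declared midline; most cells couple
  to behavior through symmetric exponential kernels with a bimodal
  distribution of time constants; a minority are anticorrelated with running
  and concentrated in a synthetic pars-intercerebralis (PI) region; sparse
  residual clusters are placed as compact blobs, a configurable fraction
  mirrored across the midline.

* **Activity** -- the exact forward model the encoding stage assumes
  (quadratic drift + kernel-filtered behavior terms) plus smooth cluster
  latent factors and white noise; raw red/green channels add exponential
  photobleaching and, for a few cells, artifactual red-channel variance so
  the fluorescence stage has something to invert and to flag.

All randomness derives from per-operation substreams of ``config.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import (
    MARKER_NAMES,
    Ethogram,
    MarkerTimeSeries,
    StateProbabilities,
)
from .encoding import convolve_state
from .fluorescence import DualChannelTraces

__all__ = [
    "BehaviorSimConfig",
    "NeuralSimConfig",
    "BehaviorSim",
    "CellCoordinates",
    "GroundTruth",
    "ActivitySim",
    "generate_behavior",
    "generate_cells",
    "generate_activity",
    "generate_dataset",
]

DEFAULT_STATES = ("quiescent", "run", "front_groom", "back_groom", "abdomen_bend")

#: Fraction of time in each state, matching the occupancies reported for
#: tethered flies (quiescent 50%, run 19%, front groom 6%, back groom 15%,
#: abdomen bend 10%).
DEFAULT_OCCUPANCY = {
    "quiescent": 0.50,
    "run": 0.19,
    "front_groom": 0.06,
    "back_groom": 0.15,
    "abdomen_bend": 0.10,
}

#: Per-state frame-to-frame marker displacement SD (pixels) for each marker
#: group, chosen so the heuristic-label thresholds separate the states.
_MARKER_AMPLITUDES = {
    #            fore  mid   hind  abdomen
    "quiescent": (0.05, 0.05, 0.05, 0.05),
    "run": (2.0, 2.0, 2.0, 0.3),
    "front_groom": (1.0, 0.1, 0.05, 0.05),
    "back_groom": (0.05, 0.1, 1.0, 0.05),
    "abdomen_bend": (0.1, 0.1, 0.1, 3.0),
    "flail": (2.5, 2.5, 2.5, 0.5),
}


@dataclass
class BehaviorSimConfig:
    """Configuration of the behavioral simulation.

    ``bout_timescale_fast`` is the fast relaxation time of the run/not-run
    switching process (the entry and exit rates are p(t)/tau_fast and
    (1 - p(t))/tau_fast), so the conditional autocorrelation time of running
    equals the configured value; the mean run-bout duration is then
    tau_fast / (1 - p). ``tendency_timescale_slow`` is the correlation time
    of the Ornstein-Uhlenbeck modulation of the run-entry log-odds.
    """

    sampling_rate: float = 10.0
    duration: float = 1200.0
    states: tuple = DEFAULT_STATES
    bout_timescale_fast: float = 1.0
    tendency_timescale_slow: float = 40.0
    state_occupancy_targets: dict = field(default_factory=lambda: dict(DEFAULT_OCCUPANCY))
    prob_softness: float = 0.25
    tendency_sd: float = 1.0
    nonrun_dwell_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        total = sum(self.state_occupancy_targets.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"occupancy targets must sum to 1, got {total}")
        if self.bout_timescale_fast <= 0 or self.tendency_timescale_slow <= 0:
            raise ValueError("timescales must be positive")
        if self.bout_timescale_fast >= self.tendency_timescale_slow:
            raise ValueError("fast bout timescale must be smaller than the slow tendency timescale")
        if set(self.state_occupancy_targets) != set(self.states):
            raise ValueError("occupancy targets must name exactly the configured states")
        if self.duration < 10.0 * self.tendency_timescale_slow:
            warnings.warn(
                "duration is shorter than 10x the slow tendency timescale; "
                "the two-exponential autocorrelation fit will be unstable",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class NeuralSimConfig:
    """Configuration of the neural population simulation.

    Activity is in dF/F units. Kernel time constants are bimodal: a
    ``frac_fast_tau`` fraction of cells draw tau from ``tau_fast_range`` and
    the rest from ``tau_slow_range`` (seconds). Residual structure comes
    from ``n_residual_clusters`` groups of cells sharing a smooth latent
    factor; cluster sizes are exponentially distributed (clipped at 2) and a
    ``bilateral_fraction`` of clusters is mirrored across the midline.

    Every cell additionally carries smooth idiosyncratic residual dynamics
    (``cell_dynamics_sd``, an Ornstein-Uhlenbeck process with correlation
    time ``cell_dynamics_timescale``), emulating the observation that all
    recorded cells show temporally structured residual activity. For
    cluster members most of that dynamic budget is the shared latent, so
    their idiosyncratic amplitude is scaled down by
    ``member_dynamics_factor``.
    """

    n_cells: int = 200
    frac_fast_tau: float = 0.57
    frac_slow_tau: float = 0.43
    tau_fast_range: tuple = (0.5, 3.0)
    tau_slow_range: tuple = (20.0, 60.0)
    frac_anticorrelated: float = 0.10
    n_residual_clusters: int = 10
    cluster_size_mean: float = 4.0
    cluster_latent_timescale: float = 5.0
    cluster_loading: float = 0.25
    bilateral_fraction: float = 0.5
    cluster_jitter_um: float = 8.0
    noise_sd: float = 0.05
    cell_dynamics_sd: float = 0.1
    cell_dynamics_timescale: float = 5.0
    member_dynamics_factor: float = 0.75
    bleach_amplitude: float = 0.3
    bleach_timescale: float = 600.0
    n_motion_cells: int = 5
    gamma_run_range: tuple = (0.05, 0.4)
    gamma_other_max: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_fast_range", "tau_slow_range", "gamma_run_range"):
            setattr(self, name, tuple(getattr(self, name)))
        for name in ("frac_fast_tau", "frac_slow_tau", "frac_anticorrelated", "bilateral_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.frac_fast_tau + self.frac_slow_tau - 1.0) > 1e-6:
            raise ValueError("frac_fast_tau and frac_slow_tau must sum to 1")
        for name in ("cluster_latent_timescale", "bleach_timescale", "cluster_size_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_size_mean < 2:
            raise ValueError("cluster sizes are >= 2, so cluster_size_mean must be >= 2")


@dataclass
class BehaviorSim:
    """Output bundle of :func:`generate_behavior`."""

    config: BehaviorSimConfig
    hard_labels: np.ndarray
    state_probs: StateProbabilities
    ethogram: Ethogram
    ball_signal: np.ndarray
    markers: MarkerTimeSeries
    run_tendency: np.ndarray


@dataclass
class CellCoordinates:
    """Cell somata positions (micrometers) and the midline lateral coordinate."""

    xyz: np.ndarray
    midline: float
    lateral_axis: int = 0
    pi_region_mask: np.ndarray | None = None


@dataclass
class GroundTruth:
    """Generating parameters for recovery tests."""

    behaviors: tuple
    gamma: np.ndarray  # n_cells x n_behaviors
    tau: np.ndarray
    phi: np.ndarray
    alpha: np.ndarray  # n_cells x 3
    cluster_members: list
    cluster_loadings: list
    latents: np.ndarray | None  # n_clusters x T
    anticorrelated_mask: np.ndarray
    motion_cell_mask: np.ndarray | None = None


@dataclass
class ActivitySim:
    """Output bundle of :func:`generate_activity`."""

    dff: np.ndarray
    traces: DualChannelTraces
    truth: GroundTruth
    behavior_prediction: np.ndarray


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def _solve_logit_offset(p_target: float, sd: float) -> float:
    """mu such that E[sigmoid(mu + x)] = p_target for x ~ N(0, sd^2)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)

    def mean_p(mu):
        return float(np.sum(weights / np.sqrt(2 * np.pi) * (1.0 / (1.0 + np.exp(-(mu + sd * nodes))))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < p_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ou_series(
    n: int, dt: float, timescale: float, sd: float, rng: np.random.Generator,
    n_series: int | None = None,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path(s) with SD ``sd`` and correlation
    time ``timescale``; shape (n,) or (n_series, n)."""
    from scipy.signal import lfilter

    rho = np.exp(-dt / timescale)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    shape = (n,) if n_series is None else (n_series, n)
    eps = rng.normal(0.0, innov_sd, size=shape)
    # first sample from the stationary distribution
    eps[..., 0] = rng.normal(0.0, sd, size=shape[:-1] if n_series else ())
    return lfilter([1.0], [1.0, -rho], eps, axis=-1)


def _soften_labels(
    labels: np.ndarray, states: tuple, softness: float, sampling_rate: float
) -> np.ndarray:
    """Boxcar-smoothed one-hot labels sharpened with a temperature.

    The boxcar width scales with the temperature, so in the zero-temperature
    limit the probabilities are exactly one-hot and argmax reproduces the
    hard sequence.
    """
    T = labels.shape[0]
    onehot = np.zeros((len(states), T))
    for i, s in enumerate(states):
        onehot[i, labels == s] = 1.0
    if softness <= 0:
        return onehot
    width = max(1, int(round(2.0 * softness * sampling_rate)))
    if width > 1:
        kernel = np.ones(width) / width
        sm = np.empty_like(onehot)
        for i in range(onehot.shape[0]):
            padded = np.pad(onehot[i], width, mode="edge")
            sm[i] = np.convolve(padded, kernel, mode="same")[width:-width]
    else:
        sm = onehot.copy()
    sharp = np.power(np.maximum(sm, 1e-12), 1.0 / softness)
    return sharp / sharp.sum(axis=0, keepdims=True)


def generate_behavior(config: BehaviorSimConfig) -> BehaviorSim:
    """Simulate the behavioral state sequence, soft probabilities, markers,
    and ball motion-energy signal."""
    n = config.n_frames
    dt = 1.0 / config.sampling_rate
    states = config.states
    rng_state = _rng(config.seed, 0)
    rng_marker = _rng(config.seed, 1)

    p_run_target = config.state_occupancy_targets["run"]
    mu = _solve_logit_offset(p_run_target, config.tendency_sd)
    tendency = _ou_series(n, dt, config.tendency_timescale_slow, config.tendency_sd, rng_state)
    p_run = 1.0 / (1.0 + np.exp(-(mu + tendency)))

    nonrun_states = [s for s in states if s != "run"]
    nonrun_w = np.array([config.state_occupancy_targets[s] for s in nonrun_states])
    nonrun_w = nonrun_w / nonrun_w.sum()

    labels = np.empty(n, dtype=object)
    tau_f = config.bout_timescale_fast
    running = rng_state.random() < p_run_target
    current_nonrun = nonrun_states[int(rng_state.choice(len(nonrun_states), p=nonrun_w))]
    u = rng_state.random(n)
    u_dwell = rng_state.random(n)
    for t in range(n):
        if running:
            if u[t] < dt * (1.0 - p_run[t]) / tau_f:
                running = False
                current_nonrun = nonrun_states[int(rng_state.choice(len(nonrun_states), p=nonrun_w))]
        else:
            if u[t] < dt * p_run[t] / tau_f:
                running = True
            elif u_dwell[t] < dt / config.nonrun_dwell_mean:
                current_nonrun = nonrun_states[int(rng_state.choice(len(nonrun_states), p=nonrun_w))]
        labels[t] = "run" if running else current_nonrun

    probs = _soften_labels(labels, states, config.prob_softness, config.sampling_rate)
    state_probs = StateProbabilities(probs=probs, states=states, sampling_rate=config.sampling_rate)
    ethogram = Ethogram(labels=labels.copy(), states=states, sampling_rate=config.sampling_rate)

    # ball motion energy: high exactly during run
    run_ind = (labels == "run").astype(float)
    ball = run_ind * (0.8 + 0.15 * np.abs(rng_marker.normal(size=n))) + 0.02 * np.abs(
        rng_marker.normal(size=n)
    )

    # marker coordinates: random-walk-free jitter around resting positions,
    # with per-state displacement amplitudes per marker group
    group_of = {m: g for g, members in enumerate(
        (("fb", "ft"), ("mb", "mt"), ("hb", "ht"), ("ab", "at"))
    ) for m in members}
    base = rng_marker.uniform(50, 400, size=(len(MARKER_NAMES), 2))
    amp = np.empty((n, len(MARKER_NAMES)))
    for t in range(n):
        amps = _MARKER_AMPLITUDES.get(labels[t], _MARKER_AMPLITUDES["quiescent"])
        for j, name in enumerate(MARKER_NAMES):
            amp[t, j] = amps[group_of[name]]
    xy = base[None, :, :] + amp[:, :, None] * rng_marker.normal(size=(n, len(MARKER_NAMES), 2))
    markers = MarkerTimeSeries(xy=xy, sampling_rate=config.sampling_rate)

    return BehaviorSim(
        config=config,
        hard_labels=labels,
        state_probs=state_probs,
        ethogram=ethogram,
        ball_signal=ball,
        markers=markers,
        run_tendency=tendency,
    )


# ---------------------------------------------------------------------------
# cell geometry

BOX_UM = (300.0, 340.0, 100.0)  # lateral, anterior-posterior, depth
MIDLINE_UM = 150.0
PI_REGION = ((130.0, 170.0), (0.0, 60.0), (60.0, 100.0))


def generate_cells(config: NeuralSimConfig) -> tuple[CellCoordinates, GroundTruth]:
    """Place cell somata, residual clusters, and the anticorrelated PI group.

    Cluster sizes are drawn from an exponential distribution (mean
    ``cluster_size_mean``) clipped below at 2; bilateral clusters are built
    as mirrored pairs of jittered positions, so with ``bilateral_fraction=1``
    every cluster's member set is exactly invariant under midline reflection.
    """
    rng = _rng(config.seed, 2)
    n = config.n_cells

    sizes = []
    for _ in range(config.n_residual_clusters):
        s = max(2, int(round(rng.exponential(config.cluster_size_mean))))
        sizes.append(s)
    bilateral = np.zeros(len(sizes), dtype=bool)
    if sizes:
        n_bilateral = int(round(config.bilateral_fraction * len(sizes)))
        bilateral[:n_bilateral] = True
        sizes = [s + (s % 2) if b else s for s, b in zip(sizes, bilateral)]
    if sizes and n < 2 * max(sizes):
        raise ValueError(
            f"n_cells={n} is smaller than twice the largest requested cluster ({max(sizes)})"
        )
    if sum(sizes) > n:
        raise ValueError("clusters request more cells than the population contains")

    xyz = np.column_stack(
        [rng.uniform(0, BOX_UM[0], n), rng.uniform(0, BOX_UM[1], n), rng.uniform(0, BOX_UM[2], n)]
    )

    members_list = []
    cursor = 0
    for size, is_bilateral in zip(sizes, bilateral):
        members = np.arange(cursor, cursor + size)
        cursor += size
        if is_bilateral:
            half = size // 2
            center = np.array(
                [rng.uniform(25, MIDLINE_UM - 30), rng.uniform(30, BOX_UM[1] - 30),
                 rng.uniform(20, BOX_UM[2] - 20)]
            )
            pos = center[None, :] + rng.normal(0, config.cluster_jitter_um, size=(half, 3))
            mirrored = pos.copy()
            mirrored[:, 0] = 2 * MIDLINE_UM - pos[:, 0]
            xyz[members[:half]] = pos
            xyz[members[half:]] = mirrored
        else:
            center = np.array(
                [rng.uniform(25, BOX_UM[0] - 25), rng.uniform(30, BOX_UM[1] - 30),
                 rng.uniform(20, BOX_UM[2] - 20)]
            )
            xyz[members] = center[None, :] + rng.normal(0, config.cluster_jitter_um, size=(size, 3))
        members_list.append(members)

    # anticorrelated cells concentrated in the synthetic PI region; drawn from
    # cells not already claimed by a residual cluster
    n_anti = int(round(config.frac_anticorrelated * n))
    free = np.arange(cursor, n)
    if n_anti > free.size:
        n_anti = free.size
    anti_idx = free[:n_anti]
    anticorr = np.zeros(n, dtype=bool)
    anticorr[anti_idx] = True
    pi_mask = np.zeros(n, dtype=bool)
    pi_mask[anti_idx] = True
    for axis, (lo, hi) in enumerate(PI_REGION):
        xyz[anti_idx, axis] = rng.uniform(lo, hi, size=n_anti)

    coords = CellCoordinates(xyz=xyz, midline=MIDLINE_UM, lateral_axis=0, pi_region_mask=pi_mask)
    truth = GroundTruth(
        behaviors=(),
        gamma=np.empty((n, 0)),
        tau=np.empty(n),
        phi=np.empty(n),
        alpha=np.empty((n, 3)),
        cluster_members=members_list,
        cluster_loadings=[],
        latents=None,
        anticorrelated_mask=anticorr,
    )
    return coords, truth


def generate_activity(
    behavior: BehaviorSim,
    cells: tuple[CellCoordinates, GroundTruth],
    config: NeuralSimConfig,
) -> ActivitySim:
    """Simulate dF/F from the forward encoding model plus cluster latents and
    noise, and synthesize the raw two-channel traces.

    dF/F_i(t) = sum_j alpha_ij t^j + sum_b gamma_bi (b_t (*) kappa) +
    sum_c m_ic z_c(t) + eps. Raw channels: red = baseline x exponential
    bleach (plus artifact variance for motion cells), green = red x (1 + dF/F),
    so the fluorescence stage can invert them.
    """
    coords, truth = cells
    n = config.n_cells
    if truth.tau.shape[0] != n:
        raise ValueError("cells and config disagree on n_cells")
    T = behavior.state_probs.n_frames
    dt = 1.0 / behavior.config.sampling_rate
    if behavior.config.n_frames != T:
        raise ValueError("behavior config and probabilities disagree on the time base")
    rng = _rng(config.seed, 3)

    behaviors = tuple(s for s in behavior.config.states if s != "quiescent")
    n_b = len(behaviors)

    n_fast = int(round(config.frac_fast_tau * n))
    tau = np.empty(n)
    fast_mask = np.zeros(n, dtype=bool)
    fast_idx = rng.permutation(n)[:n_fast]
    fast_mask[fast_idx] = True
    tau[fast_mask] = rng.uniform(*config.tau_fast_range, size=n_fast)
    tau[~fast_mask] = rng.uniform(*config.tau_slow_range, size=n - n_fast)
    # shifts are positive and scale with tau, capped inside the default search grid
    phi = np.minimum(tau * rng.uniform(0.5, 1.2, size=n), 25.0)

    gamma = np.zeros((n, n_b))
    run_col = behaviors.index("run")
    gamma[:, run_col] = rng.uniform(*config.gamma_run_range, size=n)
    gamma[truth.anticorrelated_mask, run_col] *= -1.0
    for j, b in enumerate(behaviors):
        if j != run_col:
            gamma[:, j] = rng.uniform(0.0, config.gamma_other_max, size=n)

    alpha = np.column_stack(
        [rng.uniform(-0.05, 0.05, n), rng.uniform(-0.02, 0.02, n), rng.uniform(-0.02, 0.02, n)]
    )

    tt = np.linspace(0.0, 1.0, T)
    drift = alpha @ np.vstack([np.ones(T), tt, tt**2])

    prediction = drift.copy()
    for i in range(n):
        for j, b in enumerate(behaviors):
            if gamma[i, j] != 0.0:
                prediction[i] += gamma[i, j] * convolve_state(
                    behavior.state_probs.row(b), tau[i], phi[i], dt, truncate=True
                )

    loadings = []
    latents = np.zeros((len(truth.cluster_members), T))
    cluster_part = np.zeros((n, T))
    member_mask = np.zeros(n, dtype=bool)
    for c, members in enumerate(truth.cluster_members):
        latents[c] = _ou_series(T, dt, config.cluster_latent_timescale, 1.0, rng)
        m = config.cluster_loading * rng.uniform(0.8, 1.2, size=members.size)
        loadings.append(m)
        cluster_part[members] += m[:, None] * latents[c][None, :]
        member_mask[members] = True

    # idiosyncratic smooth residual dynamics: every cell has some; cluster
    # members' dynamics are dominated by the shared latent instead
    if config.cell_dynamics_sd > 0:
        own = _ou_series(T, dt, config.cell_dynamics_timescale, 1.0, rng, n_series=n)
        amp = np.full(n, config.cell_dynamics_sd)
        amp[member_mask] *= config.member_dynamics_factor
        cluster_part += amp[:, None] * own

    noise = rng.normal(0.0, config.noise_sd, size=(n, T)) if config.noise_sd > 0 else 0.0
    dff = prediction + cluster_part + noise

    # raw channels
    frames = np.arange(T)
    bleach = (1.0 - config.bleach_amplitude) + config.bleach_amplitude * np.exp(
        -frames * dt / config.bleach_timescale
    )
    r0 = rng.uniform(80.0, 120.0, size=n)
    red = r0[:, None] * bleach[None, :]
    motion_mask = np.zeros(n, dtype=bool)
    if config.n_motion_cells > 0:
        motion_idx = rng.permutation(n)[: config.n_motion_cells]
        motion_mask[motion_idx] = True
        for i in motion_idx:
            artifact = _ou_series(T, dt, 1.0, 1.2, rng)
            red[i] = red[i] * np.exp(artifact - artifact.mean())
    # ratio convention: the baseline is the trace minimum (calcium signals
    # are positive-going), so the target ratio is 1 + (dff - min dff)
    green = red * (1.0 + dff - dff.min(axis=1, keepdims=True))
    traces = DualChannelTraces(green=green, red=red, sampling_rate=behavior.config.sampling_rate)

    full_truth = GroundTruth(
        behaviors=behaviors,
        gamma=gamma,
        tau=tau,
        phi=phi,
        alpha=alpha,
        cluster_members=truth.cluster_members,
        cluster_loadings=loadings,
        latents=latents,
        anticorrelated_mask=truth.anticorrelated_mask,
        motion_cell_mask=motion_mask,
    )
    return ActivitySim(dff=dff, traces=traces, truth=full_truth, behavior_prediction=prediction)


def generate_dataset(
    behavior_config: BehaviorSimConfig | None = None,
    neural_config: NeuralSimConfig | None = None,
):
    """Convenience wrapper: behavior + cells + activity with matched configs."""
    behavior_config = behavior_config or BehaviorSimConfig()
    neural_config = neural_config or NeuralSimConfig()
    behavior = generate_behavior(behavior_config)
    cells = generate_cells(neural_config)
    activity = generate_activity(behavior, cells, neural_config)
    return behavior, cells[0], activity
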