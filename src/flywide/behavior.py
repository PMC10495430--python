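"""Behavioral signal processing: motion energy, heuristic labels, ethograms,
and the two-exponential autocorrelation fit.

The fly's behavior is summarized at three levels: continuous motion-energy
(ME) signals from the treadmill ball and from tracked body points, discrete
heuristic labels derived from thresholded ME signals, and soft per-state
probabilities whose argmax (with an "undefined" fallback) gives the ethogram.
Running shows autocorrelation on two timescales -- the duration of individual
bouts (seconds) and a slow drift in the tendency to run (tens of seconds) --
captured here by a sum-of-two-exponentials fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from skimage.restoration import denoise_tv_chambolle

__all__ = [
    "MARKER_NAMES",
    "FORELIMB_MARKERS",
    "HINDLIMB_MARKERS",
    "ABDOMEN_MARKERS",
    "MarkerTimeSeries",
    "MotionEnergy",
    "StateProbabilities",
    "Ethogram",
    "AutocorrFit",
    "marker_motion_energy",
    "ball_motion_energy",
    "heuristic_labels",
    "ethogram_from_probs",
    "state_autocorrelation",
    "fit_two_exponential",
]

#: The 8 tracked body points, ordered from anterior to posterior:
#: front bottom/top, middle bottom/top, hind bottom/top, abdomen bottom/top.
MARKER_NAMES = ("fb", "ft", "mb", "mt", "hb", "ht", "ab", "at")

FORELIMB_MARKERS = ("fb", "ft")
HINDLIMB_MARKERS = ("hb", "ht")
ABDOMEN_MARKERS = ("ab", "at")

UNDEFINED = "undefined"
NONE_LABEL = "none"

#: Heuristic-label thresholds on normalized motion-energy signals.
RUN_THRESHOLD = 0.5
QUIESCENT_THRESHOLD = 0.02
ABDOMEN_THRESHOLD = 0.9
GROOM_ON_THRESHOLD = 0.05
GROOM_OFF_THRESHOLD = 0.02

#: Ethogram confidence rule: frames whose maximum state probability falls
#: below this value are labeled "undefined".
ETHOGRAM_CONFIDENCE = 0.75


@dataclass
class MarkerTimeSeries:
    """Per-frame (x, y) pixel coordinates of the 8 tracked body points.

    ``xy`` has shape (n_frames, 8, 2), ordered as :data:`MARKER_NAMES`.
    """

    xy: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[1] != len(MARKER_NAMES) or self.xy.shape[2] != 2:
            raise ValueError(f"marker array must be (T, 8, 2), got {self.xy.shape}")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("marker coordinates contain non-finite values (interpolate gaps first)")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def group(self, names) -> np.ndarray:
        idx = [MARKER_NAMES.index(n) for n in names]
        return self.xy[:, idx, :]


@dataclass
class MotionEnergy:
    """A nonnegative per-frame movement-intensity signal.

    ``raw`` is the un-normalized energy; ``normalized`` maps either the 99th
    percentile (marker ME) or the maximum (ball ME) to 1.
    """

    raw: np.ndarray
    normalized: np.ndarray
    sampling_rate: float
    denoised: np.ndarray | None = None


@dataclass
class StateProbabilities:
    """Soft per-state probabilities, shape (n_states, n_frames); columns sum to 1."""

    probs: np.ndarray
    states: tuple
    sampling_rate: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.states = tuple(self.states)
        if self.probs.shape[0] != len(self.states):
            raise ValueError("probability matrix rows must match state names")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.probs.shape[1]

    def row(self, state: str) -> np.ndarray:
        return self.probs[self.states.index(state)]


@dataclass
class Ethogram:
    """Per-frame discrete behavioral label (one of the states or "undefined")."""

    labels: np.ndarray
    states: tuple
    sampling_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.states = tuple(self.states)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def indicator(self, state: str) -> np.ndarray:
        return (self.labels == state).astype(float)

    def occupancy(self) -> dict:
        return {s: float(np.mean(self.labels == s)) for s in self.states}

    def bouts(self):
        """Maximal runs of identical labels, as (label, start, stop) with stop exclusive."""
        out = []
        labels = self.labels
        start = 0
        for t in range(1, len(labels) + 1):
            if t == len(labels) or labels[t] != labels[start]:
                out.append((labels[start], start, t))
                start = t
        return out


@dataclass
class AutocorrFit:
    """Sum-of-two-exponentials fit A1*exp(-t/tau1) + A2*exp(-t/tau2), tau1 < tau2."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    lags: np.ndarray = field(repr=False)
    residual: float = 0.0

    def predict(self, lags: np.ndarray) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        return self.a1 * np.exp(-lags / self.tau1) + self.a2 * np.exp(-lags / self.tau2)


def _frame_energy(xy: np.ndarray) -> np.ndarray:
    """Mean squared frame-to-frame displacement over markers; first frame 0."""
    d = np.diff(xy, axis=0)
    e = np.mean(np.sum(d**2, axis=-1), axis=-1)
    return np.concatenate([[0.0], e])


def marker_motion_energy(
    markers_or_xy,
    sampling_rate: float | None = None,
    tv_weight: float = 0.05,
) -> MotionEnergy:
    """Motion energy of a marker group: squared displacement averaged over
    markers, denoised with a total-variation smoother, with the 99th
    percentile mapped to 1.

    Parameters
    ----------
    markers_or_xy
        A :class:`MarkerTimeSeries` or an (n_frames, n_markers, 2) array.
    tv_weight
        Weight of the Chambolle total-variation denoiser.
    """
    if isinstance(markers_or_xy, MarkerTimeSeries):
        xy = markers_or_xy.xy
        sampling_rate = markers_or_xy.sampling_rate
    else:
        xy = np.asarray(markers_or_xy, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required when passing a raw array")
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute motion energy")
    raw = _frame_energy(xy)
    denoised = np.maximum(denoise_tv_chambolle(raw, weight=tv_weight * max(raw.max(), 1e-30)), 0.0)
    p99 = np.percentile(denoised, 99)
    normalized = denoised / p99 if p99 > 0 else np.zeros_like(denoised)
    return MotionEnergy(
        raw=raw, normalized=normalized, sampling_rate=sampling_rate, denoised=denoised
    )


def ball_motion_energy(signal: np.ndarray, sampling_rate: float) -> MotionEnergy:
    """Treadmill (ball) motion energy, min-max normalized to [0, 1]."""
    raw = np.asarray(signal, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("ball signal must be a 1-D series of >= 2 frames")
    lo, hi = raw.min(), raw.max()
    normalized = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return MotionEnergy(raw=raw, normalized=normalized, sampling_rate=sampling_rate)


def heuristic_labels(
    ball_me: MotionEnergy,
    all_marker_me: MotionEnergy,
    forelimb_me: MotionEnergy,
    hindlimb_me: MotionEnergy,
    abdomen_me: MotionEnergy,
) -> np.ndarray:
    """Threshold-based behavioral labels, assigned in priority order.

    Rules (on normalized ME): run if ball ME > 0.5; else quiescent if the
    all-marker ME < 0.02; else abdomen bend if abdomen ME > 0.9; else front
    (back) groom if forelimb (hindlimb) ME > 0.05 while the opposing limb
    ME < 0.02. Frames matching no rule get "none".
    """
    signals = {
        "ball": ball_me,
        "all": all_marker_me,
        "fore": forelimb_me,
        "hind": hindlimb_me,
        "abdomen": abdomen_me,
    }
    n = None
    for name, me in signals.items():
        if me is None:
            raise ValueError(f"missing required motion-energy signal: {name}")
        if n is None:
            n = me.normalized.shape[0]
        elif me.normalized.shape[0] != n:
            raise ValueError("motion-energy signals must share a time base")

    labels = np.full(n, NONE_LABEL, dtype=object)
    run = ball_me.normalized > RUN_THRESHOLD
    quiet = (all_marker_me.normalized < QUIESCENT_THRESHOLD) & ~run
    bend = (abdomen_me.normalized > ABDOMEN_THRESHOLD) & ~run & ~quiet
    front = (
        (forelimb_me.normalized > GROOM_ON_THRESHOLD)
        & (hindlimb_me.normalized < GROOM_OFF_THRESHOLD)
        & ~run & ~quiet & ~bend
    )
    back = (
        (hindlimb_me.normalized > GROOM_ON_THRESHOLD)
        & (forelimb_me.normalized < GROOM_OFF_THRESHOLD)
        & ~run & ~quiet & ~bend & ~front
    )
    labels[run] = "run"
    labels[quiet] = "quiescent"
    labels[bend] = "abdomen_bend"
    labels[front] = "front_groom"
    labels[back] = "back_groom"
    return labels


def ethogram_from_probs(probs: StateProbabilities, confidence: float = ETHOGRAM_CONFIDENCE) -> Ethogram:
    """Discrete ethogram: per-frame argmax of state probabilities, with frames
    whose maximum probability is below ``confidence`` labeled "undefined"."""
    p = probs.probs
    colsums = p.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-6):
        raise ValueError("state probability columns must sum to 1 (renormalize first)")
    winners = np.argmax(p, axis=0)
    maxp = p[winners, np.arange(p.shape[1])]
    labels = np.array([probs.states[w] for w in winners], dtype=object)
    labels[maxp < confidence] = UNDEFINED
    return Ethogram(labels=labels, states=probs.states, sampling_rate=probs.sampling_rate)


def state_autocorrelation(
    ethogram: Ethogram, state: str, max_lag_s: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation of the binary indicator of one behavioral state.

    Returns ``(lags_s, acf)`` with the autocovariance normalized to 1 at lag 0.
    """
    ind = ethogram.indicator(state)
    if ind.sum() == 0:
        raise ValueError(f"state {state!r} never occurs in the ethogram")
    x = ind - ind.mean()
    n = x.size
    max_lag = int(round(max_lag_s * ethogram.sampling_rate))
    max_lag = min(max_lag, n - 1)
    # biased autocovariance estimator (divides by n at every lag)
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag] / n
    acf = full / full[0]
    lags = np.arange(max_lag + 1) / ethogram.sampling_rate
    return lags, acf


def _two_exp_design(lags: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    return np.column_stack([np.exp(-lags / tau1), np.exp(-lags / tau2)])


def fit_two_exponential(
    acf: np.ndarray,
    lags: np.ndarray,
    tau_bounds: tuple[float, float] = (0.05, 300.0),
    n_grid: int = 15,
    bias_n_frames: int | None = None,
    sampling_rate: float | None = None,
) -> AutocorrFit:
    """Least-squares fit of ``A1*exp(-t/tau1) + A2*exp(-t/tau2)`` to an
    autocorrelation, via a multi-start profiled search.

    Amplitudes are solved linearly at each log-spaced (tau1, tau2) grid pair;
    the best pair seeds a bounded nonlinear polish of all four parameters.
    Time constants are returned sorted ascending.

    When ``bias_n_frames`` (the length in frames of the series the sample
    autocorrelation came from) and ``sampling_rate`` are given, the standard
    first-order small-sample bias of the sample ACF -- an approximately
    constant offset of ``-(1 + 2 fs (A1 tau1 + A2 tau2)) / n`` caused by
    estimating the series mean -- is included self-consistently in the model,
    which removes the systematic shortening of the slow time constant.
    """
    acf = np.asarray(acf, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if acf.shape != lags.shape:
        raise ValueError("acf and lags must have equal shapes")
    if acf.size < 20:
        raise ValueError("need at least 20 lag points for a two-exponential fit")
    if np.ptp(acf) == 0:
        raise ValueError("degenerate autocorrelation (all values equal)")
    if bias_n_frames is not None and sampling_rate is None:
        raise ValueError("sampling_rate is required with bias_n_frames")
    n_obs = bias_n_frames
    fs = sampling_rate

    taus = np.geomspace(tau_bounds[0], tau_bounds[1], n_grid)
    target = acf + (1.0 / n_obs if n_obs else 0.0)
    # the standard ACF estimator attenuates lag k by (1 - k/n)
    atten = 1.0 - lags * fs / n_obs if n_obs else np.ones_like(lags)
    best = None
    for i in range(n_grid):
        for j in range(i + 1, n_grid):
            X = _two_exp_design(lags, taus[i], taus[j]) * atten[:, None]
            if n_obs:
                X = X - np.array([2 * fs * taus[i] / n_obs, 2 * fs * taus[j] / n_obs])
            coef, _, _, _ = np.linalg.lstsq(X, target, rcond=None)
            r = target - X @ coef
            ssr = float(r @ r)
            if best is None or ssr < best[0]:
                best = (ssr, taus[i], taus[j], coef)
    _, t1, t2, (c1, c2) = best

    def resid(p):
        a1, lt1, a2, lt2 = p
        tt1, tt2 = np.exp(lt1), np.exp(lt2)
        model = (a1 * np.exp(-lags / tt1) + a2 * np.exp(-lags / tt2)) * atten
        if n_obs:
            model = model - (1.0 + 2 * fs * (a1 * tt1 + a2 * tt2)) / n_obs
        return model - acf

    sol = least_squares(
        resid,
        x0=[c1, np.log(t1), c2, np.log(t2)],
        bounds=(
            [-np.inf, np.log(tau_bounds[0]), -np.inf, np.log(tau_bounds[0])],
            [np.inf, np.log(tau_bounds[1]), np.inf, np.log(tau_bounds[1])],
        ),
        method="trf",
    )
    a1, lt1, a2, lt2 = sol.x
    tau1, tau2 = np.exp(lt1), np.exp(lt2)
    if tau1 > tau2:
        (a1, tau1), (a2, tau2) = (a2, tau2), (a1, tau1)
    return AutocorrFit(
        a1=float(a1), tau1=float(tau1), a2=float(a2), tau2=float(tau2),
        lags=lags, residual=float(np.sum(resid(sol.x) ** 2)),
    )
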