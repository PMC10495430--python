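"""Structure in the activity not explained by behavior.

The residual r_it = f_it - fit_it of the encoding model is analyzed for
temporal structure (Ljung-Box autocorrelation scan), dimensionality
(cross-validated probabilistic-PCA likelihood), sparseness of principal
modes (participation ratio), behavioral-state subspace overlap, pairwise
correlations by state, and transition-triggered averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox

from .behavior import Ethogram, StateProbabilities

__all__ = [
    "PCAModes",
    "SparsenessResult",
    "DimensionalityResult",
    "SubspaceOverlapResult",
    "compute_residuals",
    "split_time_blocks",
    "ljung_box_scan",
    "pca_modes",
    "cv_dimensionality",
    "participation",
    "binarize_mode",
    "state_subspaces",
    "pairwise_state_correlations",
    "transition_triggered_average",
]


@dataclass
class PCAModes:
    """Orthonormal cell-weight vectors (rows of ``modes``) with eigenvalues
    (variance units, non-increasing) and per-mode score time series."""

    modes: np.ndarray      # n_modes x n_cells
    eigenvalues: np.ndarray
    scores: np.ndarray = field(repr=False)  # n_modes x n_frames
    mean: np.ndarray = field(repr=False)


@dataclass
class SparsenessResult:
    """Participation ratio PR_j = (sum v^2)^2 / sum v^4 per mode; the
    sparseness fraction is PR/N and the participating-neuron count is PR."""

    pr: np.ndarray
    fraction: np.ndarray
    n_cells: int


@dataclass
class DimensionalityResult:
    """Held-out log-likelihood curve over candidate mode counts m and its argmax."""

    m: int
    loglik: np.ndarray
    m_values: np.ndarray
    train_fraction: float
    rank_limited: bool = False


@dataclass
class SubspaceOverlapResult:
    """Cross-state variance-explained curves E_mb and common dimensionality."""

    states: tuple
    e_curves: dict      # (fit_state, eval_state) -> array over m
    dimensionality: dict  # state -> DimensionalityResult (within-state)
    common_dimensionality: dict  # (fit_state, eval_state) -> DimensionalityResult


def compute_residuals(dff: np.ndarray, fits, probs: StateProbabilities) -> np.ndarray:
    """Residual matrix r_it = f_it - prediction_it for the fitted population."""
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    resid = np.empty_like(dff)
    for i, fit in enumerate(fits):
        resid[i] = dff[i] - fit.predict(probs)
    return resid


def split_time_blocks(
    n_frames: int, n_blocks: int = 5, test_block: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous-block train/test split of the time axis.

    The session is cut into ``n_blocks`` contiguous blocks; one (the middle
    block by default) is held out, respecting temporal autocorrelation.
    Returns (train_idx, test_idx).
    """
    edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    if test_block is None:
        test_block = n_blocks // 2
    test = np.arange(edges[test_block], edges[test_block + 1])
    train = np.setdiff1d(np.arange(n_frames), test)
    return train, test


def ljung_box_scan(
    residuals: np.ndarray, lag_min: int = 10, lag_max: int = 610
) -> np.ndarray:
    """Ljung-Box autocorrelation test per cell, at every lag in
    [lag_min, lag_max] frames. Returns p-values, shape (n_cells, n_lags)."""
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    T = residuals.shape[1]
    if T <= lag_max:
        warnings.warn(
            f"series length {T} <= lag_max {lag_max}; truncating lag range", stacklevel=2
        )
        lag_max = T - 1
    lags = np.arange(lag_min, lag_max + 1)
    out = np.empty((residuals.shape[0], lags.size))
    for i in range(residuals.shape[0]):
        lb = acorr_ljungbox(residuals[i], lags=lags, return_df=False)
        out[i] = lb["lb_pvalue"].to_numpy()
    return out


def pca_modes(data: np.ndarray, mean: np.ndarray | None = None) -> PCAModes:
    """PCA of a cells x frames matrix; modes are unit cell-weight vectors.

    Time points are samples and cells are features. Eigenvalues use the
    1/n_frames normalization, so they sum to the total variance.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    mu = data.mean(axis=1) if mean is None else mean
    X = (data - mu[:, None]).T  # frames x cells
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / X.shape[0]
    scores = (u * s).T
    return PCAModes(modes=vt, eigenvalues=eig, scores=scores, mean=mu)


def _heldout_loglik(
    test_centered: np.ndarray, modes: np.ndarray, eig: np.ndarray, m_values: np.ndarray
) -> np.ndarray:
    """Average held-out Gaussian log-likelihood under the rank-m + isotropic
    covariance (top-m train eigenvalues; noise = mean discarded eigenvalue)."""
    n_test, n_cells = test_centered.shape
    rank = eig.size
    z = test_centered @ modes.T  # projections onto all train modes
    z2 = z**2
    total2 = np.sum(test_centered**2, axis=1)
    logliks = np.empty(m_values.size)
    cum_z2 = np.concatenate([[np.zeros(n_test).sum()], np.cumsum(z2.sum(axis=0))])
    for idx, m in enumerate(m_values):
        sigma2 = eig[m:].mean() if m < rank else max(eig[-1], 1e-12)
        sigma2 = max(sigma2, 1e-12)
        lam = np.maximum(eig[:m], sigma2)
        quad = np.sum(z2[:, :m] / lam[None, :]) if m else 0.0
        resid2 = total2.sum() - cum_z2[m]
        quad += resid2 / sigma2
        logdet = np.sum(np.log(lam)) + (n_cells - m) * np.log(sigma2)
        ll = -0.5 * (quad + n_test * (logdet + n_cells * np.log(2 * np.pi)))
        logliks[idx] = ll / n_test
    return logliks


def cv_dimensionality(
    residuals: np.ndarray,
    train_frac: float = 0.8,
    n_blocks: int = 5,
    max_modes: int | None = None,
) -> DimensionalityResult:
    """Dimensionality as the mode count maximizing held-out log-likelihood.

    PCA is fit on the contiguous-block training split (``train_frac`` of
    frames); for each candidate m the held-out frames are scored under a
    low-rank-plus-isotropic-noise Gaussian whose noise variance is the mean
    of the discarded training eigenvalues.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    n_cells, T = residuals.shape
    if T < 50:
        raise ValueError("need at least 50 time points for cross-validated dimensionality")
    n_blocks = max(2, int(round(1.0 / max(1.0 - train_frac, 1e-9)))) if n_blocks is None else n_blocks
    train, test = split_time_blocks(T, n_blocks=n_blocks)
    p = pca_modes(residuals[:, train])
    rank = int(np.sum(p.eigenvalues > 1e-12 * p.eigenvalues[0]))
    limit = rank if max_modes is None else min(max_modes, rank)
    m_values = np.arange(0, limit + 1)
    # at m = rank there are no discarded eigenvalues; cap at rank anyway and flag
    test_centered = (residuals[:, test] - p.mean[:, None]).T
    loglik = _heldout_loglik(test_centered, p.modes[:rank], p.eigenvalues[:rank], m_values)
    m_best = int(m_values[np.argmax(loglik)])
    rank_limited = m_best >= limit and max_modes is not None and rank > limit
    if m_best == limit and limit == rank:
        warnings.warn("log-likelihood still rising at full rank; returning rank", stacklevel=2)
        rank_limited = True
    return DimensionalityResult(
        m=m_best, loglik=loglik, m_values=m_values,
        train_fraction=float(train.size) / T, rank_limited=rank_limited,
    )


def participation(modes: np.ndarray | PCAModes) -> SparsenessResult:
    """Participation ratio per mode: (sum_k v_k^2)^2 / sum_k v_k^4.

    For a unit vector this is an effective count of large entries: 1 for a
    one-hot mode, N for a uniform mode, ~N/3 for an i.i.d. Gaussian vector.
    ``fraction`` divides by N.
    """
    V = modes.modes if isinstance(modes, PCAModes) else np.atleast_2d(np.asarray(modes, float))
    norms2 = np.sum(V**2, axis=1)
    if np.any(norms2 == 0):
        raise ValueError("zero mode vector")
    pr = norms2**2 / np.sum(V**4, axis=1)
    return SparsenessResult(pr=pr, fraction=pr / V.shape[1], n_cells=V.shape[1])


def binarize_mode(mode: np.ndarray, sd_thresh: float = 5.0) -> np.ndarray:
    """Indices of cells whose mode weight deviates from the mean by more than
    ``sd_thresh`` standard deviations (SD over cells). Sign-flip invariant in
    the sense that the selected set is unchanged under v -> -v."""
    mode = np.asarray(mode, dtype=float)
    if mode.size < 3:
        raise ValueError("mode must have at least 3 cells")
    dev = np.abs(mode - mode.mean())
    sd = mode.std()
    if sd == 0:
        return np.array([], dtype=int)
    return np.where(dev > sd_thresh * sd)[0]


def _state_frames(ethogram: Ethogram, state: str) -> np.ndarray:
    return np.where(ethogram.labels == state)[0]


def state_subspaces(
    residuals: np.ndarray,
    ethogram: Ethogram,
    states: tuple = ("quiescent", "run"),
    max_modes: int | None = None,
    min_frames: int = 100,
) -> SubspaceOverlapResult:
    """Per-state residual PCA, cross-state variance-explained curves, and
    common dimensionality.

    E_mb sums, over the top m modes fit in state b, the variance of the
    other state's residuals projected on each mode, divided by the summed
    eigenvalues; E with the fitted state itself is 1 for every m. Common
    dimensionality applies :func:`cv_dimensionality` to the cross-projected
    score matrix.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    frames = {}
    for s in states:
        idx = _state_frames(ethogram, s)
        if idx.size == 0:
            raise ValueError(f"state {s!r} absent from the ethogram")
        if idx.size < min_frames:
            raise ValueError(f"state {s!r} has only {idx.size} frames (< {min_frames})")
        frames[s] = idx

    pcas = {s: pca_modes(residuals[:, frames[s]]) for s in states}
    e_curves: dict = {}
    common: dict = {}
    dims = {}
    for b in states:
        dims[b] = cv_dimensionality(residuals[:, frames[b]], max_modes=max_modes)
        lam = pcas[b].eigenvalues
        rank = int(np.sum(lam > 1e-12 * lam[0]))
        m_max = rank if max_modes is None else min(max_modes, rank)
        for b0 in states:
            X0 = residuals[:, frames[b0]] - pcas[b].mean[:, None]
            proj = pcas[b].modes[:m_max] @ X0  # m x frames_b0
            var_proj = proj.var(axis=1)
            e = np.cumsum(var_proj) / np.cumsum(lam[:m_max])
            e_curves[(b, b0)] = e
            if b0 != b:
                common[(b, b0)] = cv_dimensionality(proj, max_modes=max_modes)
    return SubspaceOverlapResult(
        states=tuple(states), e_curves=e_curves, dimensionality=dims,
        common_dimensionality=common,
    )


def pairwise_state_correlations(
    residuals: np.ndarray,
    ethogram: Ethogram,
    states: tuple = ("quiescent", "run"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation matrices of residuals within each of two states
    and the distribution of per-pair differences (first minus second).

    Cells with zero variance within a state produce undefined (NaN)
    correlations; those pairs are excluded from the differences.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    mats = []
    for s in states:
        idx = _state_frames(ethogram, s)
        if idx.size < 2:
            raise ValueError(f"state {s!r} has fewer than 2 frames")
        X = residuals[:, idx]
        sd = X.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        C[sd == 0, :] = np.nan
        C[:, sd == 0] = np.nan
        mats.append(C)
    iu = np.triu_indices(residuals.shape[0], k=1)
    diffs = mats[0][iu] - mats[1][iu]
    diffs = diffs[np.isfinite(diffs)]
    return mats[0], mats[1], diffs


def transition_triggered_average(
    residuals: np.ndarray,
    ethogram: Ethogram,
    from_state: str,
    to_state: str,
    window_s: float = 5.0,
    min_transitions: int = 3,
) -> dict:
    """Population-average residual activity aligned to state transitions.

    Transitions require a full pre-window within the ``from_state`` bout and
    a full post-window of data; the baseline for each transition is the mean
    residual over the early part of the same bout (from the bout start up to
    the start of the pre-window), i.e. an epoch distant from the transition.
    Returns the across-transition mean trace +/- SEM of the cell-averaged
    residual, the number of transitions used and excluded.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    W = int(round(window_s * ethogram.sampling_rate))
    pop = residuals.mean(axis=0)
    used, excluded = [], 0
    for label, start, stop in ethogram.bouts():
        if label != from_state:
            continue
        t = stop  # first frame after the bout
        if t >= ethogram.n_frames or ethogram.labels[t] != to_state:
            continue
        if stop - start < W + 1 or t + W > ethogram.n_frames:
            excluded += 1
            continue
        baseline_frames = np.arange(start, stop - W)
        if baseline_frames.size == 0:
            excluded += 1
            continue
        snippet = pop[t - W : t + W] - pop[baseline_frames].mean()
        used.append(snippet)
    if len(used) < min_transitions:
        raise ValueError(
            f"only {len(used)} usable {from_state}->{to_state} transitions "
            f"(need >= {min_transitions}; {excluded} excluded for insufficient context)"
        )
    arr = np.array(used)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    times = (np.arange(-W, W)) / ethogram.sampling_rate
    return {
        "times": times, "mean": mean, "sem": sem,
        "n_transitions": arr.shape[0], "n_excluded": excluded,
    }
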