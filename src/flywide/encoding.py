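"""Per-cell encoding model of neural activity from behavior.

Each cell's activity f_i(t) is modeled as a quadratic drift plus a weighted
sum of behavioral state probabilities filtered through a cell-specific
symmetric exponential kernel:

    f_it ~ sum_j alpha_ij t^j  +  sum_b gamma_bi (b_t (*) kappa_{tau_i, phi_i})

with kappa_{tau,phi}(t) = (2 tau)^-1 exp(-|t - phi| / tau). The kernel is
symmetric about its shift phi, so no causal direction between behavior and
activity is presumed; phi > 0 means the cell's activity lags behavior.

Fitting profiles the nonlinear kernel parameters on a (tau, phi) grid --
the linear coefficients (alpha, gamma) are ordinary least squares at each
grid point -- with an optional Nelder-Mead polish of (tau, phi). This is a
deterministic replacement for a joint SLSQP fit of all parameters.

Significance is assessed with circular-shift nulls: all regressors are
rolled by a common random fraction (33-66%) of the session, the full model
(including tau, phi) is refit, and a cell is significant only if its true
r^2 exceeds all five null r^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from .behavior import Ethogram, MarkerTimeSeries, StateProbabilities

__all__ = [
    "BehaviorKernel",
    "CellRegressionFit",
    "behavior_kernel",
    "convolve_state",
    "PopulationEncoder",
    "fit_cell",
    "shift_significance",
    "markers_model_fit",
    "marker_principal_components",
    "max_crosscorr",
    "variance_rate_by_behavior",
    "DEFAULT_TAU_GRID",
    "DEFAULT_PHI_GRID",
]

DEFAULT_TAU_GRID = np.geomspace(0.3, 120.0, 12)
DEFAULT_PHI_GRID = np.linspace(-30.0, 30.0, 13)
KERNEL_SUPPORT_TAUS = 6.0
N_SHIFTS = 5


@dataclass
class BehaviorKernel:
    """Symmetric exponential kernel kappa_{tau,phi} sampled at dt resolution."""

    tau: float
    phi: float
    dt: float
    offsets: np.ndarray = field(repr=False)  # frame offsets k: y_t += w_k * b_{t-k}
    weights: np.ndarray = field(repr=False)  # sums to 1 (discrete mass)


def behavior_kernel(tau: float, phi: float, dt: float) -> BehaviorKernel:
    """Truncated (±6 tau around phi), renormalized discrete kernel."""
    if tau <= 0:
        raise ValueError("kernel time constant tau must be positive")
    # floor, so that a sub-frame kernel (tau << dt) collapses to a single tap
    half = max(int(np.floor(KERNEL_SUPPORT_TAUS * tau / dt)), 0)
    center = int(round(phi / dt))
    offsets = np.arange(center - half, center + half + 1)
    t = offsets * dt
    w = np.exp(-np.abs(t - phi) / tau) / (2.0 * tau)
    w = w / w.sum()  # unit discrete mass: sum(w) * dt * (1/dt) = 1
    return BehaviorKernel(tau=tau, phi=phi, dt=dt, offsets=offsets, weights=w)


def convolve_state(
    b: np.ndarray, tau: float, phi: float, dt: float, truncate: bool = False
) -> np.ndarray:
    """Convolve a behavior series with kappa_{tau,phi}, reflecting at the edges.

    y_t = sum_k w_k b_{t-k}; a positive phi centers kernel mass on the past
    of b, so the output lags the input. By default a kernel support (±6 tau
    around phi) longer than the series is an error; with ``truncate=True``
    the support is capped to fit the series and the kernel renormalized,
    which long-tau fits on short sessions require.
    """
    b = np.asarray(b, dtype=float)
    kern = behavior_kernel(tau, phi, dt)
    pad = int(np.max(np.abs(kern.offsets))) + 1
    if pad >= b.size and truncate:
        center = int(round(phi / dt))
        half = b.size - abs(center) - 2
        if half < 0:
            raise ValueError("kernel shift phi exceeds the series length")
        offsets = np.arange(center - half, center + half + 1)
        w = np.exp(-np.abs(offsets * dt - phi) / tau) / (2.0 * tau)
        kern = BehaviorKernel(tau=tau, phi=phi, dt=dt, offsets=offsets, weights=w / w.sum())
        pad = int(np.max(np.abs(kern.offsets))) + 1
    if pad >= b.size:
        raise ValueError(
            f"kernel support ({pad} frames) exceeds series length ({b.size} frames)"
        )
    bp = np.pad(b, pad, mode="reflect")
    # y_t = sum_j weights[j] * bp[t + pad - offsets[0] - j]  ->  y_t = full[t + pad - offsets[0]]
    full = fftconvolve(bp, kern.weights, mode="full")
    start = pad - int(kern.offsets[0])
    y = full[start : start + b.size]
    return y


@dataclass
class CellRegressionFit:
    """Fitted encoding model for one cell."""

    gamma: dict
    alpha: np.ndarray
    tau: float
    phi: float
    r2: float
    significant: bool | None = None
    shifted_r2: np.ndarray | None = None
    unidentifiable: tuple = ()

    def predict(self, probs: StateProbabilities, behaviors=None) -> np.ndarray:
        behaviors = tuple(self.gamma.keys()) if behaviors is None else behaviors
        T = probs.n_frames
        dt = 1.0 / probs.sampling_rate
        tt = np.linspace(0.0, 1.0, T)
        out = self.alpha[0] + self.alpha[1] * tt + self.alpha[2] * tt**2
        for b in behaviors:
            out = out + self.gamma[b] * convolve_state(probs.row(b), self.tau, self.phi, dt, truncate=True)
        return out


def _drift_columns(T: int) -> np.ndarray:
    tt = np.linspace(0.0, 1.0, T)
    return np.column_stack([np.ones(T), tt, tt**2])


class PopulationEncoder:
    """Fit the encoding model to many cells over a shared (tau, phi) grid.

    The convolved regressors at each grid point are shared by all cells, so
    they are precomputed once; per-cell work is then a single least-squares
    projection per grid point, vectorized across cells.

    Parameters
    ----------
    probs
        Soft behavioral state probabilities.
    behaviors
        Regressor set B. Default: every active (non-quiescent) state present;
        quiescence is the implicit baseline absorbed by the drift intercept.
    tau_grid, phi_grid
        Kernel parameter search grids (seconds).
    polish
        Refine (tau, phi) per cell from the best grid point by Nelder-Mead.
    """

    def __init__(
        self,
        probs: StateProbabilities,
        behaviors: tuple | None = None,
        tau_grid: np.ndarray | None = None,
        phi_grid: np.ndarray | None = None,
        polish: bool = False,
    ) -> None:
        self.probs = probs
        if behaviors is None:
            behaviors = tuple(
                s for s in probs.states
                if s != "quiescent" and probs.row(s).max() > 0
            )
        self.behaviors = tuple(behaviors)
        if len(self.behaviors) == 0:
            raise ValueError("need at least one active behavior to regress on")
        self.tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid, float)
        self.phi_grid = DEFAULT_PHI_GRID if phi_grid is None else np.asarray(phi_grid, float)
        self.polish = polish
        self.dt = 1.0 / probs.sampling_rate
        self._raw = np.vstack([probs.row(b) for b in self.behaviors])
        self.unidentifiable = tuple(
            b for b, row in zip(self.behaviors, self._raw) if np.ptp(row) == 0
        )

    # -- grid machinery ----------------------------------------------------

    def _grid_points(self):
        for tau in self.tau_grid:
            for phi in self.phi_grid:
                yield float(tau), float(phi)

    def _design(self, raw: np.ndarray, tau: float, phi: float) -> np.ndarray:
        T = raw.shape[1]
        cols = [_drift_columns(T)]
        cols.append(
            np.column_stack([convolve_state(row, tau, phi, self.dt, truncate=True) for row in raw])
        )
        return np.concatenate(cols, axis=1)

    def _fit_grid(self, F: np.ndarray, raw: np.ndarray):
        """Vectorized grid fit. F: cells x T. Returns per-cell best fit arrays."""
        n_cells, T = F.shape
        sst = np.sum((F - F.mean(axis=1, keepdims=True)) ** 2, axis=1)
        sst = np.where(sst > 0, sst, np.inf)
        best_ssr = np.full(n_cells, np.inf)
        best_coef = np.zeros((n_cells, 3 + len(self.behaviors)))
        best_tau = np.empty(n_cells)
        best_phi = np.empty(n_cells)
        for tau, phi in self._grid_points():
            X = self._design(raw, tau, phi)
            coef, _, _, _ = np.linalg.lstsq(X, F.T, rcond=None)
            resid = F.T - X @ coef
            ssr = np.sum(resid**2, axis=0)
            improved = ssr < best_ssr
            best_ssr[improved] = ssr[improved]
            best_coef[improved] = coef.T[improved]
            best_tau[improved] = tau
            best_phi[improved] = phi
        r2 = 1.0 - best_ssr / sst
        return best_coef, best_tau, best_phi, np.clip(r2, 0.0, 1.0), best_ssr, sst

    def _polish_cell(self, f: np.ndarray, raw: np.ndarray, tau0: float, phi0: float):
        T = f.size
        drift = _drift_columns(T)
        tau_lo, tau_hi = self.tau_grid.min(), self.tau_grid.max()
        phi_lo, phi_hi = self.phi_grid.min(), self.phi_grid.max()

        def objective(p):
            tau = float(np.clip(np.exp(p[0]), tau_lo, tau_hi))
            phi = float(np.clip(p[1], phi_lo, phi_hi))
            conv = np.column_stack(
                [convolve_state(row, tau, phi, self.dt, truncate=True) for row in raw]
            )
            X = np.concatenate([drift, conv], axis=1)
            coef, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
            r = f - X @ coef
            return float(r @ r)

        sol = minimize(
            objective, x0=[np.log(tau0), phi0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
        )
        tau = float(np.clip(np.exp(sol.x[0]), tau_lo, tau_hi))
        phi = float(np.clip(sol.x[1], phi_lo, phi_hi))
        X = self._design(raw, tau, phi)
        coef, _, _, _ = np.linalg.lstsq(X, f, rcond=None)
        r = f - X @ coef
        return coef, tau, phi, float(r @ r)

    # -- public API --------------------------------------------------------

    def fit(self, F: np.ndarray, raw: np.ndarray | None = None) -> list[CellRegressionFit]:
        """Fit every cell (rows of F) and return per-cell fits (no nulls)."""
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if not np.all(np.isfinite(F)):
            raise ValueError("activity contains non-finite values")
        raw = self._raw if raw is None else raw
        if raw.shape[1] != F.shape[1]:
            raise ValueError("activity and behavior must share a time base")
        coef, tau, phi, r2, ssr, sst = self._fit_grid(F, raw)
        fits = []
        for i in range(F.shape[0]):
            ci, ti, pi, ssri = coef[i], tau[i], phi[i], ssr[i]
            if self.polish:
                ci, ti, pi, ssri = self._polish_cell(F[i], raw, tau[i], phi[i])
            r2i = float(np.clip(1.0 - ssri / sst[i], 0.0, 1.0)) if np.isfinite(sst[i]) else 0.0
            gamma = dict(zip(self.behaviors, ci[3:]))
            fits.append(
                CellRegressionFit(
                    gamma=gamma, alpha=ci[:3].copy(), tau=float(ti), phi=float(pi),
                    r2=r2i, unidentifiable=self.unidentifiable,
                )
            )
        return fits

    def fit_with_significance(
        self, F: np.ndarray, n_shifts: int = N_SHIFTS, seed: int = 0
    ) -> list[CellRegressionFit]:
        """Fit every cell plus circular-shift nulls shared across the population.

        Each null rolls all regressors by a common uniform-random fraction of
        the session in [1/3, 2/3] (wrapping around) and refits the full model,
        including the kernel grid. A cell is significant iff its true r^2
        exceeds every null r^2.
        """
        F = np.atleast_2d(np.asarray(F, dtype=float))
        T = F.shape[1]
        if T < 3 * n_shifts:
            raise ValueError("session too short for distinct circular shifts")
        fits = self.fit(F)
        rng = np.random.default_rng(seed)
        null_r2 = np.empty((n_shifts, F.shape[0]))
        for s in range(n_shifts):
            frac = rng.uniform(1.0 / 3.0, 2.0 / 3.0)
            shift = int(round(frac * T))
            raw_shifted = np.roll(self._raw, shift, axis=1)
            _, _, _, r2s, _, _ = self._fit_grid(F, raw_shifted)
            null_r2[s] = r2s
        for i, fit in enumerate(fits):
            fit.shifted_r2 = null_r2[:, i].copy()
            fit.significant = bool(fit.r2 > null_r2[:, i].max())
        return fits

    def to_frame(self, fits: list[CellRegressionFit]) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(fits):
            row = {"cell": i, "tau": f.tau, "phi": f.phi, "r2": f.r2,
                   "significant": f.significant}
            row.update({f"gamma_{b}": g for b, g in f.gamma.items()})
            row.update({f"alpha_{j}": a for j, a in enumerate(f.alpha)})
            if f.shifted_r2 is not None:
                row.update({f"shifted_r2_{k}": v for k, v in enumerate(f.shifted_r2)})
            rows.append(row)
        return pd.DataFrame(rows)


def fit_cell(
    f: np.ndarray,
    probs: StateProbabilities,
    behaviors: tuple | None = None,
    tau_grid: np.ndarray | None = None,
    phi_grid: np.ndarray | None = None,
    polish: bool = True,
) -> CellRegressionFit:
    """Fit the encoding model to a single cell (grid + polish)."""
    enc = PopulationEncoder(
        probs, behaviors=behaviors, tau_grid=tau_grid, phi_grid=phi_grid, polish=polish
    )
    return enc.fit(np.atleast_2d(f))[0]


def shift_significance(
    f: np.ndarray,
    probs: StateProbabilities,
    behaviors: tuple | None = None,
    n_shifts: int = N_SHIFTS,
    seed: int = 0,
    tau_grid: np.ndarray | None = None,
    phi_grid: np.ndarray | None = None,
) -> tuple[bool, np.ndarray]:
    """Circular-shift significance for one cell; returns (significant, null r^2)."""
    enc = PopulationEncoder(probs, behaviors=behaviors, tau_grid=tau_grid, phi_grid=phi_grid)
    fit = enc.fit_with_significance(np.atleast_2d(f), n_shifts=n_shifts, seed=seed)[0]
    return bool(fit.significant), fit.shifted_r2


def marker_principal_components(markers: MarkerTimeSeries) -> np.ndarray:
    """Principal-component scores of the normalized, mean-subtracted marker
    x/y coordinates: up to 16 orthogonal series, shape (n_components, T).

    Zero-variance coordinates are dropped (with fewer components returned).
    """
    xy = markers.xy.reshape(markers.n_frames, -1)  # T x 16
    sd = xy.std(axis=0)
    keep = sd > 1e-10 * max(float(np.max(np.abs(xy))), 1.0)
    if not np.all(keep):
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance marker coordinates",
            stacklevel=2,
        )
    z = (xy[:, keep] - xy[:, keep].mean(axis=0)) / sd[keep]
    # PCA via SVD; scores are orthogonal time series
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = (u * s).T
    return scores


def markers_model_fit(
    f: np.ndarray,
    markers: MarkerTimeSeries,
    tau_grid: np.ndarray | None = None,
    phi_grid: np.ndarray | None = None,
    n_shifts: int = N_SHIFTS,
    seed: int = 0,
) -> tuple[CellRegressionFit, float]:
    """Alternative model using marker principal components as regressors.

    Identical kernel/grid machinery with the 16 marker PCs in place of state
    probabilities. Returns ``(fit, excess_variance)`` where excess variance
    is r^2 minus the mean circular-shift null r^2 -- the fraction of variance
    explained that exceeds expectation.
    """
    scores = marker_principal_components(markers)
    names = tuple(f"pc{k}" for k in range(scores.shape[0]))
    probs_like = StateProbabilities.__new__(StateProbabilities)
    # marker PCs are not probabilities; bypass the [0,1] check by building a
    # minimal stand-in with the same interface
    probs_like.probs = scores
    probs_like.states = names
    probs_like.sampling_rate = markers.sampling_rate
    enc = PopulationEncoder(
        probs_like, behaviors=names, tau_grid=tau_grid, phi_grid=phi_grid
    )
    fit = enc.fit_with_significance(np.atleast_2d(f), n_shifts=n_shifts, seed=seed)[0]
    excess = float(fit.r2 - fit.shifted_r2.mean())
    return fit, excess


def max_crosscorr(
    f: np.ndarray, running: np.ndarray, max_lag_s: float, sampling_rate: float
) -> tuple[float, float]:
    """Maximum normalized cross-correlation with running and its signed lag.

    Positive lag means neural activity lags behavior. Both series are
    z-scored; correlation at lag L pairs f_t with running_{t-L}.
    """
    f = np.asarray(f, dtype=float)
    running = np.asarray(running, dtype=float)
    if f.shape != running.shape:
        raise ValueError("series must have equal length")
    if f.std() == 0 or running.std() == 0:
        raise ValueError("zero-variance input")
    zf = (f - f.mean()) / f.std()
    zr = (running - running.mean()) / running.std()
    max_lag = int(round(max_lag_s * sampling_rate))
    best_cc, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = zf[lag:], zr[: zr.size - lag]
        else:
            a, b = zf[:lag], zr[-lag:]
        cc = float(np.mean(a * b))
        if cc > best_cc:
            best_cc, best_lag = cc, lag
    return best_cc, best_lag / sampling_rate


def variance_rate_by_behavior(
    fits: list[CellRegressionFit],
    probs: StateProbabilities,
    ethogram: Ethogram,
    reference: str = "run",
    tau_strata: tuple = (("tau<4s", 0.0, 4.0), ("tau>4s", 4.0, np.inf), ("tau>20s", 20.0, np.inf)),
) -> pd.DataFrame:
    """Variance explained per behavior per unit time in that behavior,
    normalized to the reference behavior (running).

    For each cell, the variance of each term gamma_b * yhat_b over the
    session is divided by the total time the fly spent in behavior b; each
    rate is then divided by the same quantity for the reference behavior.
    Rates are aggregated as mean ± SEM within kernel-time-constant strata.
    Behaviors absent from the ethogram are excluded.
    """
    dt = 1.0 / probs.sampling_rate
    occupancy = ethogram.occupancy()
    behaviors = [b for b in fits[0].gamma if occupancy.get(b, 0.0) > 0]
    if reference not in behaviors:
        raise ValueError(f"reference behavior {reference!r} absent from the session")
    time_in = {b: occupancy[b] * ethogram.n_frames * dt for b in behaviors}

    per_cell = np.full((len(fits), len(behaviors)), np.nan)
    taus = np.array([f.tau for f in fits])
    for i, fit in enumerate(fits):
        rates = {}
        for b in behaviors:
            term = fit.gamma[b] * convolve_state(probs.row(b), fit.tau, fit.phi, dt, truncate=True)
            rates[b] = np.var(term) / time_in[b]
        ref = rates[reference]
        if ref > 0:
            for j, b in enumerate(behaviors):
                per_cell[i, j] = rates[b] / ref

    rows = []
    for name, lo, hi in tau_strata:
        mask = (taus >= lo) & (taus < hi)
        for j, b in enumerate(behaviors):
            vals = per_cell[mask, j]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "stratum": name,
                    "behavior": b,
                    "n_cells": int(vals.size),
                    "rate_mean": float(np.mean(vals)) if vals.size else np.nan,
                    "rate_sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
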