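"""Two-channel fluorescence processing: ratiometric F, LAD exponential
baseline, delta-F-over-F, and the CV-squared motion filter.

The activity channel (nuclear GCaMP, "green") is divided by a static
structural channel (nuclear dsRed, "red") so that shared artifacts --
photobleaching and residual motion -- cancel in the ratio F = green/red.
A slow exponential baseline F0(t) = m + a*exp(-t/b) is then fit to each
cell's F by least-absolute-deviation (LAD) regression on the forward
difference dF_t = F_{t+1} - F_t, which is robust both to transients
(outliers in dF) and to slow nonstationarity. Activity is
dF/F = (F - F0)/F0. Cells whose red channel still fluctuates after
registration are flagged by a squared coefficient of variation computed
from the red channel and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DualChannelTraces",
    "BaselineFit",
    "ActivityMatrix",
    "ratiometric_f",
    "fit_baseline_lad",
    "delta_f_over_f",
    "cv2_filter",
    "process",
    "CV2_THRESHOLD",
]

#: Discard threshold for the red-channel CV². Kept cells sit far below 1 and
#: motion-corrupted cells far above it, so any mid-gap value is equivalent;
#: 1.0 is the scale-free midpoint.
CV2_THRESHOLD = 1.0


@dataclass
class DualChannelTraces:
    """Per-ROI green (activity) and red (structural) traces, cells x time."""

    green: np.ndarray
    red: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.green = np.atleast_2d(np.asarray(self.green, dtype=float))
        self.red = np.atleast_2d(np.asarray(self.red, dtype=float))
        if self.green.shape != self.red.shape:
            raise ValueError("green and red must have equal shapes")
        bad = np.where(np.any(self.red <= 0, axis=1))[0]
        if bad.size:
            raise ValueError(f"red channel must be strictly positive; offending cells: {bad.tolist()}")

    @property
    def n_cells(self) -> int:
        return self.green.shape[0]

    @property
    def n_frames(self) -> int:
        return self.green.shape[1]


@dataclass
class BaselineFit:
    """Exponential baseline F0(t) = m + a*exp(-t/b), t and b in frames.

    ``l1_objective`` is the residual LAD objective on dF so degraded fits are
    visible; ``converged`` is False when the optimizer failed and the flat
    fallback (a = 0, F0 = min F) was returned.
    """

    a: float
    b: float
    m: float
    f0: np.ndarray = field(repr=False)
    l1_objective: float = 0.0
    converged: bool = True


@dataclass
class ActivityMatrix:
    """dF/F per cell per frame, with red-channel QC."""

    dff: np.ndarray
    sampling_rate: float
    qc_cv2: np.ndarray
    kept_mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def ratiometric_f(traces: DualChannelTraces) -> np.ndarray:
    """Elementwise ratio F = green/red."""
    bad = np.where(np.any(traces.red <= 0, axis=1))[0]
    if bad.size:
        raise ValueError(f"red channel must be strictly positive; offending cells: {bad.tolist()}")
    return traces.green / traces.red


def _lad_amplitude(d: np.ndarray, h: np.ndarray) -> float:
    """argmin_a sum |d - a h| -- the weighted median of d/h with weights |h|."""
    w = np.abs(h)
    r = d / h
    order = np.argsort(r)
    cw = np.cumsum(w[order])
    k = np.searchsorted(cw, 0.5 * cw[-1])
    return float(r[order[min(k, r.size - 1)]])


def fit_baseline_lad(
    f: np.ndarray,
    b_grid: np.ndarray | None = None,
    polish: bool = True,
    min_rel_improvement: float = 0.01,
) -> BaselineFit:
    """LAD fit of an exponentially decaying baseline to one fluorescence trace.

    Minimizes ``sum_t |dF_t - dF0(t, a, b)|`` with
    ``dF0(t, a, b) = -(a/b) exp(-t/b)`` and ``dF_t = F_{t+1} - F_t``
    (forward difference; the last frame is dropped). The decay time ``b``
    is scanned on a log grid; the amplitude ``a >= 0`` has a closed-form
    weighted-median LAD solution at each ``b``. The best grid point is
    polished by Nelder-Mead. Growth is not modeled: if the best amplitude
    is ~0 the flat baseline ``F0 = min F`` is returned.

    Two guards keep the fit identifiable on traces with no real decay:
    the amplitude is capped at the trace's range (the baseline cannot start
    above the data), and the exponential is accepted only if it improves
    the L1 objective over the flat baseline by ``min_rel_improvement``
    (a very slow exponential is indistinguishable from a constant dF
    offset, which would otherwise absorb the median of dF).
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size < 100:
        raise ValueError("baseline fit requires a 1-D trace of at least 100 frames")
    if not np.all(np.isfinite(f)):
        raise ValueError("trace contains non-finite values")
    T = f.size
    d = np.diff(f)
    t = np.arange(T - 1, dtype=float)
    m = float(np.min(f))
    a_max = float(np.ptp(f))
    t_full = np.arange(T, dtype=float)

    if b_grid is None:
        b_grid = np.geomspace(5.0, 5.0 * T, 40)

    obj_flat = float(np.sum(np.abs(d)))
    best = None
    for b in b_grid:
        h = -(1.0 / b) * np.exp(-t / b)
        a = float(np.clip(_lad_amplitude(d, h), 0.0, a_max))
        obj = float(np.sum(np.abs(d - a * h)))
        if best is None or obj < best[0]:
            best = (obj, a, b)
    obj0, a0, b0 = best

    converged = True
    a, b, obj = a0, b0, obj0
    if polish and a0 > 0:
        def objective(p):
            la, lb = p
            aa, bb = min(np.exp(la), a_max), np.exp(lb)
            return np.sum(np.abs(d + (aa / bb) * np.exp(-t / bb)))

        try:
            sol = minimize(
                objective,
                x0=[np.log(max(a0, 1e-12)), np.log(b0)],
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
            )
            if np.isfinite(sol.fun) and sol.fun <= obj0 + 1e-15:
                a, b = min(float(np.exp(sol.x[0])), a_max), float(np.exp(sol.x[1]))
                obj = float(sol.fun)
            else:
                converged = False
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            converged = False

    accept = obj < (1.0 - min_rel_improvement) * obj_flat if obj_flat > 0 else False
    if not converged or a <= 1e-12 or not accept:
        a = 0.0
        f0 = np.full(T, m)
        obj_out = obj if converged and accept else obj_flat
        return BaselineFit(a=0.0, b=float(b), m=m, f0=f0, l1_objective=float(obj_out), converged=converged)

    f0 = m + a * np.exp(-t_full / b)
    return BaselineFit(a=float(a), b=float(b), m=m, f0=f0, l1_objective=float(obj), converged=True)


def delta_f_over_f(f: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """dF/F = (F - F0)/F0; requires F0 > 0 everywhere."""
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 must be strictly positive")
    return (f - f0) / f0


def _red_dff(red_trace: np.ndarray) -> np.ndarray:
    """dF/F of a red trace around its own LAD exponential baseline.

    The red channel keeps its own units, so the trace is normalized to unit
    temporal mean first; CV² is then scale-free.
    """
    r = red_trace / np.mean(red_trace)
    fit = fit_baseline_lad(r, polish=False)
    f0 = fit.f0
    if np.any(f0 <= 0):
        f0 = np.full_like(r, np.mean(r))
    return (r - f0) / f0


def cv2_filter(
    red: np.ndarray, threshold: float = CV2_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell squared coefficient of variation of the red channel.

    CV² = Var[dF/F_red] / Mean[F_red]², with the red trace normalized to unit
    mean (making the denominator 1 and the statistic scale-free). Stationary
    cells have CV² << 1; motion-corrupted cells have CV² >> 1 and are
    discarded. Returns ``(qc_cv2, kept_mask)``.
    """
    red = np.atleast_2d(np.asarray(red, dtype=float))
    qc = np.empty(red.shape[0])
    for i in range(red.shape[0]):
        if np.ptp(red[i]) == 0:
            qc[i] = 0.0
            continue
        dff_r = _red_dff(red[i])
        qc[i] = float(np.var(dff_r)) / float(np.mean(red[i] / np.mean(red[i])) ** 2)
    kept = qc < threshold
    return qc, kept


def process(traces: DualChannelTraces, cv2_threshold: float = CV2_THRESHOLD) -> ActivityMatrix:
    """Full fluorescence stage: ratio, per-cell LAD baseline, dF/F, red QC."""
    F = ratiometric_f(traces)
    dff = np.empty_like(F)
    for i in range(F.shape[0]):
        fit = fit_baseline_lad(F[i])
        f0 = fit.f0
        if np.any(f0 <= 0):
            # guard for traces whose minimum is <= 0; shift into positivity
            f0 = f0 - f0.min() + 1e-6
        dff[i] = delta_f_over_f(F[i], f0)
    qc, kept = cv2_filter(traces.red, threshold=cv2_threshold)
    return ActivityMatrix(dff=dff, sampling_rate=traces.sampling_rate, qc_cv2=qc, kept_mask=kept)
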