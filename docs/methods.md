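# Methods

This note documents the models, estimators and numerical choices behind
`flywide`, what the synthetic-data generator does and does not emulate, and
the known limitations. Units: times in seconds throughout (sampling rate
converts to frames); fluorescence in arbitrary camera units; activity in
ΔF/F (unitless); coordinates in micrometers.

## Fluorescence model

The measured signals are a calcium-dependent green channel and a static red
channel per ROI. Activity is the ratio F = green/red, which cancels
multiplicative artifacts (bleaching, residual motion) common to both
channels. The baseline is an exponential decay F0(t) = m + a·exp(−t/b)
with m = min F: the convention, standard for positive-going calcium
indicators, that the quietest moments define the baseline.

(a, b) are estimated by least absolute deviations on the forward
difference dF_t = F_{t+1} − F_t against dF0(t) = −(a/b)exp(−t/b). Working
on the derivative removes sensitivity to slow additive nonstationarity; L1
loss makes transients (outliers in dF) nearly irrelevant. The solver scans
b on a log grid (40 points, 5 frames to 5× the trace length); at each b
the 1-D L1 problem in a has the closed-form weighted-median solution; the
best grid point is polished by Nelder–Mead in (log a, log b). Two
identifiability guards matter in practice: a is capped at the trace's
range (a baseline cannot start above the data), and the exponential is
accepted only if it beats the flat baseline's L1 objective by ≥1%.
Without the second guard, a very slow exponential (b → ∞) degenerates into
a constant dF offset that absorbs the median of dF and produces absurd
baselines on traces with no real decay. Growth is not modeled: such fits
fall back to F0 ≡ min F, with the flat objective reported so degraded fits
remain visible.

Motion QC: CV² = Var[ΔF/F_red]/Mean[F̃_red]², computed on the red channel
with its own LAD baseline and with the red trace normalized to unit
temporal mean, making the statistic scale-free. Stationary cells sit
orders of magnitude below 1 and motion-corrupted cells orders of magnitude
above it, so the discard threshold (default 1.0) is uncritical anywhere in
the gap.

## Behavior

Marker motion energy is the mean squared frame-to-frame displacement over
a marker group, denoised with a Chambolle total-variation smoother
(default weight 0.05, scaled by the signal maximum) and normalized so the
99th percentile maps to 1; ball motion energy is min–max normalized.
Heuristic labels apply fixed thresholds in priority order: run (ball
ME > 0.5), quiescent (all-marker ME < 0.02), abdomen bend (abdomen
ME > 0.9), then front/back groom (limb ME > 0.05 with the opposing limb
< 0.02). Marker groups: forelimb {fb, ft}, hindlimb {hb, ht}, abdomen
{ab, at}. The ethogram is the per-frame argmax of the soft state
probabilities, with frames whose maximum is below 0.75 labeled undefined.

The running autocorrelation is the biased sample autocorrelation of the
binary run indicator, fit by A₁e^{−t/τ₁} + A₂e^{−t/τ₂} via a profiled
multi-start: amplitudes are linear at each log-spaced (τ₁, τ₂) pair, and
the best pair seeds a bounded trust-region polish. For quantitative
recovery the fit can include the two known small-sample artifacts of the
sample ACF self-consistently in the model: the constant negative offset
−(1 + 2f_s(A₁τ₁ + A₂τ₂))/n from estimating the series mean, and the
(1 − k/n) attenuation of lag k. Both are functions of the fitted
parameters, not free parameters — a free offset is nearly collinear with a
slow exponential over a 60 s window and destabilizes the fit. Without the
correction the slow time constant of a 20-minute session is systematically
shortened by ~15%.

## Encoding model

Each cell: f_it ~ Σ_j α_ij t^j (j ≤ 2, t rescaled to [0,1] for
conditioning) + Σ_b γ_bi (b_t ⊛ κ_{τ_i,φ_i}), with the symmetric
exponential kernel κ_{τ,φ}(t) = (2τ)^{-1}e^{−|t−φ|/τ} truncated at ±6τ
around φ and renormalized to unit discrete mass; regressor edges are
handled by reflection. The regressor set is every active (non-quiescent)
state present in the session; quiescence is the baseline absorbed by α₀.
On sessions shorter than the kernel support the support is capped to the
series length and renormalized (the alternative — refusing to fit slow
kernels on short sessions — is available as the strict mode of the
convolution).

Fitting profiles (τ, φ) on a grid (defaults: τ log-spaced 0.3–120 s × 12,
φ linear −30…30 s × 13) with the linear coefficients solved by OLS at each
point; an optional Nelder–Mead polish refines (τ, φ) from the best grid
point. This profiled approach is deterministic and convex in the
coefficients at every grid point, replacing a joint constrained
optimization of all parameters. The grid regressors are shared across the
population, so fitting many cells is a vectorized least-squares per grid
point.

Significance: five circular-shift nulls, each rolling all regressors by a
common uniform-random fraction of the session in [1/3, 2/3] (wrapping),
refitting the full model including the (τ, φ) grid; a cell is significant
iff its true r² exceeds all five. Under exchangeability a pure-noise cell
is significant with probability ~1/6, so the test is deliberately
permissive per cell and meant for population-level statements; the shifts
are shared across cells, as one set of shifted regressor tensors serves
the whole population. A caution from the synthetic experiments: on short
sessions with heavily smoothed (large-τ) regressors the behavior
regressors become nearly collinear, and OLS can fit slow non-behavioral
dynamics with large opposing coefficients; session lengths of ~20 minutes
with the default grids keep this pathology rare.

The markers variant replaces state probabilities with the ≤16 principal
components of the z-scored marker x/y coordinates (zero-variance
coordinates dropped) and reports excess variance r² − mean(null r²) for
comparing model families of different sizes.

Variance rate per behavior: Var(γ_b·ŷ_b) over the session divided by the
total time in behavior b, normalized to running, aggregated as mean ± SEM
within τ strata (<4 s, >4 s, >20 s). The attribution uses each term's
marginal variance; correlated regressors make the partition approximate.

## Residual structure

Residuals are r_it = f_it − fit_it. Ljung–Box scans use lags 10–610 frames
(~1–61 s at 10 Hz) per cell. PCA treats time points as samples and cells
as features; eigenvalues use the 1/T normalization so they sum to total
variance.

Cross-validated dimensionality: the session is cut into 5 contiguous
blocks and the middle block held out (contiguous blocks respect temporal
autocorrelation; random frames would leak). For each candidate m the
held-out frames are scored under a Gaussian whose covariance keeps the top
m training eigenpairs and replaces the rest by isotropic noise equal to
the mean discarded training eigenvalue; the reported dimensionality
maximizes this likelihood. Two caveats established on synthetic data: the
estimator resolves at most roughly T_train/(2·τ_latent·f_s) smooth latent
factors (effective sample count), and a strongly heteroskedastic residual
diagonal inflates the estimate because per-cell variance is itself
predictable structure under an isotropic-noise model.

Participation ratio PR = (Σv²)²/Σv⁴ per unit-norm mode; the sparseness
fraction is PR/N (≈1/3 for an i.i.d. Gaussian vector, 1/N for one-hot,
1 for uniform) and the participating-neuron count is PR itself. Mode
binarization selects cells more than 5 SD from the mode mean.

State subspaces: PCA per behavioral state; E_mb sums the variance of the
other state's residuals projected on the top m modes of state b, divided
by the corresponding eigenvalue sum (1 for self-projection). E is
normalized by the *fitting* state's spectrum, so it is only interpretable
when that state has genuine structure. Common dimensionality applies the
held-out likelihood to the cross-projected score matrix. Transition
averages align the cell-averaged residual to bout transitions, using the
early part of the source bout as the per-transition baseline and excluding
transitions without a full window of context.

## Clustering significance

Ward-linkage agglomeration (Euclidean affinity) on training frames, cells
as rows. Every child with ≥2 members is tested on the held-out frames:
intra-cluster variance (mean squared deviation from the cluster-mean time
course) versus N_samples = min(C(N_p, N_c), 100) size-matched subsets of
its parent; p = (1 + #{subset ≤ child})/(1 + N_samples), significant at
p < 0.05. When all C(N_p, N_c) ≤ 100 subsets can be enumerated they all
are (including the child itself); in the sampling regime the exact child
set is excluded since alternatives exist. With fewer than 20 subsets
p < 0.05 is unattainable and the node is reported untestable rather than
significant. Terminal ("leaf-of-significance") clusters are significant
nodes with no significant node anywhere below them; the literal
no-significant-direct-children reading lets large root-level unions count
as terminal, which distorts the size histogram.

Power analysis on synthetic data shows the test discriminates a cluster
only if its members' *idiosyncratic* (non-shared) variance is below the
typical per-cell variance in the parent — two cells tied by a latent but
embedded among cells of equal idiosyncratic power are invisible to a
variance comparison. Detection of two-cell clusters therefore requires
the shared latent to dominate the members' residual dynamics, which is
also what the generator produces (within-pair correlation ≈ 0.9).

## Spatial tests

Folding replaces the lateral coordinate by |lateral − midline| (midline:
supplied, or the median lateral coordinate), so bilaterally mirrored cells
coincide. The statistic is the mean pairwise Euclidean distance of a
pattern's cells after folding (the full pairwise distance distribution is
also exported); the null is the same statistic for uniformly drawn
same-size cell sets, p with the add-one convention. Compactness and
bilateral symmetry are deliberately conflated by the fold — either yields
a small statistic.

## Synthetic-data generator

Behavior: running is a discrete-time telegraph process with entry rate
p(t)/τ_fast and exit rate (1 − p(t))/τ_fast, so its conditional
autocorrelation time is exactly the configured τ_fast (default 1 s) and
the mean bout lasts τ_fast/(1 − p) — a few seconds. p(t) is a sigmoid of
a stationary Ornstein–Uhlenbeck process with correlation time
`tendency_timescale_slow` (default 40 s) and SD 1 on the log-odds scale,
with the offset solved by Gauss–Hermite quadrature so the mean run
occupancy hits its target (default 19%). The resulting run autocorrelation
is the sum of a fast (bout) and a slow (tendency) component; the sigmoid
slightly distorts the slow component away from a single exponential, which
is why recovered slow constants center a few percent low. Non-running
frames follow a semi-Markov chain over quiescence, grooming and abdomen
bending with exponential dwells (mean 2 s) and stationary probabilities
proportional to the occupancy targets (defaults 50/6/15/10%). Soft
probabilities are boxcar-smoothed one-hot labels (width scaling with the
temperature) sharpened by exponent 1/temperature — at temperature → 0 they
are exactly one-hot. Marker jitter amplitudes per state and a ball signal
high exactly during running are constructed so the heuristic labeler
recovers the states.

Cells: somata in a 300×340×100 μm box, midline at 150 μm. Cluster sizes
are exponential (mean 4) clipped at ≥2; bilateral clusters (default half)
are mirrored pairs of jittered positions (σ = 8 μm), so with full
bilaterality the member set is exactly reflection-invariant.
Anticorrelated cells (default 10%) get negative running weights and sit in
a dorsomedial "PI" box.

Activity is the encoding model's own forward model: quadratic drift,
kernel-filtered behavior terms (τ bimodal: 57% in 0.5–3 s, 43% in
20–60 s; φ positive, scaling with τ, capped at 25 s; γ_run 0.05–0.4 ΔF/F,
other behaviors ≤0.08), plus cluster latents (OU, 5 s, loading 0.25 so
within-cluster correlation ≈0.9), per-cell idiosyncratic OU dynamics
(SD 0.1 ΔF/F, 5 s; members scaled by 0.75 — their dynamics budget is the
shared latent), and white noise (SD 0.05). Raw channels: red = baseline ×
exponential bleach (amplitude 0.3, 600 s), with multiplicative artifact
noise for a few motion cells; green = red × (1 + ΔF/F − min ΔF/F), the
baseline-at-minimum convention the ΔF/F estimator assumes.

What the generator does **not** emulate: optics and image formation,
motion correction and segmentation errors (beyond the CV²-flagged cells),
pose-estimation noise and label errors from a real classifier,
non-exponential bleaching, indicator nonlinearity and saturation,
inter-animal variability, and any dependence of residual dynamics on
behavioral state (residuals are state-independent by construction, the
regime the state-subspace analysis is designed to detect). Tests passing
on this generator validate the estimators' correctness and calibration
under the stated statistical structure, not robustness to those real-data
failure modes.

## Problem sizes and determinism

The test suite runs the full chain at desk scale: sessions of 2–20
minutes at 10 Hz, populations of 20–300 cells, 5–40 planted clusters;
dimensionality recovery at 40 factors uses 40-minute sessions because the
effective sample count for smooth latents, not the frame count, limits
resolution. Every stochastic component takes an explicit seed;
per-operation substreams derive from the config seed, and identical
configurations reproduce byte-identical pipeline outputs (hash manifest).

## Known limitations

- The baseline's m = min F makes recovered ΔF/F correct up to a per-cell
  constant when activity never returns exactly to baseline; downstream
  drift terms absorb it.
- The shift-significance test is permissive per cell (~1/6 null rate) by
  construction; use it to select populations, not to certify single cells.
- The isotropic-noise likelihood overestimates dimensionality on strongly
  heteroskedastic residuals (see above).
- E_mb curves are undefined/inflated when the fitting state is pure noise.
- The Ward tree is rebuilt per session; no attempt is made to match
  clusters across sessions or animals.
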