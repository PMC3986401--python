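# Methods

This note documents the models, estimators, numerical choices and known
limitations of soma-spt. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from data the
package cannot regenerate.

## Image formation model (the simulator)

A raw camera frame is modelled as

    ADU = gain · Poisson(b + Σ_on-emitters N · PSF(x, y, σ)) + offset [+ read noise]

where `PSF` is a symmetric 2D Gaussian integrated over each pixel (difference
of error functions per axis), `N` the expected photons per frame from an
on-state emitter, and `b` the expected background photons per pixel per
frame. Gaussian read noise is supported but off by default because the MLE
fitter downstream assumes pure Poisson counts; EMCCD excess noise is not
modelled.

Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| pixel size | 0.127 µm | the reference imaging systems' pixel pitch |
| z-step | 0.300 µm | the reference z-stack acquisition step |
| PSF σ | 1.2 px ≈ 152 nm | diffraction-limited width for a ~620 nm emitter at NA 1.4 |
| photons/frame (on) | 800 | a bright single QD at video rate; makes ≤ 50 nm localization attainable with margin |
| background | 10 photons/px/frame | cellular autofluorescence at moderate excitation |
| blink p_off, p_on | 0.10, 0.50 per frame | two-state Markov chain with ~83% duty cycle; kinetics are a package choice, stated not measured |
| camera offset, gain | 100 ADU, 2 ADU/e⁻ | typical EMCCD calibration values |

Blinking is a two-state (on/off) Markov chain sampled per frame; real QD
off-time distributions are power-law-like, so long dark states are
under-represented — blink-related conclusions from the simulator are about
the analysis logic (gap tolerance, level detection), not QD photophysics.

Trajectories are piecewise-homogeneous sequences of motion phases:
Brownian (per-axis step variance `2·D·dt`), directed (arc-length advance
`v·dt` along a polyline path), confined (Brownian proposals mirror-reflected
at a square corral of side `L` centred at phase entry; the reflecting square
matches the corral MSD model used by the fitter) and stationary. Motion is
planar; z is fixed, matching fixed-z live acquisition.

Z-stacks render each QD over 3–5 planes with a triangular axial intensity
profile of half-width two z-steps — a stand-in for the unmodelled axial PSF
that guarantees the ≥ 3-plane linking criterion is meaningful. The membrane
channel renders each plane's contour as a Gaussian ridge (σ equal to the
PSF σ) over background. Cell contours are smooth star-convex blobs (low-order
Fourier radius modulation, gentle axial taper), placed so internal QDs are
≥ 0.5 µm inside and membrane QDs within 0.1 µm of the contour, with a 0.9 µm
minimum in-plane separation so puncta are resolvable, as they are in the
sparse-labelling regime the analysis targets.

What the simulator deliberately omits: realistic neuron morphology
(non-convex somata, processes), spectral crosstalk, chromatic aberration
beyond a rigid shift, axial astigmatism, EMCCD excess noise, power-law
blinking. Passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to every property of real recordings.

## Detection and MLE localization

Candidates are local maxima of a difference-of-Gaussians filter (σ 1.0/2.0 px)
above 4× the robust (MAD-based) sigma of the filtered frame, excluding a
half-ROI border; candidates closer than one ROI width keep only the brighter
(ties: lower row, then column). The 7×7 ROI around each candidate is fit by
Poisson maximum likelihood with per-parameter damped Newton updates over
(x, y, N, b), position steps clamped to 1 px, at most 30 iterations,
converged when the position update < 1e-4 px. σ is fixed at the configured
PSF width. The CRLB is taken from the inverse Fisher information of the
fitted model; the Monte-Carlo standard deviation of the estimator matches it
within 20% at default SNR (tested). The goodness filter computes
`LLR = 2(LL_saturated − LL_fit)` and accepts a fit when its χ² upper-tail
p-value (dof = n_pixels − 4) is ≥ 1e-3 and the fitted photons exceed the
intensity threshold; non-converged fits are never accepted.

Coordinate convention, used everywhere: 0-based pixel indices; the centre of
pixel (row r, col c) is at (x, y) = ((c+0.5)·p, (r+0.5)·p) µm.

## Radial-symmetry localization

The gradient of a radially symmetric spot points at its centre. On the
half-pixel midpoint grid, intensity gradients are taken along the two
diagonals, smoothed 3×3, and the centre is the weighted least-squares point
minimizing perpendicular distance to the gradient lines (weights: squared
gradient magnitude over distance to the gradient centroid). This is fit-free
and roughly 100× faster than the MLE; at the default SNR its RMSE is ~11 nm
(recomputed by `scripts/acceptance.py`), comfortably below the 50 nm
resolution requirement. Degenerate (structureless) ROIs raise an error.

## Membrane segmentation

Per plane: a noise-compensated phase-congruency map (log-Gabor bank, 3
scales, 6 orientations, minimum wavelength 4 px, multiplier 2.1, σ_onf 0.55,
noise factor k = 2) is thresholded by Otsu, intersected with a dilated Otsu
intensity mask, skeletonized, and the largest connected ridge is ordered into
a closed contour by polar angle about its centroid. Phase congruency is
contrast-invariant, so the contour shifts < 0.1 px under affine intensity
rescaling (tested). The polar-angle ordering assumes a star-convex cell
outline — adequate for somata, wrong for strongly lobed cells; a
gradient-magnitude ridge fallback is available and flagged in the output
metadata. Planes with no closed contour are marked empty, not fatal.

## z-linking and classification

Localizations whose positions fall in the same XY pixel across planes are
grouped with a 1-pixel Chebyshev tolerance (sub-pixel jitter straddles pixel
edges; the strict same-pixel rule is available as `tol_px=0`). Planes need
not be contiguous, tolerating blinking; groups spanning < 3 planes are
discarded. A group's z is the mean member-plane z, its x-y the mean of member
localizations. Classification uses the signed Euclidean distance to the
contour of the single nearest z-plane (even-odd rule for the sign; no 3D
surface interpolation — the stack's 3D rendering is visualization, not
measurement): membrane if |d| ≤ 0.25 µm (~2 px, a package default),
internal if inside, external if outside, unresolved if the nearest plane has
no contour.

## Tracking

Stage 1 solves, per consecutive frame pair, a padded rectangular assignment
with link cost = squared displacement (forbidden beyond `max_disp`) and
birth/death alternative cost `(1.05·max_disp)²`. Stage 2 closes gaps by a
second global assignment joining segment ends to later segment starts
(1 ≤ dark frames ≤ `max_gap`, default 5; forbidden beyond `max_disp` per
elapsed frame). Both stages use an exact solver, not a greedy one. Bridged
frames carry linearly interpolated positions flagged `gap=True` and no
photometry. Defaults: `max_disp` 0.64 µm/frame (5 px at 9 frames/s — covers
the fastest directed transport observed, ~2.5 µm/s, with margin). Linking
correctness is verified against exhaustive enumeration for two particles and
by trajectory-purity ≥ 0.98 on rendered movies with ≥ 2 µm spacing.

Channel alignment maximizes the mean-subtracted cross-correlation of the two
channels' sum projections with 3-point quadratic sub-pixel refinement; the
search is limited to shifts under a quarter of the image width and a peak on
the search border is an error.

## MSD analysis

`MSD(kΔt)` averages squared displacements over all observed frame pairs at
lag k (bridged gap frames contribute no pairs), to a default maximum lag of a
quarter of the frame span; the implementation is tested for exact equality
with an O(N²) double-loop oracle. Fits use the first min(10, available) lags,
weighted by pair counts: free diffusion `4DΔt + c` via nonnegative weighted
least squares, corralled diffusion `(L²/3)(1 − e^{−12DΔt/L²}) + c` via
bounded Levenberg-Marquardt (initialized from the first-lag slope and the MSD
plateau); the model with lower AIC is reported. `model_ok` is lowered when
the selected model's weighted R² < 0.98 — ballistic input fails this, which
guards against fitting a diffusion model to transport. A non-convergent
corral fit falls back to the free model with `fit_converged=False`. Note that
single-trajectory MSD fits have large variance; D should be pooled across
trajectories or replicates, as the acceptance script does (20 replicates of
1000 frames recover D within a few percent).

## Paths, speeds, phases

Smooth paths are least-squares fits of x(t) and y(t), either one global
quadratic or cubic least-squares splines with equally spaced interior knots.
When the segment count is not given it is doubled from 2 until the residual
RMS falls to twice the localization uncertainty (estimated from second
differences when not supplied) — smooth without truncating features. Arc
length integrates the densely sampled path (10 samples per frame). Path
position s(t) is the arc length of the nearest dense sample to each
localization, ties resolved toward smaller s; s(t) is not forced monotone,
so back-tracking is representable. Speeds are slopes of first-order
polynomial fits over consecutive (default 2 s) sections; positive speed is
motion away from the path start.

Phase segmentation classifies rolling 2 s windows (0.5 s step): immobile if
the window's net displacement < 3× localization σ; directed if window path
speed ≥ 0.2 µm/s and straightness (net/path length) ≥ 0.8; else diffusive.
Label runs shorter than 3 windows are absorbed into the longer neighbour
(transition windows straddle two phases and flicker). Merged diffusive
segments ≥ 4 s whose interior (trimmed by one window at each end) stays
within a 1.0 µm bounding box are relabelled confined. These thresholds are
package defaults chosen for the magnitudes this system exhibits (transport
0.2–2.5 µm/s, corrals ≲ 1 µm); they are not universal constants and should
be revisited for other receptors or cell types.

## Blinking classification

The intensity trace sums calibrated counts in a 6×6 px window (760×760 nm)
centred on the particle's rounded position, using the interpolated position
across bridged gaps. States come from an Otsu threshold. A trace is
`multiple` when a 3-level 1D k-means finds three levels each occupying ≥ 5%
of frames with inter-level gaps ≥ 5 within-level standard deviations —
independent emitters superimpose to a stable intermediate level. It is
`single` when on/off separation is ≥ 3σ, at least one off excursion reaches
the background level (2nd percentile of the trace when no external estimate
is given) and the on level is unimodal by the same k-means gap criterion.
Everything else — including a constant trace — is `indeterminate`.

## Pipeline and evaluation

The movie mode runs simulate → calibrate/detect/fit/filter → link → MSD/phase
analysis at a fixed z; the z-stack mode runs simulate → membrane segmentation
→ per-plane radial-symmetry localization → z-linking → classification. All
randomness flows from one seed through a single generator, so a config + seed
pair reproduces byte-identical outputs (tested); every output carries the
seed and a SHA-256 hash of the configuration. Evaluation against simulator
truth uses greedy nearest matching within 2 px, each truth point used once —
greedy rather than optimal assignment, which is accurate at the sparse
densities involved and much cheaper. Internalization is reported pooled over
QDs; per-cell weighting is a choice the caller makes by running cells
separately.

## Problem sizes

The bundled validation uses desk-scale problems: 500-spot localization
ensembles, 20 replicate 1000-frame trajectories for diffusion recovery,
single 360–630-frame trajectories for path/speed recovery, and one
256×256×15-plane two-channel cell with 50 QDs for the internalization
measurement. These sizes give sampling error comfortably inside the stated
tolerances while keeping the full suite fast.

## Known limitations

- Membrane contours must be star-convex about their centroid.
- The corral MSD model assumes a square reflecting domain; other confinement
  geometries bias L.
- Fixed-σ PSF fitting biases photometry when the true PSF width deviates
  from the configured value (a free-σ refit is not implemented).
- The two-state blink model cannot produce the power-law dark times of real
  QDs; gap-closing performance on real data may differ.
- Evaluation matching is greedy; at very high emitter densities it can
  undercount true positives.
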