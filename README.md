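# soma-spt

Single-particle tracking analysis of quantum-dot-labelled ligand–receptor
complexes (QD-BDNF bound to TrkB) in the soma of live neurons, rebuilt as a
tested, reusable Python pipeline. Because single fluorescent emitters inside a
cell are diffraction-limited spots on a noisy EMCCD frame, every biological
quantity — where a receptor complex sits relative to the plasma membrane, how
fast it is transported, whether its motion is free, confined or directed —
must be recovered by statistical estimation from the raw movie. This package
implements that full chain and ships a ground-truthed microscopy simulator so
every stage can be validated end to end without experimental data.

The pipeline is aimed at quantitative cell biologists and microscopists
analysing single-QD tracking data (fixed-z movies and two-channel z-stacks),
and at method developers who need a forward model with known truth.

## What it computes

**Detection and localization.** Raw frames are calibrated to photon counts,
`counts = (ADU − offset) / gain`, so pixel values are Poisson distributed.
Candidate spots from a difference-of-Gaussians filter are fit with a
pixel-integrated 2D Gaussian PSF by Poisson maximum likelihood, maximizing
`L(x, y, N, b) = Σᵢ dᵢ ln μᵢ − μᵢ` with `μᵢ = b + N ∫pixel i G(x,y,σ)`. The
Fisher information of the same model gives the CRLB on the position, and a
log-likelihood-ratio test against the saturated Poisson model rejects
candidates that do not match the PSF shape (two overlapping emitters, debris).
A radial-symmetry localizer (gradient-line least squares) provides a fast,
fit-free alternative used in the z-stack branch; both reach well under the
50 nm resolution the imaging system is specified to deliver on 127 nm pixels.

**Membrane vs cytoplasm (3D).** The membrane-label channel of a z-stack
(z-step 300 nm) is segmented per plane by phase congruency — a log-Gabor
filter-bank edge measure that is invariant to image contrast — thinned to a
ridge and fit with a closed contour. QD localizations are linked across
planes (same XY pixel in ≥ 3 planes, not necessarily contiguous, to tolerate
blinking; z = mean member-plane z) and classified membrane / internal /
external by signed distance to the nearest-plane contour. The internalized
fraction is `n_internal / (n_internal + n_membrane)`.

**Tracking.** Per-frame localizations are linked by the two-stage cost-matrix
method: optimal frame-to-frame assignment with squared-displacement costs and
a birth/death alternative, then global gap closing across blinking-induced
dark frames. A rigid sub-pixel channel shift is estimated from sum-projection
cross-correlation.

**Dynamics.** Per-trajectory mean-square displacement is fit to free
diffusion, `MSD(Δt) = 4DΔt + c`, or corralled diffusion,
`MSD(Δt) = (L²/3)(1 − e^{−12DΔt/L²}) + c`, selected by AIC. Smooth paths
(quadratic or segmented spline in x(t), y(t)) give curvilinear arc length;
speeds are slopes of first-order fits to path position vs time. A
rolling-window classifier segments trajectories into directed / confined /
diffusive / immobile phases, and 6×6-pixel intensity traces are classified as
single-QD (square-pulse on/off blinking reaching background) or multiple.

## Worked example

Simulate a 20 s movie of five membrane-diffusing QD-BDNF complexes
(D = 0.29 µm²/s, 9 frames/s, blinking emitters), then detect, track and fit:

```python
import numpy as np
from soma_spt import RunConfig, run

config = RunConfig(
    mode="movie", seed=7, n_frames=180, dt_s=1/9, image_shape=(192, 192),
    n_particles=5, phases=[{"kind": "brownian", "duration": 20.0, "D": 0.29}],
    blink={"p_off": 0.02, "p_on": 0.6}, min_separation_um=4.0,
)
bundle = run(config, "out")
ds = [f["D_um2_s"] for f in bundle["msd_fits"].values()]
rep = bundle["evaluation"]
print(f"{len(bundle['trajectories'])} trajectories; "
      f"mean D over {len(ds)} MSD fits = {np.mean(ds):.3f} um^2/s")
print(f"detection recall {rep.detection_recall:.3f}, "
      f"localization RMSE {1000*rep.localization_rmse_um:.1f} nm, "
      f"trajectory purity {rep.trajectory_purity:.3f}")
```

prints

```
34 trajectories; mean D over 20 MSD fits = 0.319 um^2/s
detection recall 0.998, localization RMSE 10.8 nm, trajectory purity 1.000
```

Every emitter is found (recall 0.998) and localized to ~11 nm, no trajectory
mixes two particles (purity 1.000), and the pooled diffusion coefficient
recovers the simulated 0.29 µm²/s within the scatter expected from twenty
short single-trajectory MSD fits. The 34 trajectories reflect blinking:
off-periods longer than the gap-closing limit split tracks, exactly as in
real QD data. The same `run()` writes `localizations.csv`,
`trajectories.csv`, `phases.csv`, `msd_fits.json` and `evaluation.json`, and
the CLI (`soma-spt simulate|detect|track|analyze|run --config cfg.yaml`)
exposes the identical stages.

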