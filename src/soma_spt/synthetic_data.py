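"""Ground-truthed synthetic fluorescence microscopy for single-QD tracking.

Generates movies (fixed z, one blinking-emitter channel) and two-channel
z-stacks (QD channel + membrane-label channel) with the statistical
structure the downstream analysis assumes:

* single quantum-dot emitters with two-state Markov blinking,
* a pixel-integrated 2D Gaussian PSF on a 127 nm pixel grid,
* Poisson shot noise scaled by camera gain with a fixed offset
  (optional additive Gaussian read noise, off by default),
* per-z-plane closed membrane contours (z-step 300 nm),
* trajectories composed of Brownian, directed, confined and stationary
  motion phases at experimentally reported magnitudes.

Every simulator returns the rendered data together with a ground-truth
table so detection, localization, linking and dynamics estimates can be
scored against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LinearRing, Point, Polygon

from ._gauss import gaussian_spot

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: pixel size of the reference imaging system (µm); one pixel = 127 nm
DEFAULT_PIXEL_SIZE_UM = 0.127
#: axial step between z-planes (µm)
DEFAULT_Z_STEP_UM = 0.300


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera calibration: raw ADU = gain * photoelectrons + offset."""

    offset: float = 100.0
    gain: float = 2.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass(frozen=True)
class PSFModel:
    """Imaging model of a point emitter.

    sigma is the Gaussian PSF standard deviation in pixels (default
    1.2 px ≈ 152 nm, diffraction-limited for a red-emitting QD at
    NA 1.4). photons_on is the expected photon yield per frame in the
    fluorescent on state; background is expected photons/pixel/frame.
    """

    sigma: float = 1.2
    photons_on: float = 800.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.photons_on <= 0:
            raise ValueError("photons_on must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass(frozen=True)
class BlinkModel:
    """Two-state Markov blinking: per-frame switching probabilities."""

    p_off: float = 0.1
    p_on: float = 0.5
    initial_state: str = "on"

    def __post_init__(self) -> None:
        for p in (self.p_off, self.p_on):
            if not 0.0 <= p <= 1.0:
                raise ValueError("blink probabilities must be in [0, 1]")
        if self.initial_state not in ("on", "off"):
            raise ValueError("initial_state must be 'on' or 'off'")

    @property
    def stationary_on_fraction(self) -> float:
        denom = self.p_on + self.p_off
        return 1.0 if denom == 0 else self.p_on / denom


PHASE_KINDS = ("brownian", "directed", "confined", "stationary")


@dataclass(frozen=True)
class MotionPhase:
    """One homogeneous motion phase of a simulated trajectory.

    kind:
      brownian   — isotropic diffusion, per-axis step variance 2·D·dt
      directed   — arc-length advance v·dt along `path` (control points
                   in µm, relative to the phase entry point; a straight
                   line along +x when absent)
      confined   — Brownian proposals reflected at a square corral of
                   side L centred on the phase entry point
      stationary — position held fixed
    """

    kind: str
    duration: float
    D: float = 0.0
    v: float = 0.0
    L: float = 0.0
    path: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.D < 0 or self.v < 0:
            raise ValueError("D and v must be >= 0")
        if self.kind == "confined" and self.L <= 0:
            raise ValueError("confined phase requires L > 0")


@dataclass
class TruthTrajectory:
    """Ground-truth particle path sampled at the frame interval."""

    particle_id: int
    times: np.ndarray  # (n,), s, strictly increasing
    positions: np.ndarray  # (n, 3), µm
    on_states: np.ndarray  # (n,), bool
    phase_labels: np.ndarray  # (n,), str

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.positions) == len(self.on_states) == len(self.phase_labels) == n):
            raise ValueError("per-frame arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CellGeometry:
    """Closed membrane contour per z-plane.

    contours[j] is an (m_j, 2) array of ordered (x, y) vertices in µm
    describing a simple closed polygon; plane j sits at z = j * z_step.
    """

    contours: list[np.ndarray]
    z_step: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("need at least one plane")
        for c in self.contours:
            ring = LinearRing(c)
            if not ring.is_simple:
                raise ValueError("membrane contour must be simple (non-self-intersecting)")

    @property
    def n_planes(self) -> int:
        return len(self.contours)

    def plane_z(self, j: int) -> float:
        return j * self.z_step

    def polygon(self, j: int) -> Polygon:
        return Polygon(self.contours[j])


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _polyline_cumlen(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arclength(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length s along a polyline; extrapolates past the end."""
    if s <= 0:
        return points[0].copy()
    if s >= cum[-1]:
        # continue along the last segment direction
        d = points[-1] - points[-2]
        d = d / np.linalg.norm(d)
        return points[-1] + (s - cum[-1]) * d
    k = int(np.searchsorted(cum, s, side="right")) - 1
    f = (s - cum[k]) / (cum[k + 1] - cum[k])
    return points[k] + f * (points[k + 1] - points[k])


def simulate_trajectory(
    phases: Sequence[MotionPhase],
    dt: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    seed: int | np.random.Generator | None = None,
    particle_id: int = 0,
) -> TruthTrajectory:
    """Simulate a particle path as an ordered sequence of motion phases.

    Motion is in the x-y plane (z is held at the origin value, matching
    fixed-z live imaging). The first sample is at the origin at t = 0;
    each phase contributes round(duration / dt) steps.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not phases:
        raise ValueError("need at least one phase")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    pos = [np.asarray(origin, dtype=float)]
    labels = ["init"]
    for phase in phases:
        n_steps = max(1, int(round(phase.duration / dt)))
        entry = pos[-1].copy()
        labels[-1] = phase.kind if labels[-1] == "init" else labels[-1]
        if phase.kind == "stationary":
            for _ in range(n_steps):
                pos.append(entry.copy())
                labels.append(phase.kind)
        elif phase.kind == "brownian":
            steps = rng.normal(0.0, np.sqrt(2.0 * phase.D * dt), size=(n_steps, 2))
            cur = entry.copy()
            for s in steps:
                cur = cur + np.array([s[0], s[1], 0.0])
                pos.append(cur.copy())
                labels.append(phase.kind)
        elif phase.kind == "confined":
            half = phase.L / 2.0
            lo = entry[:2] - half
            hi = entry[:2] + half
            cur = entry.copy()
            sd = np.sqrt(2.0 * phase.D * dt)
            for _ in range(n_steps):
                prop = cur[:2] + rng.normal(0.0, sd, size=2)
                # reflect into the corral (repeat for large excursions)
                for ax in range(2):
                    x = prop[ax]
                    width = hi[ax] - lo[ax]
                    while x < lo[ax] or x > hi[ax]:
                        if x < lo[ax]:
                            x = 2 * lo[ax] - x
                        else:
                            x = 2 * hi[ax] - x
                    prop[ax] = x
                cur = np.array([prop[0], prop[1], entry[2]])
                pos.append(cur.copy())
                labels.append(phase.kind)
        else:  # directed
            if phase.path is not None:
                ctrl = np.asarray(phase.path, dtype=float)
                pts = entry[:2] + ctrl  # control points relative to entry
                if not np.allclose(pts[0], entry[:2]):
                    pts = np.vstack([entry[:2], pts])
            else:
                pts = np.vstack([entry[:2], entry[:2] + [1.0, 0.0]])
            cum = _polyline_cumlen(pts)
            for k in range(1, n_steps + 1):
                xy = _point_at_arclength(pts, cum, phase.v * dt * k)
                pos.append(np.array([xy[0], xy[1], entry[2]]))
                labels.append(phase.kind)

    positions = np.asarray(pos)
    n = len(positions)
    times = np.arange(n) * dt
    return TruthTrajectory(
        particle_id=particle_id,
        times=times,
        positions=positions,
        on_states=np.ones(n, dtype=bool),
        phase_labels=np.asarray(labels, dtype=object),
    )


def simulate_blink_states(
    blink: BlinkModel, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame on/off booleans from the two-state Markov chain."""
    states = np.empty(n_frames, dtype=bool)
    cur = blink.initial_state == "on"
    u = rng.random(n_frames)
    for i in range(n_frames):
        states[i] = cur
        cur = (u[i] >= blink.p_off) if cur else (u[i] < blink.p_on)
    return states


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------


def _apply_camera(
    expected_photons: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator,
    poisson_noise: bool = True,
) -> np.ndarray:
    if np.any(expected_photons < 0):
        raise ValueError("negative expected intensity")
    counts = rng.poisson(expected_photons) if poisson_noise else expected_photons
    raw = camera.gain * counts.astype(float) + camera.offset
    if camera.read_noise_sd > 0:
        raw = raw + rng.normal(0.0, camera.read_noise_sd, size=raw.shape)
    return raw


def render_movie(
    truths: Sequence[TruthTrajectory],
    camera: CameraModel,
    psf: PSFModel,
    blink: BlinkModel,
    n_frames: int,
    image_shape: tuple[int, int],
    seed: int | np.random.Generator | None = None,
    poisson_noise: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories to a raw-camera-unit movie plus a truth table.

    Each frame is gain · Poisson(background + Σ_on photons_on · PSF) +
    offset (plus optional Gaussian read noise). An emitter contributes
    in frame f while f < len(truth) and its blink state is on. Blink
    states are drawn per emitter from `blink` and recorded in the
    returned truth table (particle_id, frame, x_um, y_um, z_um, on,
    phase).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = camera.pixel_size
    h, w = image_shape

    blink_states = []
    for truth in truths:
        st = simulate_blink_states(blink, min(n_frames, len(truth)), rng)
        blink_states.append(st)
        xy = truth.positions[: len(st), :2]
        if np.any(xy < 0) or np.any(xy[:, 0] > w * p) or np.any(xy[:, 1] > h * p):
            raise ValueError(f"particle {truth.particle_id} leaves the field of view")

    movie = np.empty((n_frames, h, w), dtype=float)
    rows = []
    for f in range(n_frames):
        lam = np.full((h, w), float(psf.background))
        for truth, st in zip(truths, blink_states):
            if f >= len(st):
                continue
            x, y, z = truth.positions[f]
            on = bool(st[f])
            if on:
                lam += psf.photons_on * gaussian_spot((h, w), x / p, y / p, psf.sigma)
            rows.append(
                dict(
                    particle_id=truth.particle_id,
                    frame=f,
                    x_um=x,
                    y_um=y,
                    z_um=z,
                    on=on,
                    phase=truth.phase_labels[f],
                )
            )
        movie[f] = _apply_camera(lam, camera, rng, poisson_noise)

    truth_table = pd.DataFrame(
        rows, columns=["particle_id", "frame", "x_um", "y_um", "z_um", "on", "phase"]
    )
    return movie, truth_table


def render_spot_roi(
    size: int,
    x_px: float,
    y_px: float,
    psf: PSFModel,
    rng: np.random.Generator,
    poisson_noise: bool = True,
) -> np.ndarray:
    """Photon-count ROI containing a single emitter (no camera scaling)."""
    lam = psf.background + psf.photons_on * gaussian_spot((size, size), x_px, y_px, psf.sigma)
    return rng.poisson(lam).astype(float) if poisson_noise else lam


# ---------------------------------------------------------------------------
# Cell geometry and z-stacks
# ---------------------------------------------------------------------------


def make_cell_geometry(
    center_um: tuple[float, float] = (16.0, 16.0),
    mean_radius_um: float = 6.0,
    n_planes: int = 15,
    z_step: float = DEFAULT_Z_STEP_UM,
    irregularity: float = 0.10,
    n_vertices: int = 96,
    seed: int | np.random.Generator | None = None,
) -> CellGeometry:
    """A smooth star-convex soma-like contour per z-plane.

    The in-plane radius is modulated by a few low-order Fourier modes
    (amplitude `irregularity`) shared across planes, and scaled gently
    along z to mimic an optical section through the middle of a cell.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    modes = np.zeros_like(theta)
    for m in (2, 3, 4):
        amp = irregularity * rng.uniform(0.3, 1.0) / m
        phase = rng.uniform(0, 2 * np.pi)
        modes += amp * np.cos(m * theta + phase)
    base_r = mean_radius_um * (1.0 + modes)

    mid = (n_planes - 1) / 2.0
    contours = []
    for j in range(n_planes):
        # gentle ellipsoidal taper: >= 85% of the mid-plane radius
        u = 0.0 if mid == 0 else (j - mid) / (1.15 * (mid + 1))
        scale = max(0.85, np.sqrt(max(0.0, 1.0 - u * u)))
        r = base_r * scale
        contours.append(
            np.column_stack(
                [center_um[0] + r * np.cos(theta), center_um[1] + r * np.sin(theta)]
            )
        )
    return CellGeometry(contours=contours, z_step=z_step)


def _sample_point_inside(
    poly: Polygon, margin_um: float, rng: np.random.Generator, max_tries: int = 2000
) -> np.ndarray:
    """Uniform point at least margin_um inside the polygon boundary."""
    inner = poly.buffer(-margin_um)
    if inner.is_empty:
        raise ValueError("contour too small to place interior points at the stated margin")
    minx, miny, maxx, maxy = inner.bounds
    for _ in range(max_tries):
        pt = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if inner.contains(pt):
            return np.array([pt.x, pt.y])
    raise RuntimeError("rejection sampling failed")


def _sample_point_near_boundary(
    poly: Polygon, max_dist_um: float, rng: np.random.Generator
) -> np.ndarray:
    ring = poly.exterior
    pt = ring.interpolate(rng.uniform(0.0, ring.length))
    # offset along a random direction by at most max_dist_um
    ang = rng.uniform(0, 2 * np.pi)
    d = rng.uniform(0.0, max_dist_um)
    return np.array([pt.x + d * np.cos(ang), pt.y + d * np.sin(ang)])


def _axial_weight(dz_um: float, z_step: float) -> float:
    """Triangular axial intensity profile, full width 4 z-steps."""
    return max(0.0, 1.0 - abs(dz_um) / (2.0 * z_step))


def simulate_cell_zstack(
    geometry: CellGeometry,
    n_qd: int,
    frac_internal: float,
    membrane_label_photons: float = 300.0,
    camera: CameraModel | None = None,
    psf: PSFModel | None = None,
    seed: int | np.random.Generator | None = None,
    image_shape: tuple[int, int] = (256, 256),
    min_separation_um: float = 0.9,
    internal_margin_um: float = 0.5,
    membrane_band_um: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Two-channel synthetic z-stack of a membrane-labelled cell with QDs.

    Places round(frac_internal · n_qd) QDs at least `internal_margin_um`
    inside the contour of a random plane and the rest within
    `membrane_band_um` of the contour; each QD appears in >= 3
    consecutive planes with a triangular axial intensity falloff. The
    membrane channel renders each plane's contour as a bright Gaussian
    ridge over background. Returns (qd_stack, membrane_stack, truth)
    with stacks in raw camera units.
    """
    if not 0.0 <= frac_internal <= 1.0:
        raise ValueError("frac_internal must be in [0, 1]")
    if n_qd < 0:
        raise ValueError("n_qd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    camera = camera or CameraModel()
    psf = psf or PSFModel()
    p = camera.pixel_size
    h, w = image_shape
    n_planes = geometry.n_planes

    n_internal = int(round(frac_internal * n_qd))
    # keep emitters >= 2 planes from the stack ends so the axial profile fits
    plane_lo, plane_hi = 2, max(2, n_planes - 3)

    placed: list[np.ndarray] = []
    rows = []
    for i in range(n_qd):
        label = "internal" if i < n_internal else "membrane"
        for _ in range(500):
            j = int(rng.integers(plane_lo, plane_hi + 1))
            poly = geometry.polygon(j)
            if label == "internal":
                xy = _sample_point_inside(poly, internal_margin_um, rng)
            else:
                xy = _sample_point_near_boundary(poly, membrane_band_um, rng)
            if all(np.linalg.norm(xy - q) >= min_separation_um for q in placed):
                break
        else:
            raise RuntimeError("could not place QDs at the requested separation")
        placed.append(xy)
        z = geometry.plane_z(j) + rng.uniform(-0.3, 0.3) * geometry.z_step
        rows.append(
            dict(particle_id=i, x_um=xy[0], y_um=xy[1], z_um=z, label=label, plane=j)
        )
    truth = pd.DataFrame(
        rows, columns=["particle_id", "x_um", "y_um", "z_um", "label", "plane"]
    )

    # QD channel
    qd_stack = np.empty((n_planes, h, w), dtype=float)
    for j in range(n_planes):
        lam = np.full((h, w), float(psf.background))
        zj = geometry.plane_z(j)
        for r in rows:
            wgt = _axial_weight(r["z_um"] - zj, geometry.z_step)
            if wgt > 0:
                lam += (
                    wgt
                    * psf.photons_on
                    * gaussian_spot((h, w), r["x_um"] / p, r["y_um"] / p, psf.sigma)
                )
        qd_stack[j] = _apply_camera(lam, camera, rng)

    # membrane channel: Gaussian ridge along each plane's contour
    from scipy.spatial import cKDTree

    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([(xx.ravel() + 0.5) * p, (yy.ravel() + 0.5) * p])
    mem_stack = np.empty((n_planes, h, w), dtype=float)
    ridge_sigma = psf.sigma * p
    for j in range(n_planes):
        ring = LinearRing(geometry.contours[j])
        samples = [
            ring.interpolate(s) for s in np.linspace(0, ring.length, 4000, endpoint=False)
        ]
        tree = cKDTree(np.array([[q.x, q.y] for q in samples]))
        d, _ = tree.query(centers, k=1)
        lam = psf.background + membrane_label_photons * np.exp(
            -(d.reshape(h, w) ** 2) / (2.0 * ridge_sigma**2)
        )
        mem_stack[j] = _apply_camera(lam, camera, rng)

    return qd_stack, mem_stack, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_stack(
    path: str | Path,
    stack: np.ndarray,
    meta: dict,
    truth: pd.DataFrame | None = None,
) -> None:
    """16-bit multi-page TIFF + JSON metadata sidecar (+ truth CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    if truth is not None:
        truth.to_csv(path.with_suffix("").as_posix() + "_truth.csv", index=False)


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return data, meta
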