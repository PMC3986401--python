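"""Motion and photophysics analysis of single-particle trajectories.

* Mean-square displacement curves and fits to a free-diffusion model
  (MSD = 4DΔt + offset) or a corralled-diffusion model
  (MSD = (L²/3)(1 − exp(−12DΔt/L²)) + offset), selected by AIC.
* Smooth paths (second-order polynomial or segmented spline of x(t),
  y(t)), arc-length positions along the path, and piecewise speeds from
  first-order polynomial fits of path position versus time (positive =
  motion away from the path start).
* Rolling-window motion-phase segmentation into directed / confined /
  diffusive / immobile.
* QD blinking analysis: 6×6-pixel intensity traces and single-vs-
  multiple emitter classification from the on/off level structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import LSQUnivariateSpline
from scipy.optimize import curve_fit, nnls
from skimage.filters import threshold_otsu

from .tracking import Trajectory

DEFAULT_LOC_SIGMA_UM = 0.03  # typical localization uncertainty (30 nm)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray
    dt: float
    model: str | None = None  # "free" | "corralled"
    D: float = np.nan  # µm²/s
    L: float = np.nan  # µm (corralled)
    offset: float = np.nan  # µm²
    r2: float = np.nan
    model_ok: bool = False
    fit_converged: bool = True


def compute_msd(traj: Trajectory, max_lag_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all observed frame pairs of one trajectory.

    msd(kΔt) = mean over i of |r(i+k) − r(i)|² using only observed
    (non-gap) localizations; bridged frames contribute no pairs. Lags
    run to one quarter of the trajectory frame span by default.
    """
    obs = ~traj.gap
    if obs.sum() < 10:
        raise ValueError("trajectory too short for MSD (need >= 10 observed frames)")
    frames = traj.frames[obs]
    xy = traj.xy[obs]
    span = frames[-1] - frames[0]
    kmax = max(1, span // 4) if max_lag_frames is None else max_lag_frames
    dt = float(np.median(np.diff(traj.times[obs]) / np.diff(frames)))

    pos = {int(f): xy[i] for i, f in enumerate(frames)}
    lags, msds, npairs = [], [], []
    for k in range(1, kmax + 1):
        d2 = [
            float(((pos[f + k] - pos[f]) ** 2).sum())
            for f in pos
            if f + k in pos
        ]
        if d2:
            lags.append(k * dt)
            msds.append(np.mean(d2))
            npairs.append(len(d2))
    return MSDCurve(
        lags_s=np.asarray(lags),
        msd=np.asarray(msds),
        n_pairs=np.asarray(npairs),
        dt=dt,
    )


def _corral_model(t: np.ndarray, D: float, L: float, offset: float) -> np.ndarray:
    return (L**2 / 3.0) * (1.0 - np.exp(-12.0 * D * t / L**2)) + offset


def fit_msd(msd: MSDCurve, max_fit_lags: int = 10) -> MSDCurve:
    """Fit free and corralled diffusion models; keep the lower-AIC one.

    Weighted least squares with weights proportional to the number of
    displacement pairs per lag, over the first min(max_fit_lags, n)
    lags. Constraints: D >= 0, offset >= 0, L > 0. The model_ok flag is
    lowered when even the selected model explains the curve poorly
    (weighted R² < 0.98), e.g. for ballistic input neither diffusion
    model applies.
    """
    n_use = min(max_fit_lags, len(msd.lags_s))
    if n_use < 4:
        raise ValueError("need at least 4 lags to fit")
    t = msd.lags_s[:n_use]
    y = msd.msd[:n_use]
    w = msd.n_pairs[:n_use].astype(float)
    sw = np.sqrt(w)

    # free model by nonnegative weighted LS: y = 4D t + offset
    A = np.column_stack([4.0 * t * sw, sw])
    coef, _ = nnls(A, y * sw)
    d_free, off_free = float(coef[0]), float(coef[1])
    res_free = y - (4.0 * d_free * t + off_free)
    rss_free = float(np.sum(w * res_free**2))

    # corralled model
    corral_ok = True
    try:
        slope0 = max((y[1] - y[0]) / (t[1] - t[0]), 1e-6)
        p0 = [slope0 / 4.0, max(np.sqrt(3.0 * max(y.max() - y[0], 1e-6)), 0.05), max(y[0], 0.0)]
        popt, _ = curve_fit(
            _corral_model,
            t,
            y,
            p0=p0,
            sigma=1.0 / sw,
            absolute_sigma=False,
            bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        d_cor, l_cor, off_cor = map(float, popt)
        res_cor = y - _corral_model(t, *popt)
        rss_cor = float(np.sum(w * res_cor**2))
    except (RuntimeError, ValueError):
        corral_ok = False
        rss_cor = np.inf
        d_cor = l_cor = off_cor = np.nan

    n = len(t)
    aic_free = n * np.log(max(rss_free, 1e-300) / n) + 2 * 2
    aic_cor = n * np.log(max(rss_cor, 1e-300) / n) + 2 * 3 if corral_ok else np.inf

    mean_y = np.sum(w * y) / np.sum(w)
    tss = float(np.sum(w * (y - mean_y) ** 2))

    out = MSDCurve(**{k: getattr(msd, k) for k in ("lags_s", "msd", "n_pairs", "dt")})
    if corral_ok and aic_cor < aic_free:
        out.model, out.D, out.L, out.offset = "corralled", d_cor, l_cor, off_cor
        rss = rss_cor
    else:
        out.model, out.D, out.L, out.offset = "free", d_free, np.nan, off_free
        rss = rss_free
    out.fit_converged = corral_ok or out.model == "free"
    out.r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    out.model_ok = bool(out.r2 >= 0.98)
    return out


# ---------------------------------------------------------------------------
# Smooth paths and speeds
# ---------------------------------------------------------------------------


@dataclass
class SmoothPath:
    """A fitted smooth x(t), y(t) path with dense arc-length samples."""

    method: str  # "poly2" | "spline"
    n_segments: int
    arc_length: float  # µm
    t_range: tuple[float, float]
    x_of_t: Callable[[np.ndarray], np.ndarray]
    y_of_t: Callable[[np.ndarray], np.ndarray]
    dense_t: np.ndarray = field(repr=False, default=None)
    dense_xy: np.ndarray = field(repr=False, default=None)
    dense_s: np.ndarray = field(repr=False, default=None)
    residual_rms: float = np.nan


def _densify(x_of_t, y_of_t, t0: float, t1: float, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    td = np.linspace(t0, t1, n)
    xy = np.column_stack([x_of_t(td), y_of_t(td)])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return td, xy, s


def fit_smooth_path(
    traj: Trajectory,
    method: str = "spline",
    n_segments: int | None = None,
    loc_sigma_um: float | None = None,
    dense_factor: int = 10,
) -> SmoothPath:
    """Least-squares smooth path through a trajectory.

    method="poly2" fits a global second-order polynomial to x(t) and
    y(t); method="spline" fits cubic least-squares splines with
    `n_segments` equal spans. When n_segments is None it is increased
    until the residual RMS drops to twice the localization uncertainty
    (estimated from high-frequency differences when not given), so the
    path is smooth without truncating features. Arc length is the
    numerically integrated length of the densely sampled path.
    """
    obs = ~traj.gap
    t = traj.times[obs]
    xy = traj.xy[obs]
    n = len(t)
    if method == "poly2":
        if n < 6:
            raise ValueError("need >= 6 points for a quadratic path")
    elif method != "spline":
        raise ValueError("method must be 'poly2' or 'spline'")

    if loc_sigma_um is None:
        # high-frequency noise estimate: second differences of a smooth
        # path have variance 6 sigma² per axis
        if n >= 4:
            d2 = np.diff(xy, n=2, axis=0)
            loc_sigma_um = float(np.sqrt(np.median(d2**2) / 6.0))
        else:
            loc_sigma_um = DEFAULT_LOC_SIGMA_UM
        loc_sigma_um = max(loc_sigma_um, 1e-4)

    def _fit(nseg: int):
        if method == "poly2":
            cx = npoly.polyfit(t, xy[:, 0], 2)
            cy = npoly.polyfit(t, xy[:, 1], 2)
            fx = lambda tt: npoly.polyval(tt, cx)
            fy = lambda tt: npoly.polyval(tt, cy)
        else:
            knots = np.linspace(t[0], t[-1], nseg + 1)[1:-1]
            fx = LSQUnivariateSpline(t, xy[:, 0], knots, k=3)
            fy = LSQUnivariateSpline(t, xy[:, 1], knots, k=3)
        res = np.column_stack([xy[:, 0] - fx(t), xy[:, 1] - fy(t)])
        rms = float(np.sqrt(np.mean(res**2)))
        return fx, fy, rms

    if method == "poly2":
        nseg = 1
        fx, fy, rms = _fit(nseg)
    elif n_segments is not None:
        if n < 4 * n_segments + 4:
            raise ValueError("trajectory too short for the requested segments")
        nseg = n_segments
        fx, fy, rms = _fit(nseg)
    else:
        max_seg = max(2, n // 12)
        nseg = 2
        fx, fy, rms = _fit(nseg)
        while rms > 2.0 * loc_sigma_um and nseg < max_seg:
            nseg = min(max_seg, nseg * 2)
            fx, fy, rms = _fit(nseg)

    td, dxy, s = _densify(fx, fy, t[0], t[-1], dense_factor * n)
    return SmoothPath(
        method=method,
        n_segments=nseg,
        arc_length=float(s[-1]),
        t_range=(float(t[0]), float(t[-1])),
        x_of_t=fx,
        y_of_t=fy,
        dense_t=td,
        dense_xy=dxy,
        dense_s=s,
        residual_rms=rms,
    )


def path_position(traj: Trajectory, path: SmoothPath) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position along the path of each observed localization.

    s(t) is the arc length from the path start to the densely sampled
    path point nearest the observed position; at exact ties the point
    with the smaller arc length wins. Back-tracking is allowed (s need
    not be monotone).
    """
    obs = ~traj.gap
    t = traj.times[obs]
    xy = traj.xy[obs]
    from scipy.spatial import cKDTree

    tree = cKDTree(path.dense_xy)
    d, idx = tree.query(xy, k=1)
    # cKDTree returns the first (lowest-index, hence smallest-s) of ties
    return t, path.dense_s[idx]


def estimate_speeds(
    t: np.ndarray,
    s: np.ndarray,
    window_s: float = 2.0,
    step_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise speeds: slope of a first-order fit of s versus t.

    Sections are consecutive windows of `window_s` seconds (sliding by
    `step_s` when given). Positive speed means motion along the path
    away from its start. Returns (section mid-times, speeds).
    """
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    if t[-1] - t[0] < window_s:
        raise ValueError("window longer than the record")
    step = window_s if step_s is None else step_s
    mids, speeds = [], []
    start = t[0]
    while start + window_s <= t[-1] + 1e-9:
        m = (t >= start - 1e-9) & (t <= start + window_s + 1e-9)
        if m.sum() >= 3:
            slope = npoly.polyfit(t[m], s[m], 1)[1]
            mids.append(start + window_s / 2.0)
            speeds.append(float(slope))
        start += step
    return np.asarray(mids), np.asarray(speeds)


# ---------------------------------------------------------------------------
# Motion-phase segmentation
# ---------------------------------------------------------------------------


@dataclass
class PhaseSegment:
    start_s: float
    end_s: float
    kind: str  # directed | confined | diffusive | immobile
    v: float = np.nan  # µm/s, directed
    extent_um: float = np.nan  # bounding-box diagonal of the segment


def segment_phases(
    traj: Trajectory,
    window_s: float = 2.0,
    step_s: float = 0.5,
    v_min: float = 0.2,
    straightness_min: float = 0.8,
    loc_sigma_um: float = DEFAULT_LOC_SIGMA_UM,
    confinement_extent_um: float = 1.0,
    confinement_min_s: float = 4.0,
    min_run_windows: int = 3,
) -> list[PhaseSegment]:
    """Rolling-window motion classification of one trajectory.

    Each window is immobile when its net displacement is below 3× the
    localization uncertainty; directed when the window speed (path
    length / duration) exceeds v_min with straightness (net/path)
    >= straightness_min; diffusive otherwise. Label runs shorter than
    `min_run_windows` are absorbed into the longer neighbouring run
    (transition windows straddle two motion kinds and flicker), then
    adjacent same-kind windows merge; merged non-directed segments that
    stay within a bounding box smaller than `confinement_extent_um` for
    at least `confinement_min_s` are relabelled confined.
    """
    obs = ~traj.gap
    t = traj.times[obs]
    xy = traj.xy[obs]
    if t[-1] - t[0] < max(window_s * 2, 4.0):
        raise ValueError("trajectory too short to segment (need >= 4 s)")

    starts = np.arange(t[0], t[-1] - window_s + 1e-9, step_s)
    labels = []
    for st in starts:
        m = (t >= st - 1e-9) & (t <= st + window_s + 1e-9)
        if m.sum() < 3:
            labels.append("diffusive")
            continue
        pts = xy[m]
        net = float(np.linalg.norm(pts[-1] - pts[0]))
        pathlen = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        dur = float(t[m][-1] - t[m][0])
        if net < 3.0 * loc_sigma_um:
            labels.append("immobile")
        elif pathlen / dur >= v_min and pathlen > 0 and net / pathlen >= straightness_min:
            labels.append("directed")
        else:
            labels.append("diffusive")

    # absorb label runs shorter than min_run_windows into a neighbour
    runs: list[list] = []  # [label, n_windows]
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[1] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] < min_run_windows:
            if i == 0:
                runs[1][1] += runs[0][1]
                runs.pop(0)
            elif i == len(runs) - 1:
                runs[-2][1] += runs[-1][1]
                runs.pop()
            else:
                j = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
                runs[j][1] += runs[i][1]
                runs.pop(i)
            # merge now-adjacent equal labels
            k = 0
            while k < len(runs) - 1:
                if runs[k][0] == runs[k + 1][0]:
                    runs[k][1] += runs[k + 1][1]
                    runs.pop(k + 1)
                else:
                    k += 1
            changed = True
    labels = [lab for lab, cnt in runs for _ in range(cnt)]

    # windows -> contiguous cover: window i owns [start_i, start_i + step)
    bounds = list(starts) + [t[-1]]
    segments: list[PhaseSegment] = []
    for i, lab in enumerate(labels):
        s0 = float(bounds[i])
        s1 = float(t[-1]) if i == len(labels) - 1 else float(bounds[i + 1])
        if segments and segments[-1].kind == lab:
            segments[-1].end_s = s1
        else:
            segments.append(PhaseSegment(start_s=s0, end_s=s1, kind=lab))

    for seg in segments:
        m = (t >= seg.start_s - 1e-9) & (t <= seg.end_s + 1e-9)
        if m.sum() < 2:
            continue
        pts = xy[m]
        dur = seg.end_s - seg.start_s
        seg.extent_um = float(np.linalg.norm(pts.max(0) - pts.min(0)))
        if seg.kind == "directed":
            seg.v = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() / dur)
        elif seg.kind == "diffusive" and dur >= confinement_min_s:
            # boundary windows straddle the neighbouring phase: judge
            # confinement on the segment interior
            trim = min(window_s, dur / 4.0)
            mi = (t >= seg.start_s + trim) & (t <= seg.end_s - trim)
            interior = xy[mi] if mi.sum() >= 2 else pts
            ext = float(np.linalg.norm(interior.max(0) - interior.min(0)))
            if ext < confinement_extent_um:
                seg.kind = "confined"
    return segments


# ---------------------------------------------------------------------------
# Blinking analysis
# ---------------------------------------------------------------------------


@dataclass
class IntensityTrace:
    """Summed photon counts in a window around a tracked particle."""

    frames: np.ndarray
    values: np.ndarray  # photons; NaN where the window left the image
    states: np.ndarray | None = None  # bool on/off
    n_levels: int = 0
    window_px: int = 6

    def __len__(self) -> int:
        return len(self.frames)


def intensity_trace(
    movie_counts: np.ndarray,
    traj: Trajectory,
    pixel_size_um: float = 0.127,
    window_px: int = 6,
) -> IntensityTrace:
    """Per-frame summed counts in a window_px × window_px box.

    The box is centred on the particle's rounded pixel position
    (6×6 px = 760×760 nm at 127 nm pixels); bridged gap frames use the
    interpolated position, which equals the last known position for a
    stationary emitter. Frames whose window leaves the image are NaN.
    """
    vals = np.full(len(traj), np.nan)
    half = window_px // 2
    n_frames, h, w = movie_counts.shape
    for i, f in enumerate(traj.frames):
        if f < 0 or f >= n_frames:
            continue
        c = int(round(traj.xy[i, 0] / pixel_size_um - 0.5))
        r = int(round(traj.xy[i, 1] / pixel_size_um - 0.5))
        r0, c0 = r - half + 1, c - half + 1
        if r0 < 0 or c0 < 0 or r0 + window_px > h or c0 + window_px > w:
            continue
        vals[i] = movie_counts[f, r0 : r0 + window_px, c0 : c0 + window_px].sum()
    return IntensityTrace(frames=traj.frames.copy(), values=vals, window_px=window_px)


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Tiny deterministic Lloyd's algorithm on sorted quantile seeds."""
    qs = np.linspace(0, 1, k + 2)[1:-1]
    centers = np.quantile(x, qs)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[assign == j].mean() if np.any(assign == j) else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return centers, assign


def classify_single_qd(
    trace: IntensityTrace, background_level: float | None = None
) -> tuple[str, IntensityTrace]:
    """Classify a blinking trace as from a single QD, multiple QDs, or
    indeterminate.

    On/off states come from thresholding at the midpoint of the two
    dominant intensity modes (Otsu). Single: at least one complete off
    excursion reaches the background level and the on-level distribution
    is unimodal. Multiple: a stable, well-separated intermediate level
    exists (three-mode structure). Indeterminate otherwise (e.g. a
    constant trace with no off excursion).
    """
    good = np.isfinite(trace.values)
    x = trace.values[good]
    if len(x) < 50:
        raise ValueError("trace too short to classify (need >= 50 frames)")

    thr = threshold_otsu(x)
    states_good = x > thr
    states = np.zeros(len(trace.values), dtype=bool)
    states[good] = states_good
    trace.states = states

    # three-level check first: a stable, well-separated intermediate
    # intensity mode means more than one emitter
    centers, assign = _kmeans_1d(x, 3)
    order = np.argsort(centers)
    centers = centers[order]
    occ = np.array([(assign == j).mean() for j in order])
    stds = np.array(
        [x[assign == j].std() if (assign == j).sum() > 1 else 0.0 for j in order]
    )
    gap_lo = (centers[1] - centers[0]) / (max(stds[0], stds[1]) + 1e-9)
    gap_hi = (centers[2] - centers[1]) / (max(stds[1], stds[2]) + 1e-9)
    if np.all(occ >= 0.05) and gap_lo >= 5.0 and gap_hi >= 5.0:
        trace.n_levels = 3
        return "multiple", trace

    on_vals, off_vals = x[states_good], x[~states_good]
    if len(on_vals) < 3 or len(off_vals) < 3:
        trace.n_levels = 1
        return "indeterminate", trace
    sep = (on_vals.mean() - off_vals.mean()) / (on_vals.std() + off_vals.std() + 1e-9)
    if sep < 3.0:
        trace.n_levels = 1
        return "indeterminate", trace

    # single: a complete off excursion reaching the background level
    bg = background_level if background_level is not None else float(np.percentile(x, 2))
    off_runs = _runs(~states_good)
    reaches_bg = any(
        x[a:b].min() <= bg + 3.0 * (off_vals.std() + 1e-9) for a, b in off_runs
    )
    # on-level unimodality: splitting the on level must not expose two
    # well-separated, well-populated sub-levels
    c2, a2 = _kmeans_1d(on_vals, 2)
    o = np.argsort(c2)
    s2 = np.array([on_vals[a2 == j].std() if (a2 == j).sum() > 1 else 0.0 for j in o])
    occ2 = np.array([(a2 == j).mean() for j in o])
    on_gap = (c2[o][1] - c2[o][0]) / (max(s2) + 1e-9)
    unimodal_on = not (on_gap >= 5.0 and occ2.min() >= 0.10)

    trace.n_levels = 2
    if reaches_bg and unimodal_on and len(off_runs) >= 1:
        return "single", trace
    return "indeterminate", trace


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
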