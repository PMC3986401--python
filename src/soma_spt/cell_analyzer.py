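"""3D membrane-vs-cytoplasm localization of quantum dots ("Cell Analyzer").

Given a two-channel z-stack (membrane label + QD emission), this module:

* segments the plasma membrane per z-plane with a contrast-invariant
  phase-congruency edge detector (log-Gabor filter bank) followed by
  threshold-based ridge extraction and closed-contour fitting,
* refines each QD candidate to sub-pixel x-y with the radial-symmetry
  centre method,
* links per-plane localizations across z — a QD must appear at the same
  XY pixel in at least 3 planes (not necessarily contiguous, tolerating
  blinking) and its z is the mean of its member-plane z positions,
* classifies each 3D QD position as membrane / internal / external by
  its signed distance to the nearest-plane contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize
from shapely.geometry import LinearRing, Point, Polygon

from .detection import SpotFit

# phase congruency defaults (log-Gabor bank)
PC_SCALES = 3
PC_ORIENTATIONS = 6
PC_MIN_WAVELENGTH = 4.0
PC_MULT = 2.1
PC_SIGMA_ONF = 0.55
PC_NOISE_K = 2.0

D_MEM_DEFAULT_UM = 0.25  # membrane-assignment distance (~2 px)


@dataclass
class MembraneMap:
    """Per-z-plane membrane contours and edge-strength maps.

    contours[j] is an (m, 2) array of ordered (x, y) vertices in µm for
    plane j, or None where no closed contour was found. pc_maps holds
    the phase-congruency map per plane. method records whether phase
    congruency or the gradient-ridge fallback produced the result.
    """

    contours: list[np.ndarray | None]
    pc_maps: list[np.ndarray] = field(default_factory=list)
    z_step: float = 0.300
    pixel_size_um: float = 0.127
    method: str = "phase_congruency"

    @property
    def n_planes(self) -> int:
        return len(self.contours)

    def nearest_plane(self, z_um: float) -> int:
        return int(np.clip(round(z_um / self.z_step), 0, self.n_planes - 1))


@dataclass
class QD3DLocation:
    """A z-linked QD with membrane/internal/external classification."""

    x_um: float
    y_um: float
    z_um: float
    n_planes: int
    label: str = "unlabeled"
    dist_membrane: float = np.nan  # signed, negative = inside
    planes: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Phase congruency (log-Gabor filter bank, noise-compensated)
# ---------------------------------------------------------------------------


def _log_gabor_bank(
    shape: tuple[int, int],
    n_scales: int,
    n_orient: int,
    min_wavelength: float,
    mult: float,
    sigma_onf: float,
) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor filters, [orientation][scale]."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0); the filter is zeroed there anyway
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    log_sig = 2.0 * np.log(sigma_onf) ** 2
    radial = []
    for s in range(n_scales):
        f0 = 1.0 / (min_wavelength * mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / log_sig)
        lg[0, 0] = 0.0
        radial.append(lg)

    theta_sigma = np.pi / n_orient / 1.2
    bank = []
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sintheta * np.cos(angle) - costheta * np.sin(angle)
        dc = costheta * np.cos(angle) + sintheta * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))
        bank.append([radial[s] * spread for s in range(n_scales)])
    return bank


def phase_congruency(
    image: np.ndarray,
    n_scales: int = PC_SCALES,
    n_orient: int = PC_ORIENTATIONS,
    min_wavelength: float = PC_MIN_WAVELENGTH,
    mult: float = PC_MULT,
    sigma_onf: float = PC_SIGMA_ONF,
    k: float = PC_NOISE_K,
) -> np.ndarray:
    """Noise-compensated phase congruency map in [0, 1].

    Phase congruency marks points where Fourier components are maximally
    in phase (edges, lines) independently of local contrast: the map is
    invariant under affine rescaling of image intensity up to the noise
    compensation, which itself scales with the image noise estimate.
    """
    img = np.asarray(image, dtype=float)
    eps = 1e-4
    imf = np.fft.fft2(img)
    bank = _log_gabor_bank(img.shape, n_scales, n_orient, min_wavelength, mult, sigma_onf)

    num = np.zeros_like(img)
    den = np.zeros_like(img)
    for filters in bank:
        eo = [np.fft.ifft2(imf * f) for f in filters]
        e = np.stack([z.real for z in eo])
        o = np.stack([z.imag for z in eo])
        an = np.sqrt(e**2 + o**2)
        sum_e, sum_o, sum_an = e.sum(0), o.sum(0), an.sum(0)
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.sum(e * mean_e + o * mean_o - np.abs(e * mean_o - o * mean_e), axis=0)

        # noise threshold from the smallest-scale amplitude distribution
        tau = np.median(an[0]) / np.sqrt(np.log(4.0))
        total_tau = tau * (1.0 - (1.0 / mult) ** n_scales) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sd = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        t = noise_mean + k * noise_sd
        energy = np.maximum(energy - t, 0.0)

        # penalize narrow frequency spread
        width = (sum_an / (an.max(0) + eps)) / n_scales
        weight = 1.0 / (1.0 + np.exp(10.0 * (0.5 - width)))
        num += weight * energy
        den += sum_an
    return num / (den + eps)


def _order_ridge_pixels(ridge_rc: np.ndarray) -> np.ndarray | None:
    """Order ridge pixels into a closed loop by polar angle (star-convex)."""
    if len(ridge_rc) < 8:
        return None
    center = ridge_rc.mean(axis=0)
    ang = np.arctan2(ridge_rc[:, 0] - center[0], ridge_rc[:, 1] - center[1])
    order = np.argsort(ang)
    ordered = ridge_rc[order]
    # require reasonable angular coverage for a closed contour
    gaps = np.diff(np.sort(ang))
    wrap = 2 * np.pi - (np.sort(ang)[-1] - np.sort(ang)[0])
    if max(gaps.max(initial=0.0), wrap) > np.pi / 2:
        return None
    return ordered


def segment_membrane(
    wga_zstack: np.ndarray,
    pixel_size_um: float = 0.127,
    z_step: float = 0.300,
    use_fallback: bool = False,
    **pc_kwargs,
) -> MembraneMap:
    """Per-plane membrane contour from the membrane-label channel.

    Each plane's phase-congruency map is binarized by its Otsu
    threshold, intersected with an Otsu intensity mask, thinned to a
    one-pixel ridge, and the largest connected ridge is ordered into a
    single closed contour. Planes where no closed contour emerges are
    marked empty (None), not fatal. With use_fallback=True a plain
    gradient-magnitude ridge replaces phase congruency (recorded in
    `method`).
    """
    stack = np.asarray(wga_zstack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    contours: list[np.ndarray | None] = []
    pc_maps: list[np.ndarray] = []
    for plane in stack:
        if np.ptp(plane) <= 0:
            contours.append(None)
            pc_maps.append(np.zeros_like(plane))
            continue
        edge = (
            ndimage.gaussian_gradient_magnitude(plane, 1.0)
            if use_fallback
            else phase_congruency(plane, **pc_kwargs)
        )
        pc_maps.append(edge)
        if np.ptp(edge) <= 0:
            contours.append(None)
            continue
        try:
            pc_mask = edge > threshold_otsu(edge)
            int_mask = plane > threshold_otsu(plane)
        except ValueError:
            contours.append(None)
            continue
        mask = pc_mask & ndimage.binary_dilation(int_mask, iterations=2)
        if not mask.any():
            contours.append(None)
            continue
        ridge = skeletonize(mask)
        labels = cc_label(ridge, connectivity=2)
        if labels.max() == 0:
            contours.append(None)
            continue
        sizes = np.bincount(labels.ravel())[1:]
        comp = labels == (1 + int(np.argmax(sizes)))
        rc = np.column_stack(np.nonzero(comp)).astype(float)
        ordered = _order_ridge_pixels(rc)
        if ordered is None:
            contours.append(None)
            continue
        # pixel (r, c) centre -> (x, y) µm
        xy = np.column_stack(
            [(ordered[:, 1] + 0.5) * pixel_size_um, (ordered[:, 0] + 0.5) * pixel_size_um]
        )
        contours.append(xy)
    return MembraneMap(
        contours=contours,
        pc_maps=pc_maps,
        z_step=z_step,
        pixel_size_um=pixel_size_um,
        method="gradient_ridge" if use_fallback else "phase_congruency",
    )


# ---------------------------------------------------------------------------
# Radial-symmetry sub-pixel localization
# ---------------------------------------------------------------------------


def localize_radial_symmetry(
    roi: np.ndarray,
    pixel_size_um: float = 0.127,
    roi_origin: tuple[int, int] = (0, 0),
) -> tuple[float, float]:
    """Sub-pixel centre of a radially symmetric spot (µm).

    The centre is the least-squares point minimizing the gradient-
    magnitude-weighted perpendicular distance to the lines through each
    half-pixel grid point along its (3×3-smoothed) intensity-gradient
    direction. Gradients are taken along the two diagonals on the
    half-pixel midpoint grid.
    """
    img = np.asarray(roi, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("ROI must be 2D, at least 3x3")
    ny, nx = img.shape
    # midpoint grid coordinates relative to the ROI centre (pixel units)
    xm = np.arange(nx - 1) - (nx - 2) / 2.0
    ym = np.arange(ny - 1) - (ny - 2) / 2.0
    xm, ym = np.meshgrid(xm, ym)

    # diagonal derivatives (u: 45°, v: 135°)
    didu = img[:-1, 1:] - img[1:, :-1]
    didv = img[:-1, :-1] - img[1:, 1:]
    h = np.ones((3, 3)) / 9.0
    fdu = ndimage.convolve(didu, h, mode="nearest")
    fdv = ndimage.convolve(didv, h, mode="nearest")
    dmag2 = fdu**2 + fdv**2
    if not np.any(dmag2 > 0):
        raise ValueError("degenerate gradients: ROI has no intensity structure")

    # slope of the gradient line in (x, y): rotate the 45° frame back
    denom = fdu - fdv
    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(fdv + fdu) / denom
    m = np.where(np.isnan(m), 0.0, m)
    m = np.where(np.isinf(m), 1e9, m)
    b = ym - m * xm

    sdI2 = dmag2.sum()
    xc0 = (dmag2 * xm).sum() / sdI2
    yc0 = (dmag2 * ym).sum() / sdI2
    w = dmag2 / np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2 + 1e-12)

    wm2p1 = w / (m**2 + 1.0)
    sw = wm2p1.sum()
    smmw = (m**2 * wm2p1).sum()
    smw = (m * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    det = smw**2 - smmw * sw
    if abs(det) < 1e-12:
        raise ValueError("degenerate gradient geometry")
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det

    # ROI centre in full-frame pixel coordinates
    r0, c0 = roi_origin
    x_px = c0 + nx / 2.0 + xc
    y_px = r0 + ny / 2.0 + yc
    return x_px * pixel_size_um, y_px * pixel_size_um


# ---------------------------------------------------------------------------
# z-linking and classification
# ---------------------------------------------------------------------------


def link_z(
    per_plane_fits: Sequence[Sequence[SpotFit | tuple[float, float]]],
    z_step: float = 0.300,
    pixel_size_um: float = 0.127,
    min_planes: int = 3,
    tol_px: int = 1,
) -> list[QD3DLocation]:
    """Group per-plane localizations into 3D QD positions.

    Localizations whose positions round to the same XY pixel (within a
    Chebyshev tolerance of `tol_px`; tol_px=0 is the strict same-pixel
    rule) are grouped across planes; planes need not be contiguous, so
    a blink-induced missing plane does not split a QD. Groups seen in
    fewer than `min_planes` planes are discarded. x, y are the means of
    the member localizations and z the mean member-plane z.
    """
    items = []  # (plane, px_col, px_row, x_um, y_um)
    for j, fits in enumerate(per_plane_fits):
        for f in fits:
            if isinstance(f, SpotFit):
                x, y = f.x_um, f.y_um
            else:
                x, y = f
            items.append((j, int(x / pixel_size_um), int(y / pixel_size_um), x, y))
    n = len(items)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_pixel: dict[tuple[int, int], list[int]] = {}
    for i, it in enumerate(items):
        by_pixel.setdefault((it[1], it[2]), []).append(i)
    for (pc, pr), idxs in by_pixel.items():
        for dc in range(-tol_px, tol_px + 1):
            for dr in range(-tol_px, tol_px + 1):
                other = by_pixel.get((pc + dc, pr + dr))
                if other:
                    for a in idxs:
                        for b in other:
                            union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out = []
    n_discarded = 0
    for idxs in groups.values():
        planes = sorted({items[i][0] for i in idxs})
        if len(planes) < min_planes:
            n_discarded += len(idxs)
            continue
        xs = np.mean([items[i][3] for i in idxs])
        ys = np.mean([items[i][4] for i in idxs])
        zs = float(np.mean(planes)) * z_step
        out.append(
            QD3DLocation(
                x_um=float(xs),
                y_um=float(ys),
                z_um=zs,
                n_planes=len(planes),
                planes=tuple(planes),
            )
        )
    out.sort(key=lambda q: (q.z_um, q.y_um, q.x_um))
    return out


def classify_location(
    qd: QD3DLocation, membrane: MembraneMap, d_mem: float = D_MEM_DEFAULT_UM
) -> QD3DLocation:
    """Label a QD membrane / internal / external by signed membrane distance.

    dist_membrane is the Euclidean distance from (x, y) to the contour
    of the z-plane nearest qd.z, negative inside the contour (even-odd
    rule). label = membrane if |dist| <= d_mem, else internal when
    inside, external when outside; "unresolved" when the nearest plane
    has no contour.
    """
    j = membrane.nearest_plane(qd.z_um)
    contour = membrane.contours[j]
    if contour is None:
        return replace(qd, label="unresolved", dist_membrane=np.nan)
    ring = LinearRing(contour)
    poly = Polygon(contour)
    pt = Point(qd.x_um, qd.y_um)
    d = pt.distance(ring)
    signed = -d if poly.contains(pt) else d
    if abs(signed) <= d_mem:
        lab = "membrane"
    elif signed < 0:
        lab = "internal"
    else:
        lab = "external"
    return replace(qd, label=lab, dist_membrane=float(signed))


def internalization_fraction(qds: Sequence[QD3DLocation]) -> dict:
    """Fraction internal of (internal + membrane); others counted aside."""
    if not qds:
        raise ValueError("need at least one labeled QD")
    counts = {"internal": 0, "membrane": 0, "external": 0, "unresolved": 0}
    for q in qds:
        counts[q.label] = counts.get(q.label, 0) + 1
    denom = counts["internal"] + counts["membrane"]
    frac = counts["internal"] / denom if denom > 0 else np.nan
    return {"fraction_internal": frac, "defined": denom > 0, **counts}
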