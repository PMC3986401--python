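"""Spot detection and sub-pixel localization on calibrated photon frames.

Pipeline per frame: (1) convert raw camera units to Poisson-distributed
photon counts using the camera offset and gain; (2) find candidate spots
as local maxima of a difference-of-Gaussians filtered frame; (3) fit
each candidate ROI with a pixel-integrated 2D Gaussian by Poisson
maximum likelihood (Newton updates, CRLB from the Fisher information);
(4) keep fits that pass an intensity threshold and a log-likelihood
ratio goodness-of-fit test against the saturated Poisson model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import chi2

from ._gauss import (
    pixel_response_1d,
    pixel_response_1d_d1,
    pixel_response_1d_d2,
)
from .synthetic_data import CameraModel

DEFAULT_ROI_HALF = 3  # 7x7 ROI
DEFAULT_LLR_PVALUE = 1e-3


@dataclass
class PhotonFrame:
    """A camera frame calibrated to photon counts."""

    counts: np.ndarray
    index: int = 0
    pixel_size_um: float = 0.127


@dataclass
class SpotFit:
    """One sub-pixel localization with photometry and fit statistics."""

    x_um: float
    y_um: float
    photons: float
    background: float
    sigma_fit: float
    loglik: float
    llr: float
    pvalue: float
    crlb_xy_um: float
    accepted: bool = False
    converged: bool = True
    frame: int = 0


def calibrate(
    raw_frame: np.ndarray, camera: CameraModel, frame_index: int = 0
) -> PhotonFrame:
    """(raw − offset) / gain, elementwise: raw ADU to photon counts."""
    raw = np.asarray(raw_frame, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2D frame")
    return PhotonFrame(
        counts=(raw - camera.offset) / camera.gain,
        index=frame_index,
        pixel_size_um=camera.pixel_size,
    )


def _counts(frame: PhotonFrame | np.ndarray) -> np.ndarray:
    return frame.counts if isinstance(frame, PhotonFrame) else np.asarray(frame, float)


def find_candidates(
    frame: PhotonFrame | np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 2.0,
    threshold: float | None = None,
    roi_half: int = DEFAULT_ROI_HALF,
) -> list[tuple[int, int]]:
    """Candidate spot pixels from a difference-of-Gaussians filter.

    Local maxima of (G_small − G_large) ∗ frame above `threshold`
    (default: 4 × robust MAD-based sigma of the filtered frame),
    excluding a half-ROI border. Candidates closer than one ROI width
    keep only the brighter one (ties: lower row, then column).
    """
    if sigma_small >= sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    img = _counts(frame)
    if min(img.shape) < 2 * roi_half + 1:
        raise ValueError("frame smaller than filter support")
    dog = ndimage.gaussian_filter(img, sigma_small) - ndimage.gaussian_filter(
        img, sigma_large
    )
    if threshold is None:
        mad = np.median(np.abs(dog - np.median(dog)))
        threshold = 4.0 * mad / 0.67448975
        if threshold <= 0:
            threshold = np.inf
    elif threshold <= 0:
        raise ValueError("threshold must be > 0")

    local_max = dog == ndimage.maximum_filter(dog, size=3)
    mask = local_max & (dog > threshold)
    mask[:roi_half, :] = mask[-roi_half:, :] = False
    mask[:, :roi_half] = mask[:, -roi_half:] = False
    cand = [(int(r), int(c)) for r, c in zip(*np.nonzero(mask))]

    # proximity suppression: keep the brighter of any pair within one ROI width
    width = 2 * roi_half + 1
    order = sorted(cand, key=lambda rc: (-dog[rc], rc[0], rc[1]))
    kept: list[tuple[int, int]] = []
    for rc in order:
        if all(max(abs(rc[0] - k[0]), abs(rc[1] - k[1])) >= width for k in kept):
            kept.append(rc)
    kept.sort()
    return kept


def _model_and_derivs(
    theta: np.ndarray, rows: np.ndarray, cols: np.ndarray, sigma: float
):
    """Poisson mean mu and first/second derivatives w.r.t. (x, y, N, bg)."""
    x, y, N, bg = theta
    ex = pixel_response_1d(cols, x, sigma)
    ey = pixel_response_1d(rows, y, sigma)
    dex = pixel_response_1d_d1(cols, x, sigma)
    dey = pixel_response_1d_d1(rows, y, sigma)
    d2ex = pixel_response_1d_d2(cols, x, sigma)
    d2ey = pixel_response_1d_d2(rows, y, sigma)
    psf = np.outer(ey, ex)
    mu = bg + N * psf
    d1 = [
        N * np.outer(ey, dex),  # d mu / dx
        N * np.outer(dey, ex),  # d mu / dy
        psf,  # d mu / dN
        np.ones_like(psf),  # d mu / d bg
    ]
    d2 = [
        N * np.outer(ey, d2ex),
        N * np.outer(d2ey, ex),
        np.zeros_like(psf),
        np.zeros_like(psf),
    ]
    return mu, d1, d2


def _poisson_loglik(data: np.ndarray, mu: np.ndarray) -> float:
    """Sum d·ln(mu) − mu (the d! term cancels in ratios)."""
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(data > 0, data * np.log(mu), 0.0)
    return float(np.sum(term - mu))


def fit_spot_mle(
    roi: np.ndarray,
    psf_sigma: float,
    init: tuple[float, float] | None = None,
    pixel_size_um: float = 0.127,
    roi_origin: tuple[int, int] = (0, 0),
    max_iter: int = 30,
    tol_px: float = 1e-4,
    frame_index: int = 0,
) -> SpotFit:
    """Poisson maximum-likelihood fit of one pixel-integrated Gaussian.

    Maximizes sum_i (d_i ln mu_i − mu_i) with mu_i = bg + N · PSF_i over
    (x, y, N, bg) by damped per-parameter Newton updates, capped at
    `max_iter` iterations; converged when the position update falls
    below `tol_px`. The theoretical localization precision crlb_xy_um
    is the Fisher-information bound of the same model. Positions are
    reported in µm using `roi_origin` (top-left pixel of the ROI in
    the full frame) and the package pixel-centre convention.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] % 2 == 0 or roi.shape[1] % 2 == 0:
        raise ValueError("ROI must be 2D and odd-sized")
    if not np.any(roi > 0):
        raise ValueError("all-zero ROI")
    data = np.maximum(roi, 0.0)
    nr, nc = roi.shape
    rows = np.arange(nr, dtype=float)
    cols = np.arange(nc, dtype=float)

    # initialization: border median background, centroid of excess signal
    border = np.concatenate([data[0], data[-1], data[1:-1, 0], data[1:-1, -1]])
    bg0 = max(float(np.median(border)), 0.01)
    excess = np.maximum(data - bg0, 0.0)
    n0 = max(float(excess.sum()), 1.0)
    if init is None:
        if excess.sum() > 0:
            y0 = float((excess.sum(axis=1) * (rows + 0.5)).sum() / excess.sum())
            x0 = float((excess.sum(axis=0) * (cols + 0.5)).sum() / excess.sum())
        else:
            x0, y0 = nc / 2.0, nr / 2.0
    else:
        x0, y0 = init
    theta = np.array([x0, y0, n0, bg0], dtype=float)

    converged = False
    for _ in range(max_iter):
        mu, d1, d2 = _model_and_derivs(theta, rows, cols, psf_sigma)
        mu = np.maximum(mu, 1e-12)
        ratio = data / mu
        step = np.zeros(4)
        for k in range(4):
            g = np.sum((ratio - 1.0) * d1[k])
            h = np.sum((ratio - 1.0) * d2[k] - ratio / mu * d1[k] ** 2)
            if h >= 0 or not np.isfinite(h):
                h = -np.sum(d1[k] ** 2 / mu) - 1e-12
            step[k] = -g / h
        # damp position moves to 1 px, keep N and bg positive
        step[:2] = np.clip(step[:2], -1.0, 1.0)
        theta = theta + step
        theta[2] = max(theta[2], 1e-3)
        theta[3] = max(theta[3], 1e-6)
        theta[0] = np.clip(theta[0], 0.0, nc)
        theta[1] = np.clip(theta[1], 0.0, nr)
        if np.hypot(step[0], step[1]) < tol_px:
            converged = True
            break

    mu, d1, _ = _model_and_derivs(theta, rows, cols, psf_sigma)
    mu = np.maximum(mu, 1e-12)
    loglik = _poisson_loglik(data, mu)
    ll_sat = _poisson_loglik(data, np.maximum(data, 1e-12))
    llr = max(0.0, 2.0 * (ll_sat - loglik))
    dof = roi.size - 4
    pvalue = float(chi2.sf(llr, dof))

    # CRLB from the Fisher information of the fitted model
    fisher = np.empty((4, 4))
    for a in range(4):
        for b in range(a, 4):
            fisher[a, b] = fisher[b, a] = np.sum(d1[a] * d1[b] / mu)
    try:
        cov = np.linalg.inv(fisher)
        crlb_px = float(np.sqrt(max(0.0, (cov[0, 0] + cov[1, 1]) / 2.0)))
    except np.linalg.LinAlgError:
        crlb_px = np.nan

    r0, c0 = roi_origin
    return SpotFit(
        x_um=(c0 + theta[0]) * pixel_size_um,
        y_um=(r0 + theta[1]) * pixel_size_um,
        photons=float(theta[2]),
        background=float(theta[3]),
        sigma_fit=float(psf_sigma),
        loglik=loglik,
        llr=llr,
        pvalue=pvalue,
        crlb_xy_um=crlb_px * pixel_size_um,
        accepted=False,
        converged=converged,
        frame=frame_index,
    )


def llr_filter(
    fits: Sequence[SpotFit],
    intensity_min: float = 100.0,
    llr_pvalue_max: float = DEFAULT_LLR_PVALUE,
) -> list[SpotFit]:
    """Keep fits bright enough and consistent with the PSF shape.

    A fit is accepted iff photons >= intensity_min and the chi-squared
    upper-tail p-value of its log-likelihood ratio statistic (dof =
    n_pixels − 4) is >= llr_pvalue_max, i.e. the PSF model is not
    rejected at that level. Sets the accepted flag on every fit and
    returns the accepted ones.
    """
    out = []
    for f in fits:
        f.accepted = bool(
            f.photons >= intensity_min and f.pvalue >= llr_pvalue_max and f.converged
        )
        if f.accepted:
            out.append(f)
    return out


def detect_frame(
    raw_frame: np.ndarray,
    camera: CameraModel,
    psf_sigma: float = 1.2,
    frame_index: int = 0,
    sigma_small: float = 1.0,
    sigma_large: float = 2.0,
    threshold: float | None = None,
    roi_half: int = DEFAULT_ROI_HALF,
    intensity_min: float = 100.0,
    llr_pvalue_max: float = DEFAULT_LLR_PVALUE,
) -> list[SpotFit]:
    """calibrate → find_candidates → fit_spot_mle → llr_filter for one frame."""
    frame = calibrate(raw_frame, camera, frame_index)
    cands = find_candidates(frame, sigma_small, sigma_large, threshold, roi_half)
    fits = []
    for r, c in cands:
        roi = frame.counts[r - roi_half : r + roi_half + 1, c - roi_half : c + roi_half + 1]
        try:
            fit = fit_spot_mle(
                roi,
                psf_sigma,
                pixel_size_um=camera.pixel_size,
                roi_origin=(r - roi_half, c - roi_half),
                frame_index=frame_index,
            )
        except ValueError:
            continue
        fits.append(fit)
    return llr_filter(fits, intensity_min, llr_pvalue_max)
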