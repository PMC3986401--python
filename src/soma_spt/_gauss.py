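"""Pixel-integrated 2D Gaussian point-spread function.

Shared numeric primitive: the emission of a point source imaged on a pixel
grid is modelled as a symmetric 2D Gaussian integrated over each pixel
(difference of error functions along each axis).

Coordinate convention (used package-wide): 0-based pixel indices; the
continuous coordinate of the centre of pixel (row r, col c) is
(x, y) = ((c + 0.5) * p, (r + 0.5) * p) with p the pixel size in µm.
In pixel units, a position x_px measured from the left edge of pixel 0
places the centre of pixel c at c + 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


def edge_integrals(edges: np.ndarray, mu_px: float, sigma_px: float) -> np.ndarray:
    """CDF of a 1D Gaussian evaluated at pixel edges."""
    return 0.5 * (1.0 + erf((edges - mu_px) / (_SQRT2 * sigma_px)))


def pixel_response_1d(idx: np.ndarray, mu_px: float, sigma_px: float) -> np.ndarray:
    """Fraction of a unit Gaussian at mu_px falling in pixels [idx, idx+1)."""
    a = erf((idx + 1.0 - mu_px) / (_SQRT2 * sigma_px))
    b = erf((idx - mu_px) / (_SQRT2 * sigma_px))
    return 0.5 * (a - b)


def pixel_response_1d_d1(idx: np.ndarray, mu_px: float, sigma_px: float) -> np.ndarray:
    """d/d mu of pixel_response_1d."""
    g1 = np.exp(-((idx - mu_px) ** 2) / (2.0 * sigma_px**2))
    g2 = np.exp(-((idx + 1.0 - mu_px) ** 2) / (2.0 * sigma_px**2))
    return (g1 - g2) / (_SQRT2PI * sigma_px)


def pixel_response_1d_d2(idx: np.ndarray, mu_px: float, sigma_px: float) -> np.ndarray:
    """d²/d mu² of pixel_response_1d."""
    u1 = idx - mu_px
    u2 = idx + 1.0 - mu_px
    g1 = u1 * np.exp(-(u1**2) / (2.0 * sigma_px**2))
    g2 = u2 * np.exp(-(u2**2) / (2.0 * sigma_px**2))
    return (g1 - g2) / (_SQRT2PI * sigma_px**3)


def gaussian_spot(
    shape: tuple[int, int], x_px: float, y_px: float, sigma_px: float
) -> np.ndarray:
    """Unit-integral pixel-integrated Gaussian on an image of `shape`.

    x_px runs along columns, y_px along rows (both measured from the
    image origin at the outer corner of pixel (0, 0)).
    """
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    ey = pixel_response_1d(rows, y_px, sigma_px)
    ex = pixel_response_1d(cols, x_px, sigma_px)
    return np.outer(ey, ex)
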