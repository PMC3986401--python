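"""Trajectory linking across frames and rigid two-channel alignment.

Linking follows the two-stage cost-matrix scheme used throughout the
single-particle-tracking literature: (1) frame-to-frame assignment with
squared-displacement link costs and a birth/death alternative cost,
solved optimally per frame pair; (2) gap closing that joins track
segment ends to later segment starts across blinking-induced gaps,
solved as a second global assignment. Channel registration estimates a
rigid sub-pixel shift by maximizing the normalized cross-correlation of
the two channels' sum projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve

from .detection import SpotFit

_BIG = 1e12


@dataclass
class ChannelShift:
    """Rigid sub-pixel shift of channel B relative to channel A (pixels)."""

    dx: float
    dy: float


@dataclass
class Trajectory:
    """Time-ordered localizations of one particle.

    Bridged (gap-closed) frames are included with linearly interpolated
    positions and gap=True; they carry no measured localization.
    """

    particle_id: int
    frames: np.ndarray  # (n,), int, strictly increasing
    times: np.ndarray  # (n,), s
    xy: np.ndarray  # (n, 2), µm
    photons: np.ndarray  # (n,), NaN on gap frames
    gap: np.ndarray  # (n,), bool

    def __post_init__(self) -> None:
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_observed(self) -> int:
        return int((~self.gap).sum())


def _quadratic_peak(c: np.ndarray, i: int) -> float:
    """Sub-pixel peak offset from a 3-point quadratic fit along one axis."""
    y0, y1, y2 = c[i - 1], c[i], c[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return 0.5 * (y0 - y2) / denom


def align_channels(stack_a: np.ndarray, stack_b: np.ndarray) -> ChannelShift:
    """Shift of stack_b relative to stack_a from sum projections.

    Maximizes the (mean-subtracted) cross-correlation of the two sum
    projections, refined to sub-pixel by quadratic interpolation around
    the correlation peak. The shift magnitude is restricted to < 1/4 of
    the image width; a peak on the search border raises an error.
    """
    a = np.asarray(stack_a, dtype=float)
    b = np.asarray(stack_b, dtype=float)
    pa = a.sum(axis=0) if a.ndim == 3 else a
    pb = b.sum(axis=0) if b.ndim == 3 else b
    if pa.shape != pb.shape:
        raise ValueError("channel projections must have equal shape")
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    corr = fftconvolve(pb, pa[::-1, ::-1], mode="full")
    h, w = pa.shape
    # correlation lag (0,0) sits at index (h-1, w-1)
    max_lag_r, max_lag_c = h // 4, w // 4
    rs = slice(h - 1 - max_lag_r, h + max_lag_r)
    cs = slice(w - 1 - max_lag_c, w + max_lag_c)
    win = corr[rs, cs]
    idx = np.unravel_index(np.argmax(win), win.shape)
    if idx[0] in (0, win.shape[0] - 1) or idx[1] in (0, win.shape[1] - 1):
        raise ValueError("correlation peak at search border; channels misaligned?")
    dr = idx[0] - max_lag_r + _quadratic_peak(win[:, idx[1]], idx[0])
    dc = idx[1] - max_lag_c + _quadratic_peak(win[idx[0], :], idx[1])
    return ChannelShift(dx=float(dc), dy=float(dr))


# ---------------------------------------------------------------------------
# Two-stage linking
# ---------------------------------------------------------------------------


def _pad_assignment(cost_links: np.ndarray, alt_cost: float) -> list[tuple[int, int]]:
    """Solve the padded (n+m)² assignment; return accepted (i, j) links.

    Top-left: link costs (np.inf forbidden). Diagonal top-right /
    bottom-left blocks: the birth/death alternative. Bottom-right:
    zeros (auxiliary).
    """
    n, m = cost_links.shape
    size = n + m
    c = np.full((size, size), _BIG)
    tl = np.where(np.isfinite(cost_links), cost_links, _BIG)
    c[:n, :m] = tl
    for i in range(n):
        c[i, m + i] = alt_cost
    for j in range(m):
        c[n + j, j] = alt_cost
    c[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(c)
    return [
        (int(r), int(col))
        for r, col in zip(rows, cols)
        if r < n and col < m and np.isfinite(cost_links[r, col])
    ]


def link_trajectories(
    per_frame_fits: Sequence[Sequence[SpotFit | tuple[float, float]]],
    dt: float,
    max_disp: float = 0.64,
    max_gap: int = 5,
) -> list[Trajectory]:
    """Link per-frame localizations into gap-tolerant trajectories.

    Stage 1 links consecutive frames with cost = squared displacement
    (links beyond max_disp µm forbidden), birth/death alternative
    (1.05·max_disp)²; stage 2 joins segment ends to later segment starts
    with gap <= max_gap dark frames, cost = squared displacement
    (forbidden beyond max_disp per elapsed frame). Both stages solve the
    assignment exactly. Unlinked fits become singleton trajectories;
    particle ids follow segment creation order (first frame, then
    position), so ties break toward the lower id.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    def _xy(f):
        return (f.x_um, f.y_um) if isinstance(f, SpotFit) else (float(f[0]), float(f[1]))

    def _photons(f):
        return f.photons if isinstance(f, SpotFit) else np.nan

    n_frames = len(per_frame_fits)
    alt = (1.05 * max_disp) ** 2

    # stage 1: frame-to-frame segments
    segments: list[dict] = []  # frames, xy, photons
    open_segs: list[int] = []  # segment index ending at previous frame
    for f in range(n_frames):
        fits = list(per_frame_fits[f])
        coords = np.array([_xy(x) for x in fits]) if fits else np.empty((0, 2))
        if f == 0 or not open_segs:
            linked_targets = {}
        else:
            prev = np.array([segments[s]["xy"][-1] for s in open_segs])
            if len(coords):
                d2 = ((prev[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
                cost = np.where(d2 <= max_disp**2, d2, np.inf)
                links = _pad_assignment(cost, alt)
            else:
                links = []
            linked_targets = {j: open_segs[i] for i, j in links}
        next_open = []
        for j, fit in enumerate(fits):
            if j in linked_targets:
                s = linked_targets[j]
            else:
                segments.append({"frames": [], "xy": [], "photons": []})
                s = len(segments) - 1
            segments[s]["frames"].append(f)
            segments[s]["xy"].append(coords[j])
            segments[s]["photons"].append(_photons(fit))
            next_open.append(s)
        open_segs = next_open

    # stage 2: gap closing (ends -> later starts, 1 <= dark frames <= max_gap)
    ends = [(s, seg["frames"][-1], np.asarray(seg["xy"][-1])) for s, seg in enumerate(segments)]
    starts = [(s, seg["frames"][0], np.asarray(seg["xy"][0])) for s, seg in enumerate(segments)]
    if max_gap > 0 and len(segments) > 1:
        cost = np.full((len(ends), len(starts)), np.inf)
        for a, (sa, ea, pa) in enumerate(ends):
            for b, (sb, fb, pb) in enumerate(starts):
                if sa == sb:
                    continue
                gap = fb - ea - 1
                if gap < 1 or gap > max_gap:
                    continue
                d = np.linalg.norm(pa - pb)
                if d <= max_disp * (gap + 1):
                    cost[a, b] = d**2
        if np.isfinite(cost).any():
            for a, b in _pad_assignment(cost, alt):
                segments[ends[a][0]].setdefault("next", starts[b][0])

    # merge chains
    has_prev = {seg.get("next") for seg in segments if "next" in seg}
    trajectories = []
    pid = 0
    for s, seg in enumerate(segments):
        if s in has_prev:
            continue
        frames, xy, photons, gapf = [], [], [], []
        cur = s
        while True:
            c = segments[cur]
            if frames:  # bridge the gap with interpolated positions
                f0, f1 = frames[-1], c["frames"][0]
                p0, p1 = np.asarray(xy[-1]), np.asarray(c["xy"][0])
                for g in range(f0 + 1, f1):
                    t = (g - f0) / (f1 - f0)
                    frames.append(g)
                    xy.append(p0 + t * (p1 - p0))
                    photons.append(np.nan)
                    gapf.append(True)
            frames.extend(c["frames"])
            xy.extend(c["xy"])
            photons.extend(c["photons"])
            gapf.extend([False] * len(c["frames"]))
            if "next" not in c:
                break
            cur = c["next"]
        fr = np.asarray(frames, dtype=int)
        trajectories.append(
            Trajectory(
                particle_id=pid,
                frames=fr,
                times=fr * dt,
                xy=np.asarray(xy, dtype=float),
                photons=np.asarray(photons, dtype=float),
                gap=np.asarray(gapf, dtype=bool),
            )
        )
        pid += 1
    return trajectories
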