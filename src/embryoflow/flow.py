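"""Sparse optic flow: corner detection and pyramidal Lucas-Kanade tracking.

Corner features (locations with strong intensity gradients in two directions)
are detected with the Shi-Tomasi minimum-eigenvalue criterion and then followed
from one frame to the next by iterative, coarse-to-fine least-squares
refinement of a local translation model, giving sub-pixel displacements.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import pyramid_reduce
from skimage.util import img_as_float


@dataclass
class FeatureTrack:
    """Matched feature positions between two consecutive frames.

    ``old``/``new`` are (n, 2) arrays of (x, y) pixel positions (x rightward,
    y downward, origin top-left); ``ok`` flags pairs whose track survived
    (converged, stayed in frame, low residual).  Only ok pairs are used
    downstream.
    """

    old: np.ndarray
    new: np.ndarray
    ok: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.old = np.atleast_2d(np.asarray(self.old, dtype=float))
        self.new = np.atleast_2d(np.asarray(self.new, dtype=float))
        self.ok = np.asarray(self.ok, dtype=bool)
        if not (len(self.old) == len(self.new) == len(self.ok)):
            raise ValueError("old, new and ok must have equal length")


def detect_corners(
    frame: np.ndarray,
    max_features: int = 400,
    quality: float = 0.01,
    min_distance_px: float = 5,
) -> np.ndarray:
    """Detect up to ``max_features`` Shi-Tomasi corners, strongest first.

    ``quality`` is the minimum corner response relative to the strongest
    corner in the frame; returned points are at least ``min_distance_px``
    apart.  Returns an (n, 2) float array of (x, y) positions; a constant
    (gradient-free) frame yields an empty set.
    """
    if not 0 < quality <= 1:
        raise ValueError("quality must be in (0, 1]")
    img = img_as_float(np.asarray(frame))
    if img.size == 0:
        return np.empty((0, 2), dtype=float)
    if np.ptp(img) == 0:
        return np.empty((0, 2), dtype=float)
    response = corner_shi_tomasi(img, sigma=1)
    peaks = corner_peaks(
        response,
        min_distance=max(1, int(round(min_distance_px))),
        threshold_rel=quality,
        num_peaks=max_features,
    )
    if peaks.size == 0:
        return np.empty((0, 2), dtype=float)
    order = np.argsort(response[peaks[:, 0], peaks[:, 1]])[::-1]
    peaks = peaks[order]
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _sample_patches(img: np.ndarray, centers_xy: np.ndarray, half: int) -> np.ndarray:
    """Bilinear patches of side 2*half+1 around sub-pixel centers, (n, w, w)."""
    offs = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    rows = centers_xy[:, 1, None, None] + oy[None]
    cols = centers_xy[:, 0, None, None] + ox[None]
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _pyramids(img: np.ndarray, levels: int, min_dim: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) // 2 < min_dim:
            break
        pyr.append(pyramid_reduce(pyr[-1], downscale=2, channel_axis=None))
    return pyr


def track_features(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    points: np.ndarray,
    window_px: int = 15,
    max_iterations: int = 30,
    pyramid_levels: int = 3,
    frame_index: int = 0,
    convergence_px: float = 0.01,
    min_eigenvalue: float = 1e-5,
    max_residual: float = 0.08,
) -> FeatureTrack:
    """Track ``points`` from frame_a to frame_b (pyramidal Lucas-Kanade).

    Displacements are refined coarse-to-fine; at each pyramid level the local
    translation solving ``G d = b`` (G the gradient structure tensor of the
    frame_a window, b the image-difference moment) is iterated until the
    update falls below ``convergence_px``.  A pair is flagged not-ok when its
    structure tensor is near-singular, the point leaves the frame, or the
    final window residual exceeds ``max_residual`` (intensity units in [0, 1]).
    """
    a = img_as_float(np.asarray(frame_a))
    b = img_as_float(np.asarray(frame_b))
    if a.shape != b.shape:
        raise ValueError("frames must share dimensions")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 0:
        return FeatureTrack(np.empty((0, 2)), np.empty((0, 2)), np.empty(0, bool), frame_index)

    half = max(1, int(window_px) // 2)
    w2 = (2 * half + 1) ** 2
    pyr_a = _pyramids(a, pyramid_levels, 2 * half + 3)
    pyr_b = _pyramids(b, pyramid_levels, 2 * half + 3)

    d = np.zeros((n, 2))  # displacement estimate at current level scale
    ok = np.ones(n, dtype=bool)
    residual = np.zeros(n)
    for level in range(len(pyr_a) - 1, -1, -1):
        scale = 2.0**level
        al, bl = pyr_a[level], pyr_b[level]
        pl = pts / scale
        gy, gx = np.gradient(al)
        pa = _sample_patches(al, pl, half)
        pgx = _sample_patches(gx, pl, half)
        pgy = _sample_patches(gy, pl, half)
        gxx = (pgx * pgx).sum(axis=(1, 2))
        gxy = (pgx * pgy).sum(axis=(1, 2))
        gyy = (pgy * pgy).sum(axis=(1, 2))
        det = gxx * gyy - gxy * gxy
        tr = gxx + gyy
        min_eig = (tr - np.sqrt(np.maximum(tr * tr - 4 * det, 0.0))) / 2.0 / w2
        solvable = (det > 1e-12) & (min_eig >= min_eigenvalue)
        ok &= solvable

        active = ok.copy()
        for _ in range(max_iterations):
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            pb = _sample_patches(bl, pl[idx] + d[idx], half)
            diff = pa[idx] - pb
            bx = (diff * pgx[idx]).sum(axis=(1, 2))
            by = (diff * pgy[idx]).sum(axis=(1, 2))
            inv_det = 1.0 / det[idx]
            dx = (gyy[idx] * bx - gxy[idx] * by) * inv_det
            dy = (gxx[idx] * by - gxy[idx] * bx) * inv_det
            d[idx, 0] += dx
            d[idx, 1] += dy
            still = np.hypot(dx, dy) >= convergence_px
            active[idx] = still
        if level > 0:
            d *= 2.0  # propagate estimate to the next finer level

    # final residual and bounds check at full resolution
    idx = np.nonzero(ok)[0]
    if idx.size:
        pb = _sample_patches(b, pts[idx] + d[idx], half)
        pa0 = _sample_patches(a, pts[idx], half)
        residual[idx] = np.abs(pa0 - pb).mean(axis=(1, 2))
    new = pts + d
    h, w = a.shape
    in_bounds = (
        (new[:, 0] >= 0) & (new[:, 0] <= w - 1) & (new[:, 1] >= 0) & (new[:, 1] <= h - 1)
    )
    ok = ok & in_bounds & (residual <= max_residual)
    return FeatureTrack(pts, new, ok, frame_index)
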