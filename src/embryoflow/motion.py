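"""Frame-to-frame motion measures from tracked features.

Each consecutive frame pair is reduced to four measures: summed clockwise and
anticlockwise rotation of the tracked features about their centroid
(``pos_angle``, ``neg_angle``, radians, both stored as magnitudes), and the
displacement of the feature centre of mass in polar coordinates (``rho`` in
pixels, ``theta`` in radians).  "Clockwise" means a positive wrapped angle
difference in image coordinates (x right, y down) — the apparent sense on
screen.  Sums (not means) are used so that large-bodied motions involving many
features produce proportionally larger peaks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow import FeatureTrack, detect_corners, track_features

logger = logging.getLogger(__name__)

MEASURES = ("pos_angle", "neg_angle", "rho", "theta")

#: displacement below which theta is defined as 0 (polar angle undefined)
RHO_TOL = 1e-9


@dataclass
class FrameSequence:
    """Ordered grayscale frames with frame rate and recording identity."""

    frames: list[np.ndarray]
    frame_rate_hz: float = 15.0
    recording_id: str = ""
    embryo_id: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share identical dimensions")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MotionFrame:
    """The four motion measures for one frame pair."""

    pos_angle: float
    neg_angle: float
    rho: float
    theta: float
    gap: bool = False  # too few surviving tracks; measures zeroed


@dataclass
class MotionRecord:
    """Per-frame-pair motion series for one recording."""

    pos_angle: np.ndarray
    neg_angle: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    frame_rate_hz: float = 15.0
    recording_id: str = ""
    embryo_id: str = ""
    cycle_index: int = 0
    gap_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, m), dtype=float) for m in MEASURES]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all four measure series must share length")
        for m, a in zip(MEASURES, arrays):
            setattr(self, m, a)

    def __len__(self) -> int:
        return len(self.pos_angle)

    @property
    def activity(self) -> np.ndarray:
        """pos + neg rotation magnitude; a tail flick shows as a large peak."""
        return self.pos_angle + self.neg_angle

    def series(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        return getattr(self, measure)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "pos_angle": self.pos_angle,
                "neg_angle": self.neg_angle,
                "rho": self.rho,
                "theta": self.theta,
            }
        )


@dataclass
class TrackingParams:
    """Configuration of the corner detector, tracker and measure reduction."""

    max_features: int = 400
    quality: float = 0.01
    min_distance_px: float = 5
    window_px: int = 15
    pyramid_levels: int = 3
    max_iterations: int = 30
    min_tracked: int = 3
    redetect_fraction: float = 0.5
    outlier_mad_factor: float = 5.0
    outlier_floor_px: float = 12.0


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = (np.asarray(phi, dtype=float) + np.pi) % (2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def compute_motion_measures(
    track: FeatureTrack,
    min_tracked: int = 3,
    outlier_mad_factor: float = 5.0,
    outlier_floor_px: float = 12.0,
) -> MotionFrame:
    """Reduce one frame pair's tracks to the four motion measures.

    Unreliable displacements are removed first: pairs whose displacement
    magnitude exceeds max(median + ``outlier_mad_factor``*MAD,
    ``outlier_floor_px``) are dropped.  The absolute floor keeps genuine
    burst motion (a flicking tail among a static body gives a bimodal
    displacement distribution with near-zero median and MAD).

    With fewer than ``min_tracked`` surviving pairs all measures are zero and
    the frame is flagged as a gap.
    """
    old = track.old[track.ok]
    new = track.new[track.ok]
    if len(old) < min_tracked:
        return MotionFrame(0.0, 0.0, 0.0, 0.0, gap=True)

    disp = new - old
    mag = np.hypot(disp[:, 0], disp[:, 1])
    med = np.median(mag)
    mad = np.median(np.abs(mag - med))
    cutoff = max(med + outlier_mad_factor * mad, outlier_floor_px)
    keep = mag <= cutoff
    old, new = old[keep], new[keep]
    if len(old) < min_tracked:
        return MotionFrame(0.0, 0.0, 0.0, 0.0, gap=True)

    c_old = old.mean(axis=0)
    c_new = new.mean(axis=0)
    r_old = old - c_old
    r_new = new - c_new
    # rotation is undefined for a point sitting exactly on the centroid
    nz = (np.hypot(r_old[:, 0], r_old[:, 1]) > 1e-12) & (
        np.hypot(r_new[:, 0], r_new[:, 1]) > 1e-12
    )
    phi = _wrap_angle(
        np.arctan2(r_new[nz, 1], r_new[nz, 0]) - np.arctan2(r_old[nz, 1], r_old[nz, 0])
    )
    pos = float(np.maximum(phi, 0.0).sum())
    neg = float(np.maximum(-phi, 0.0).sum())
    delta = c_new - c_old
    rho = float(np.hypot(delta[0], delta[1]))
    theta = float(np.arctan2(delta[1], delta[0])) if rho >= RHO_TOL else 0.0
    return MotionFrame(pos, neg, rho, theta)


def extract_motion_record(
    seq: FrameSequence, params: TrackingParams | None = None
) -> MotionRecord:
    """Run detection + tracking over all consecutive frame pairs.

    Corners are detected on the first frame and carried forward as tracked
    positions; they are re-detected whenever the surviving tracks fall below
    ``redetect_fraction`` of the last detection count (or below
    ``min_tracked``).  Deterministic for a given input and configuration.
    """
    p = params or TrackingParams()
    frames = seq.frames
    pts = detect_corners(frames[0], p.max_features, p.quality, p.min_distance_px)
    target = max(len(pts), 1)
    out = {m: [] for m in MEASURES}
    gap_frames: list[int] = []
    n_redetect = 0
    for i in range(len(frames) - 1):
        if len(pts) < max(p.min_tracked, 1):
            pts = detect_corners(frames[i], p.max_features, p.quality, p.min_distance_px)
            target = max(len(pts), 1)
            n_redetect += 1
        if len(pts) == 0:
            mf = MotionFrame(0.0, 0.0, 0.0, 0.0, gap=True)
        else:
            track = track_features(
                frames[i],
                frames[i + 1],
                pts,
                window_px=p.window_px,
                max_iterations=p.max_iterations,
                pyramid_levels=p.pyramid_levels,
                frame_index=i,
            )
            mf = compute_motion_measures(
                track, p.min_tracked, p.outlier_mad_factor, p.outlier_floor_px
            )
            survivors = track.new[track.ok]
            if len(survivors) < p.redetect_fraction * target:
                pts = detect_corners(
                    frames[i + 1], p.max_features, p.quality, p.min_distance_px
                )
                target = max(len(pts), 1)
                n_redetect += 1
                logger.info("re-detected corners at frame %d (%d points)", i + 1, len(pts))
            else:
                pts = survivors
        if mf.gap:
            gap_frames.append(i)
        out["pos_angle"].append(mf.pos_angle)
        out["neg_angle"].append(mf.neg_angle)
        out["rho"].append(mf.rho)
        out["theta"].append(mf.theta)
    if gap_frames:
        logger.info("%d gap frames (too few tracks)", len(gap_frames))
    if n_redetect:
        logger.info("%d corner re-detections", n_redetect)
    return MotionRecord(
        pos_angle=np.array(out["pos_angle"]),
        neg_angle=np.array(out["neg_angle"]),
        rho=np.array(out["rho"]),
        theta=np.array(out["theta"]),
        frame_rate_hz=seq.frame_rate_hz,
        recording_id=seq.recording_id,
        embryo_id=seq.embryo_id,
        cycle_index=seq.cycle_index,
        gap_frames=gap_frames,
    )


def truncate_record(record: MotionRecord, length: int) -> MotionRecord:
    """Return a copy keeping the first ``length`` frame pairs."""
    return replace(
        record,
        pos_angle=record.pos_angle[:length].copy(),
        neg_angle=record.neg_angle[:length].copy(),
        rho=record.rho[:length].copy(),
        theta=record.theta[:length].copy(),
        gap_frames=[g for g in record.gap_frames if g < length],
    )
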