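"""Seeded generators of ground-truthed inputs at two levels.

Parametric motion records give the statistics modules known signal structure
without the vision stack; rendered frame sequences (a speckle-textured embryo
inside a circular chorion, with a flicking tail and a pulsing heart spot)
exercise the vision stack against pixel-level ground truth.

A recording emulates 30 s of a single embryo at 15 Hz: baseline tracking
jitter, brief tail-flick bursts at a controllable per-30-s rate, a periodic
heart-beat component and pixel noise.  A full experiment spans 15 embryos x
20 recording cycles over five exposure periods whose flick rates follow a
stimulant pulse-and-recovery time course, with lognormal between-embryo rate
heterogeneity so individuals differ in the strength of their response.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .design import PERIODS, validate_design
from .motion import FrameSequence, MotionRecord

#: Default per-period tail-flick rates (flicks per 30 s): baseline, first and
#: second exposure half, first and second recovery half.  They reproduce the
#: pulse-and-recovery time course of an acute low-dose ethanol exposure
#: (rise during exposure, overshoot decay below baseline in late recovery).
STUDY_PERIOD_RATES: dict[str, float] = {
    "pre": 2.68,
    "ethanol1": 3.5,  # onset is gradual: the first exposure half sits near baseline
    "ethanol2": 8.25,
    "recovery1": 3.87,
    "recovery2": 0.97,
}

#: Flick-vigor (amplitude) multiplier per period; flicks are more vigorous at
#: the exposure peak.
VIGOR_BY_PERIOD: dict[str, float] = {"ethanol2": 1.5}

#: Between-embryo lognormal rate-multiplier sigma.  Calibrated so that the
#: spread of per-embryo mean counts matches observed standard errors over 15
#: embryos (between-embryo CV of roughly 0.5-0.65 across periods).
EMBRYO_SIGMA = 0.5

#: Between-embryo lognormal flick-vigor sigma: embryos respond with markedly
#: different movement magnitudes, not just different rates.
VIGOR_SIGMA = 0.5


@dataclass
class SyntheticConfig:
    """Everything that determines one synthetic recording (seed included)."""

    seed: int = 0
    n_frames: int = 449
    fps: float = 15.0
    # behaviour
    flick_rate_per_30s: float = 2.68
    flick_duration_s: float = 0.3
    flick_amplitude: float = 1.0       # typical peak summed rotation, rad per frame pair
    flick_amplitude_sigma: float = 0.4  # lognormal per-event vigor jitter (0 = identical)
    flick_onsets_s: tuple[float, ...] | None = None  # scripted onsets override rate
    heart_rate_hz: float = 2.3
    heart_amplitude: float = 0.05      # rad per frame pair, peak-to-trough
    baseline_noise_sd: float = 0.01    # tracking-jitter scale of the record
    rho_burst_px: float = 2.0          # centre-of-mass shift during a flick
    # rendering geometry (pixels)
    frame_shape: tuple[int, int] = (256, 256)
    chorion_radius: float = 100.0
    embryo_axes: tuple[float, float] = (55.0, 35.0)
    tail_length: float = 45.0
    tail_width: float = 8.0
    flick_angle_deg: float = 30.0
    texture_scale: float = 3.0
    pixel_noise_sd: float = 0.005  # ~1 grey level of camera read noise at 8 bit

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.fps <= 0:
            raise ValueError("need n_frames >= 2 and fps > 0")
        for name in (
            "flick_rate_per_30s",
            "flick_duration_s",
            "flick_amplitude",
            "heart_amplitude",
            "baseline_noise_sd",
            "pixel_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    flick_onset_frames: np.ndarray
    flick_count: int
    heart_phase: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.flick_onset_frames = np.asarray(self.flick_onset_frames, dtype=int)
        if self.flick_count != len(self.flick_onset_frames):
            raise ValueError("flick count inconsistent with onset list")


def _draw_onsets(cfg: SyntheticConfig, rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """Flick onset frames: a renewal process with a refractory period.

    Inter-onset gaps are (2 x flick duration) + exponential, with the
    exponential mean set so the long-run onset rate equals the nominal rate
    (a plain Poisson process thinned by the refractory period would
    systematically undershoot the nominal rate at high rates).  Scripted
    onsets, when given, bypass the draw but keep the refractory thinning.
    """
    dur = cfg.flick_duration_s
    dead = 2.0 * dur
    duration_s = n_samples / cfg.fps
    if cfg.flick_onsets_s is not None:
        times = np.sort(np.asarray(cfg.flick_onsets_s, dtype=float))
        kept: list[float] = []
        for t in times:
            if not kept or t - kept[-1] >= dead:
                kept.append(float(t))
    else:
        rate = cfg.flick_rate_per_30s / 30.0  # onsets per second
        if rate <= 0:
            return np.empty(0, dtype=int)
        mean_gap = max(1.0 / rate, 1.05 * dead)  # rate ceiling at refractory limit
        kept = []
        # equilibrium renewal start (forward recurrence time of the
        # dead-time + exponential gap distribution), so E[count] = T/mean_gap
        if rng.uniform() < dead / mean_gap:
            t = rng.uniform(0.0, dead)
        else:
            t = dead + rng.exponential(mean_gap - dead)
        while t < duration_s - dur:
            kept.append(float(t))
            t += dead + rng.exponential(mean_gap - dead)
    frames = np.round(np.asarray(kept, dtype=float) * cfg.fps).astype(int)
    return frames[frames < n_samples]


def _burst_kernel(cfg: SyntheticConfig) -> np.ndarray:
    """Half-sine burst envelope over the flick duration (out-and-back)."""
    length = max(2, int(round(cfg.flick_duration_s * cfg.fps)))
    return np.sin(np.pi * (np.arange(length) + 0.5) / length)


def generate_motion_record(cfg: SyntheticConfig) -> tuple[MotionRecord, GroundTruth]:
    """Parametric motion record: noise + flick bursts + heart-beat sinusoid.

    pos/neg get half-sine bursts at the flick onsets plus a raised-cosine
    heart component (non-negative by construction) over half-normal baseline
    jitter; rho receives a correlated displacement burst and theta a random
    direction wherever the centre of mass moves.  Fully determined by the
    config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames - 1
    t = np.arange(n) / cfg.fps
    onsets = _draw_onsets(cfg, rng, n)
    kernel = _burst_kernel(cfg)

    heart_phase = 2 * np.pi * cfg.heart_rate_hz * t
    heart = cfg.heart_amplitude * (1.0 + np.cos(heart_phase)) / 2.0
    pos = np.abs(rng.normal(0.0, cfg.baseline_noise_sd, n)) + heart
    neg = np.abs(rng.normal(0.0, cfg.baseline_noise_sd, n)) + heart
    rho = np.abs(rng.normal(0.0, 10.0 * cfg.baseline_noise_sd, n))  # centroid jitter, px
    sig = cfg.flick_amplitude_sigma
    for onset in onsets:
        stop = min(onset + len(kernel), n)
        seg = kernel[: stop - onset]
        vigor = rng.lognormal(-(sig**2) / 2.0, sig) if sig > 0 else 1.0
        pos[onset:stop] += cfg.flick_amplitude * vigor * seg
        neg[onset:stop] += 0.9 * cfg.flick_amplitude * vigor * seg
        rho[onset:stop] += cfg.rho_burst_px * vigor * seg
    theta = np.where(rho > 1e-9, rng.uniform(-np.pi, np.pi, n), 0.0)
    record = MotionRecord(
        pos_angle=pos, neg_angle=neg, rho=rho, theta=theta, frame_rate_hz=cfg.fps
    )
    truth = GroundTruth(
        flick_onset_frames=onsets, flick_count=len(onsets), heart_phase=heart_phase
    )
    return record, truth


def _smooth_texture(shape: tuple[int, int], rng: np.random.Generator, scale: float) -> np.ndarray:
    """Speckle texture in [0.35, 1]: smoothed white noise, granularity ~scale px."""
    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=scale)
    lo, hi = noise.min(), noise.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.675)
    return 0.35 + 0.65 * (noise - lo) / (hi - lo)


def render_sequence(cfg: SyntheticConfig) -> tuple[FrameSequence, GroundTruth]:
    """Rendered frames: textured embryo in a chorion ring, flicking tail, heart.

    The tail (a tapered, textured appendage) rotates out and back through
    ``flick_angle_deg`` over ``flick_duration_s`` at each flick onset; a
    bright spot pulses in size and intensity at ``heart_rate_hz``; Gaussian
    pixel noise is added per frame.  Per-seed deterministic.
    """
    h, w = cfg.frame_shape
    cy, cx = h / 2.0, w / 2.0
    a, b = cfg.embryo_axes
    pivot_x = cx + 0.9 * a
    if (
        cfg.chorion_radius + 4 > min(cx, cy, w - cx, h - cy)
        or pivot_x + cfg.tail_length + 2 > w
    ):
        raise ValueError("embryo/chorion geometry exceeds frame bounds")
    rng = np.random.default_rng(cfg.seed)
    n_pairs = cfg.n_frames - 1
    onsets = _draw_onsets(cfg, rng, n_pairs)
    kernel_len = max(2, int(round(cfg.flick_duration_s * cfg.fps)))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    ring = 0.5 * np.exp(-((r - cfg.chorion_radius) ** 2) / (2 * 1.5**2))
    q = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    body_mask = np.clip((1.0 - q) / 0.08, 0.0, 1.0)
    texture = _smooth_texture((h, w), rng, cfg.texture_scale)
    body = 0.65 * texture * body_mask

    # tail angle per frame: half-sine out-and-back during each flick
    tail_angle = np.zeros(cfg.n_frames)
    for onset in onsets:
        stop = min(onset + kernel_len, cfg.n_frames)
        idx = np.arange(onset, stop)
        tail_angle[idx] = np.deg2rad(cfg.flick_angle_deg) * np.sin(
            np.pi * (idx - onset + 0.5) / kernel_len
        )

    t_all = np.arange(cfg.n_frames) / cfg.fps
    heart_phase = 2 * np.pi * cfg.heart_rate_hz * t_all
    heart_x, heart_y = cx - 0.35 * a, cy - 0.25 * b
    rh2 = (xx - heart_x) ** 2 + (yy - heart_y) ** 2

    frames: list[np.ndarray] = []
    for i in range(cfg.n_frames):
        frame = 0.05 + ring + body
        # tail: rotate sampling coordinates back by -angle about the pivot
        ang = tail_angle[i]
        dx, dy = xx - pivot_x, yy - cy
        u = np.cos(ang) * dx + np.sin(ang) * dy
        v = -np.sin(ang) * dx + np.cos(ang) * dy
        taper = np.clip(1.0 - 0.6 * np.clip(u, 0, cfg.tail_length) / cfg.tail_length, 0.1, 1.0)
        tail_mask = np.clip(
            (cfg.tail_width * taper - np.abs(v)) / 1.5, 0.0, 1.0
        ) * np.clip((cfg.tail_length - u) / 3.0, 0.0, 1.0) * np.clip(u / 1.0 + 1.0, 0.0, 1.0) * (u > -1)
        tex_rows = np.clip(cy + v, 0, h - 1)
        tex_cols = np.clip(pivot_x + u, 0, w - 1)
        tail_tex = ndimage.map_coordinates(texture, [tex_rows, tex_cols], order=1)
        frame = np.maximum(frame, 0.6 * tail_tex * tail_mask)
        if cfg.heart_amplitude > 0:
            pulse = 1.0 + 0.4 * np.sin(heart_phase[i])
            sigma_h = 4.0 * (1.0 + 0.3 * np.sin(heart_phase[i]))
            frame = frame + 4.0 * cfg.heart_amplitude * pulse * np.exp(
                -rh2 / (2 * sigma_h**2)
            )
        if cfg.pixel_noise_sd > 0:
            frame = frame + rng.normal(0.0, cfg.pixel_noise_sd, frame.shape)
        frames.append((np.clip(frame, 0.0, 1.0) * 255).astype(np.uint8))

    seq = FrameSequence(frames=frames, frame_rate_hz=cfg.fps)
    truth = GroundTruth(
        flick_onset_frames=onsets, flick_count=len(onsets), heart_phase=heart_phase[:-1]
    )
    return seq, truth


def generate_experiment(
    design,
    per_period_rates: dict[str, float] | None = None,
    base_cfg: SyntheticConfig | None = None,
    seed: int = 0,
    embryo_sigma: float = EMBRYO_SIGMA,
    vigor_sigma: float = VIGOR_SIGMA,
    vigor_by_period: dict[str, float] | None = None,
) -> tuple[dict[str, MotionRecord], dict[str, GroundTruth], dict[str, float]]:
    """Parametric dataset for a whole experiment design.

    Each embryo draws one lognormal rate multiplier (mean 1, shape
    ``embryo_sigma``) applied to every period's flick rate, and one lognormal
    vigor multiplier (shape ``vigor_sigma``) scaling its flick amplitudes, so
    embryos differ in both how often and how strongly they respond while
    keeping the period time course.  ``vigor_by_period`` additionally scales
    flick amplitude per period (by default flicks at the exposure peak are
    more vigorous).  Returns per-recording motion records, ground truths, and
    the embryo rate multipliers.
    """
    design = validate_design(design)
    rates = dict(STUDY_PERIOD_RATES if per_period_rates is None else per_period_rates)
    missing = [p for p in set(design["period"]) if p not in rates]
    if missing:
        raise ValueError(f"no rate given for period(s): {missing}")
    vigor_p = dict(VIGOR_BY_PERIOD if vigor_by_period is None else vigor_by_period)
    base = base_cfg or SyntheticConfig()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(design) + 1)
    rng_m = np.random.default_rng(children[0])
    embryos = sorted(design["embryo_id"].unique())
    if embryo_sigma > 0:
        mult = rng_m.lognormal(-(embryo_sigma**2) / 2.0, embryo_sigma, len(embryos))
    else:
        mult = np.ones(len(embryos))
    if vigor_sigma > 0:
        vig = rng_m.lognormal(-(vigor_sigma**2) / 2.0, vigor_sigma, len(embryos))
    else:
        vig = np.ones(len(embryos))
    multipliers = dict(zip(embryos, mult.astype(float)))
    vigors = dict(zip(embryos, vig.astype(float)))

    records: dict[str, MotionRecord] = {}
    truths: dict[str, GroundTruth] = {}
    for (_, row), child in zip(design.iterrows(), children[1:]):
        period = row["period"]
        rate = rates[period] * multipliers[row["embryo_id"]]
        amp = base.flick_amplitude * vigors[row["embryo_id"]] * vigor_p.get(period, 1.0)
        child_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        cfg = dataclasses.replace(
            base,
            seed=child_seed,
            flick_rate_per_30s=float(rate),
            flick_amplitude=float(amp),
            flick_onsets_s=None,
        )
        rec, truth = generate_motion_record(cfg)
        rec.recording_id = row["recording_id"]
        rec.embryo_id = row["embryo_id"]
        rec.cycle_index = int(row["cycle_index"])
        records[row["recording_id"]] = rec
        truths[row["recording_id"]] = truth
    return records, truths, multipliers
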