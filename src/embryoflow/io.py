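"""File formats: frame input, motion CSV, fingerprint and count tables.

Conventions: 0-based pixel coordinates, x right / y down; 1-based recording
cycles; CSV with comma separator, "." decimal, UTF-8, LF line endings.
"""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .design import validate_design
from .motion import MEASURES, FrameSequence, MotionRecord
from .spectral import FEATURE_NAMES

#: Rec. 601 luma weights for deterministic RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")

_MOTION_COLUMNS = ("frame_index",) + MEASURES


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return (img[..., :3].astype(float) @ LUMA_WEIGHTS).astype(img.dtype)
    raise ValueError(f"cannot interpret frame with shape {img.shape} as grayscale")


def read_frames(path: str | Path, frame_rate_hz: float = 15.0) -> FrameSequence:
    """Load a frame sequence from a directory of images or a video file.

    Directory frames are ordered lexicographically by filename; colour input
    is converted to grayscale with fixed Rec. 601 weights.  Mixed frame
    dimensions are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise ValueError(f"no TIFF/PNG frames found in {path}")
        frames = [_to_gray(iio.imread(f)) for f in files]
    else:
        frames = [_to_gray(np.asarray(im)) for im in iio.imiter(path)]
        if not frames:
            raise ValueError(f"no frames decoded from {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")
    return FrameSequence(frames=frames, frame_rate_hz=frame_rate_hz, recording_id=path.stem)


def write_frames(seq: FrameSequence, out_dir: str | Path) -> list[Path]:
    """Write a frame sequence as zero-padded single-frame TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq.frames):
        p = out_dir / f"frame_{i:05d}.tif"
        tifffile.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def write_motion_csv(record: MotionRecord, path: str | Path) -> None:
    """One row per frame pair: frame_index, pos_angle, neg_angle, rho, theta.

    Metadata (frame rate, identity) goes into '#'-prefixed header lines;
    values are written with 17 significant digits so write-read round-trips
    are exact.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# frame_rate_hz={record.frame_rate_hz!r}\n")
        fh.write(f"# recording_id={record.recording_id}\n")
        fh.write(f"# embryo_id={record.embryo_id}\n")
        fh.write(f"# cycle_index={record.cycle_index}\n")
        fh.write(",".join(_MOTION_COLUMNS) + "\n")
        for i in range(len(record)):
            fh.write(
                f"{i},{record.pos_angle[i]:.17g},{record.neg_angle[i]:.17g},"
                f"{record.rho[i]:.17g},{record.theta[i]:.17g}\n"
            )


def read_motion_csv(path: str | Path) -> MotionRecord:
    """Read a motion CSV written by :func:`write_motion_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if tuple(df.columns) != _MOTION_COLUMNS:
        raise ValueError(
            f"unexpected motion CSV header {tuple(df.columns)}; expected {_MOTION_COLUMNS}"
        )
    return MotionRecord(
        pos_angle=df["pos_angle"].to_numpy(),
        neg_angle=df["neg_angle"].to_numpy(),
        rho=df["rho"].to_numpy(),
        theta=df["theta"].to_numpy(),
        frame_rate_hz=float(meta.get("frame_rate_hz", "15.0")),
        recording_id=meta.get("recording_id", path.stem),
        embryo_id=meta.get("embryo_id", ""),
        cycle_index=int(meta.get("cycle_index", "0") or 0),
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, lineterminator="\n")


def read_fingerprint_table(path: str | Path) -> pd.DataFrame:
    """Read a fingerprint table (one recording per row, 72 feature columns)."""
    df = _read_table(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"fingerprint table missing columns: {missing[:4]}...")
    return df


def write_fingerprint_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path)


def read_design(path: str | Path) -> pd.DataFrame:
    return validate_design(_read_table(path))


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(validate_design(df), path)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a per-recording tail-flick count table (CSV or XLSX).

    Expects columns embryo_id, cycle_index, count, with period attached or
    derivable from the cycle index.
    """
    df = _read_table(path)
    needed = {"embryo_id", "cycle_index", "count"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if "period" not in df.columns:
        from .design import period_of_cycle

        df["period"] = df["cycle_index"].astype(int).map(period_of_cycle)
    return df


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path)


def period_mean_counts(counts: pd.DataFrame) -> pd.Series:
    """Mean tail-flick count per exposure period (over embryos and cycles)."""
    from .design import PERIODS

    means = counts.groupby("period")["count"].mean()
    return means.reindex([p for p in PERIODS if p in means.index])
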