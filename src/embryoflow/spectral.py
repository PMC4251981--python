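"""Spectral fingerprints: DFT of motion series and aggregation into period bands.

A 30-s recording at 15 Hz gives 448 frame-pair samples per measure; its DFT
yields 224 frequency bins (DC excluded, Nyquist included) spanning oscillation
periods from 29.87 s down to 0.13 s.  Summing bin magnitudes within the 18
analysed period bands, for each of the four motion measures, produces the
72-feature spectral fingerprint of the recording.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import CANONICAL_LENGTH, N_BANDS, PeriodBandTable, assign_bands
from .motion import MEASURES, MotionRecord, truncate_record

#: short measure keys used in fingerprint feature names, in canonical order
MEASURE_KEYS = ("pos", "neg", "rho", "theta")

FEATURE_NAMES = tuple(
    f"{m}_band{j}" for m in MEASURE_KEYS for j in range(1, N_BANDS + 1)
)


@dataclass
class Spectrum:
    """DFT magnitudes |X_k| for k = 1..N/2 (DC excluded)."""

    magnitudes: np.ndarray
    n_samples: int
    fs: float

    def period(self, k: int) -> float:
        """Oscillation period (s) of bin k."""
        return self.n_samples / (self.fs * k)


def canonicalize(record: MotionRecord, target_length: int = CANONICAL_LENGTH) -> MotionRecord:
    """Trim a motion record to the canonical series length.

    Keeps the first ``target_length`` samples of each measure; a shorter
    record is a hard error.
    """
    n = len(record)
    if n < target_length:
        raise ValueError(
            f"motion record has {n} samples; requires ≥ {target_length} samples"
        )
    return truncate_record(record, target_length)


def compute_spectrum(series: np.ndarray, fs: float) -> Spectrum:
    """DFT magnitude spectrum of a real series of even length N.

    Returns |X_k| for k = 1..N/2 where X_k = sum_t x_t exp(-2*pi*i*k*t/N); the
    DC bin is excluded and the Nyquist bin included, so an N-sample series
    yields N/2 bins.  Bin k has period N/(fs*k) seconds.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2 or len(x) % 2:
        raise ValueError("series must be 1-D with even length >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    mags = np.abs(np.fft.rfft(x))[1:]
    return Spectrum(magnitudes=mags, n_samples=len(x), fs=fs)


@dataclass
class SpectralFingerprint:
    """72 non-negative features: 18 period bands x 4 motion measures.

    ``values`` has shape (4, 18), measures ordered (pos, neg, rho, theta).
    ``transform`` is "raw" (band sums of DFT magnitudes) or "log1p".
    """

    values: np.ndarray
    transform: str = "raw"
    recording_id: str = ""
    embryo_id: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(MEASURE_KEYS), N_BANDS):
            raise ValueError(f"fingerprint values must have shape (4, {N_BANDS})")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("fingerprint values must be finite and non-negative")
        if self.transform not in ("raw", "log1p"):
            raise ValueError("transform must be 'raw' or 'log1p'")

    @property
    def flat(self) -> np.ndarray:
        """The 72 features in canonical order (measure-major)."""
        return self.values.ravel()

    def to_series(self) -> pd.Series:
        return pd.Series(self.flat, index=list(FEATURE_NAMES))


def fingerprint(
    record: MotionRecord, band_table: PeriodBandTable | None = None
) -> SpectralFingerprint:
    """Compute the 72-feature raw spectral fingerprint of a motion record.

    The value of band j for a measure is the sum of DFT magnitudes over the
    bins assigned to band j (summing preserves additivity of spectral mass
    across bands of unequal width).  The record should be canonicalized first
    so that the band table's printed period edges are realisable.
    """
    n = len(record)
    table = band_table if band_table is not None else assign_bands(n, record.frame_rate_hz)
    if table.n_samples != n:
        raise ValueError(
            f"band table built for N={table.n_samples}, record has {n} samples"
        )
    values = np.zeros((len(MEASURE_KEYS), N_BANDS))
    for i, measure in enumerate(MEASURES):
        spec = compute_spectrum(record.series(measure), record.frame_rate_hz)
        assigned = table.bin_band >= 0
        values[i] = np.bincount(
            table.bin_band[assigned], weights=spec.magnitudes[assigned], minlength=N_BANDS
        )
    return SpectralFingerprint(
        values=values,
        transform="raw",
        recording_id=record.recording_id,
        embryo_id=record.embryo_id,
        cycle_index=record.cycle_index,
    )


def log_transform(fp: SpectralFingerprint) -> SpectralFingerprint:
    """Apply the log(x + 1) transform (natural log) to a raw fingerprint."""
    if fp.transform != "raw":
        raise ValueError("fingerprint already log-transformed")
    return replace(fp, values=np.log1p(fp.values), transform="log1p")


def fingerprint_table(fps: list[SpectralFingerprint]) -> pd.DataFrame:
    """Stack fingerprints into a table: one row per recording, 72 feature columns."""
    if not fps:
        raise ValueError("no fingerprints given")
    states = {fp.transform for fp in fps}
    if len(states) > 1:
        raise ValueError("fingerprints mix raw and log-transformed values")
    rows = []
    for fp in fps:
        row = {
            "recording_id": fp.recording_id,
            "embryo_id": fp.embryo_id,
            "cycle_index": fp.cycle_index,
        }
        row.update(zip(FEATURE_NAMES, fp.flat))
        rows.append(row)
    return pd.DataFrame(rows)
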