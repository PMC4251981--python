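"""The 18 period bands into which DFT bins are aggregated.

For an N-sample motion series at frame rate fs, DFT bin k (k = 1..N/2)
corresponds to an oscillation period of N/(fs*k) seconds.  The canonical
recording geometry (N = 448 at 15 Hz) spans periods from 29.87 s (k = 1) down
to 0.13 s (k = 224, Nyquist).  Eighteen specific period ranges are analysed;
a bin belongs to a band when its period, rounded to two decimals, falls inside
the band's printed [lower, upper] range.  Some adjacent bands share an edge
(0.27, 0.21 and 0.19 s) — tied bins go to the lower-index band — and some
ranges leave gaps (e.g. 0.51 to 0.45 s) whose bins stay unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (upper_period_s, lower_period_s) for bands 1..18, as analysed in the study.
PERIOD_BANDS: tuple[tuple[float, float], ...] = (
    (29.87, 14.93),
    (9.96, 7.47),
    (5.97, 4.98),
    (4.27, 2.72),
    (2.49, 1.30),
    (1.24, 1.07),
    (1.03, 0.85),
    (0.83, 0.73),
    (0.71, 0.64),
    (0.62, 0.51),
    (0.45, 0.40),
    (0.39, 0.32),
    (0.31, 0.27),
    (0.27, 0.24),
    (0.23, 0.21),
    (0.21, 0.19),
    (0.19, 0.17),
    (0.16, 0.13),
)

N_BANDS = len(PERIOD_BANDS)

#: Canonical series length (frame pairs) and frame rate of one recording.
CANONICAL_LENGTH = 448
CANONICAL_FS = 15.0


def bin_period(k: int | np.ndarray, n_samples: int, fs: float) -> float | np.ndarray:
    """Oscillation period (s) of DFT bin k for an n_samples series at fs Hz."""
    return n_samples / (fs * np.asarray(k, dtype=float))


@dataclass(frozen=True)
class PeriodBandTable:
    """Assignment of DFT bins (k = 1..K) to the 18 period bands.

    ``bin_band[k-1]`` is the 0-based band index of bin k, or -1 when the bin
    falls into one of the printed gaps.
    """

    n_samples: int
    fs: float
    bands: tuple[tuple[float, float], ...] = PERIOD_BANDS
    bin_band: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_bins(self) -> int:
        return self.n_samples // 2

    def bins_in_band(self, band: int) -> np.ndarray:
        """1-based DFT bin indices assigned to 1-based band index ``band``."""
        if not 1 <= band <= len(self.bands):
            raise ValueError(f"band must be in 1..{len(self.bands)}")
        return np.nonzero(self.bin_band == band - 1)[0] + 1


def assign_bands(
    n_samples: int = CANONICAL_LENGTH,
    fs: float = CANONICAL_FS,
    bands: tuple[tuple[float, float], ...] = PERIOD_BANDS,
) -> PeriodBandTable:
    """Assign each DFT bin to at most one period band.

    Bin k joins band j when round(period(k), 2) lies within band j's printed
    range; a bin matching two bands (shared printed edge) goes to the
    lower-index band; bins matching no band are left unassigned (-1).
    """
    if n_samples < 2 or n_samples % 2:
        raise ValueError("n_samples must be even and >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    K = n_samples // 2
    bin_band = np.full(K, -1, dtype=int)
    for k in range(1, K + 1):
        p = round(float(bin_period(k, n_samples, fs)), 2)
        for j, (upper, lower) in enumerate(bands):
            if lower <= p <= upper:
                bin_band[k - 1] = j
                break
    return PeriodBandTable(n_samples=n_samples, fs=fs, bands=tuple(bands), bin_band=bin_band)
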