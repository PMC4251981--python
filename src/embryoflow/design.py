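"""Experiment design: recordings, embryos, recording cycles and exposure periods.

A recording cycle images every embryo once; twenty cycles partition into five
exposure periods of four cycles each: a pre-exposure baseline, two halves of a
chemical exposure, and two halves of a recovery phase.
"""
from __future__ import annotations

import pandas as pd

#: Exposure periods in chronological order.
PERIODS: tuple[str, ...] = ("pre", "ethanol1", "ethanol2", "recovery1", "recovery2")

CYCLES_PER_PERIOD = 4
N_CYCLES = CYCLES_PER_PERIOD * len(PERIODS)

REQUIRED_COLUMNS = ("recording_id", "embryo_id", "cycle_index", "period")


def period_of_cycle(cycle_index: int) -> str:
    """Map a 1-based recording-cycle index (1..20) to its exposure period."""
    if not 1 <= cycle_index <= N_CYCLES:
        raise ValueError(
            f"cycle_index must be in 1..{N_CYCLES}, got {cycle_index}"
        )
    return PERIODS[(cycle_index - 1) // CYCLES_PER_PERIOD]


def make_design(n_embryos: int = 15, n_cycles: int = N_CYCLES) -> pd.DataFrame:
    """Build the standard design table: every embryo recorded once per cycle.

    Returns a frame with columns recording_id, embryo_id, cycle_index, period.
    """
    if n_embryos < 1 or not 1 <= n_cycles <= N_CYCLES:
        raise ValueError("need n_embryos >= 1 and 1 <= n_cycles <= 20")
    rows = [
        (f"e{e:02d}c{c:02d}", f"e{e:02d}", c, period_of_cycle(c))
        for e in range(1, n_embryos + 1)
        for c in range(1, n_cycles + 1)
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    """Check a design table and return it with normalised dtypes.

    Every recording maps to exactly one period; recording ids are unique.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    out = df.copy()
    out["recording_id"] = out["recording_id"].astype(str)
    out["embryo_id"] = out["embryo_id"].astype(str)
    out["cycle_index"] = out["cycle_index"].astype(int)
    out["period"] = out["period"].astype(str)
    if out["recording_id"].duplicated().any():
        dupes = out.loc[out["recording_id"].duplicated(), "recording_id"].tolist()
        raise ValueError(f"duplicate recording ids in design: {dupes[:5]}")
    bad = sorted(set(out["period"]) - set(PERIODS))
    if bad:
        raise ValueError(f"unknown periods in design: {bad}; expected {PERIODS}")
    return out
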