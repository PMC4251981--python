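"""Tail-flick counting and the repeated-measures comparison of counts.

A tail flick — a rapid out-and-back movement of the embryo's tail — appears in
the motion record as a large transient peak in the summed rotation magnitude
(pos + neg).  Counting such peaks gives an automated proxy for manual flick
counts; per-period differences are tested with a one-way within-subject
(repeated-measures) ANOVA over embryos, followed by Bonferroni-adjusted paired
comparisons, and the significance pattern is compared with the pairwise ANOSIM
pattern from the spectral route.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks

from .design import PERIODS, validate_design
from .motion import MotionRecord

logger = logging.getLogger(__name__)


@dataclass
class FlickEvents:
    """Detected tail-flick events in one recording."""

    count: int
    event_frames: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.event_frames = np.asarray(self.event_frames, dtype=int)
        if self.count != len(self.event_frames):
            raise ValueError("count must equal number of event frames")


def detect_tail_flicks(
    record: MotionRecord,
    z_threshold: float = 4.0,
    refractory_s: float = 0.5,
    activity: str = "sum",
) -> FlickEvents:
    """Count large activity peaks as tail flicks.

    The activity trace is pos + neg rotation (a flick drives both senses over
    its out-and-back motion; ``activity="max"`` uses the larger of the two
    instead).  Peaks are local maxima whose robust z-score
    (a - median) / (1.4826 * MAD) reaches ``z_threshold``, accepted greedily
    in descending height with at least ``refractory_s`` separation.  The
    robust score makes the count invariant to uniform positive rescaling of
    the trace.  When the MAD is zero (e.g. a perfectly flat baseline) any
    positive local maximum counts.
    """
    if activity == "sum":
        a = record.activity
    elif activity == "max":
        a = np.maximum(record.pos_angle, record.neg_angle)
    else:
        raise ValueError("activity must be 'sum' or 'max'")
    med = float(np.median(a))
    mad = float(np.median(np.abs(a - med)))
    if mad > 0:
        threshold = med + z_threshold * 1.4826 * mad
    else:
        threshold = med + 1e-12  # flat baseline: any positive excursion
    distance = max(1, int(round(refractory_s * record.frame_rate_hz)))
    peaks, _ = find_peaks(a, height=threshold, distance=distance)
    return FlickEvents(count=len(peaks), event_frames=peaks, threshold_used=threshold)


def aggregate_counts(
    events: dict[str, FlickEvents] | dict[str, int], design: pd.DataFrame
) -> pd.DataFrame:
    """Attach per-recording flick counts to the design table.

    Returns rows (recording_id, embryo_id, cycle_index, period, count), one
    per embryo x cycle.  Recordings missing from ``events`` are logged and
    omitted.
    """
    design = validate_design(design)
    counts = {
        rid: (ev.count if isinstance(ev, FlickEvents) else int(ev))
        for rid, ev in events.items()
    }
    missing = [rid for rid in design["recording_id"] if rid not in counts]
    if missing:
        logger.warning("%d recordings without events; rows omitted", len(missing))
    out = design[design["recording_id"].isin(counts)].copy()
    out["count"] = out["recording_id"].map(counts).astype(float)
    return out.reset_index(drop=True)


@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA with Bonferroni-adjusted paired contrasts."""

    F: float
    df_effect: int
    df_error: int
    p_value: float
    pairwise: dict[tuple[str, str], dict[str, float]]


def rm_anova(
    table: pd.DataFrame,
    response: str = "count",
    within: str = "period",
    subject: str = "embryo_id",
) -> RmAnovaResult:
    """Repeated-measures ANOVA of counts over exposure periods.

    Replicate cycles are first averaged to one value per subject x period;
    the design must then be complete (every subject observed in every
    period).  F = MS_within / MS_(within x subject).  Pairwise period
    contrasts are paired t-tests with Bonferroni adjustment by the number of
    pairs (10 for five periods).
    """
    cell = table.groupby([subject, within], observed=True)[response].mean().unstack(within)
    if cell.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every period")
    n_subj, n_per = cell.shape
    if n_subj < 2 or n_per < 2:
        raise ValueError("need at least 2 subjects and 2 periods")
    X = cell.to_numpy(dtype=float)
    grand = X.mean()
    ss_subject = n_per * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_period = n_subj * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_period
    df_effect = n_per - 1
    df_error = (n_per - 1) * (n_subj - 1)
    ms_period = ss_period / df_effect
    ms_error = ss_error / df_error
    if ms_error <= 1e-300:
        F = 0.0 if ms_period <= 1e-300 else np.inf
        p = 1.0 if ms_period <= 1e-300 else 0.0
    else:
        F = float(ms_period / ms_error)
        p = float(sps.f.sf(F, df_effect, df_error))

    ordered = [p_ for p_ in PERIODS if p_ in cell.columns] + [
        p_ for p_ in cell.columns if p_ not in PERIODS
    ]
    pairs = list(itertools.combinations(ordered, 2))
    m = len(pairs)
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    for ga, gb in pairs:
        diff = cell[ga].to_numpy() - cell[gb].to_numpy()
        if np.allclose(diff, diff[0]):
            # degenerate paired t: zero variance of the differences
            if np.isclose(diff[0], 0):
                t_stat, p_raw = 0.0, 1.0
            else:
                t_stat, p_raw = float(np.sign(diff[0]) * np.inf), 0.0
        else:
            t_stat, p_raw = sps.ttest_rel(cell[ga], cell[gb])
        pairwise[(ga, gb)] = {
            "t": float(t_stat),
            "p_raw": float(p_raw),
            "p_adjusted": float(min(1.0, m * p_raw)),
        }
    return RmAnovaResult(
        F=F, df_effect=df_effect, df_error=df_error, p_value=p, pairwise=pairwise
    )


def significance_category(p: float) -> str:
    """Star category used in pairwise summaries: ***, **, * or ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def concordance_report(
    anosim_pairs: dict[tuple[str, str], float],
    anova_pairs: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict:
    """Agreement between the automated (ANOSIM) and count-based (RM-ANOVA) routes.

    Both inputs map the same unordered period pairs to p-values.  Each pair is
    categorised (***, **, *, ns) per method; agreement counts pairs whose
    significance status at ``alpha`` matches (different star levels on the
    same side of ``alpha`` still agree).
    """
    norm_a = {tuple(sorted(k)): v for k, v in anosim_pairs.items()}
    norm_b = {tuple(sorted(k)): v for k, v in anova_pairs.items()}
    if set(norm_a) != set(norm_b):
        raise ValueError("the two result sets cover different period pairs")
    pairs_out = {}
    agreement = 0
    for key in sorted(norm_a):
        pa, pb = norm_a[key], norm_b[key]
        agree = (pa <= alpha) == (pb <= alpha)
        agreement += int(agree)
        pairs_out["__".join(key)] = {
            "automated_p": float(pa),
            "automated": significance_category(pa),
            "manual_p": float(pb),
            "manual": significance_category(pb),
            "agree": bool(agree),
        }
    return {"pairs": pairs_out, "agreement": agreement, "n_pairs": len(norm_a)}
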