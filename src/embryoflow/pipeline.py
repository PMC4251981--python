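"""End-to-end orchestration and declarative configuration.

The full pipeline runs: motion extraction (or synthetic generation) ->
canonicalisation -> spectral fingerprinting -> log transform -> Bray-Curtis /
ANOSIM / nMDS on the spectral route, in parallel with tail-flick counting ->
repeated-measures ANOVA on the count route, ending in a concordance report
between the two routes.
"""
from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import CANONICAL_LENGTH
from .counts import aggregate_counts, concordance_report, detect_tail_flicks, rm_anova
from .design import PERIODS, make_design, validate_design
from .motion import MotionRecord
from .spectral import (
    FEATURE_NAMES,
    canonicalize,
    fingerprint,
    fingerprint_table,
    log_transform,
)
from .stats import (
    anosim,
    dissimilarity_matrix,
    group_mean_fingerprints,
    nmds,
    pairwise_anosim,
)
from .synthetic import STUDY_PERIOD_RATES, EMBRYO_SIGMA, SyntheticConfig, generate_experiment


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; YAML round-trips byte-stably."""

    fps: float = 15.0
    canonical_length: int = CANONICAL_LENGTH
    n_embryos: int = 15
    permutations: int = 9999
    nmds_restarts: int = 20
    z_threshold: float = 4.0
    refractory_s: float = 0.5
    seed: int = 0
    per_period_rates: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_PERIOD_RATES)
    )
    embryo_sigma: float = EMBRYO_SIGMA

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)


def analyse_fingerprints(
    fp_table: pd.DataFrame,
    design: pd.DataFrame,
    permutations: int = 9999,
    nmds_restarts: int = 20,
    seed: int | None = None,
) -> dict:
    """Spectral-route comparison: global + pairwise ANOSIM, group means, nMDS.

    ``fp_table`` holds log-transformed fingerprints keyed by recording_id.
    """
    design = validate_design(design)
    df = fp_table.merge(
        design[["recording_id", "period"]], on="recording_id", how="inner"
    ) if "period" not in fp_table.columns else fp_table
    if len(df) != len(fp_table):
        raise ValueError("some recordings in the fingerprint table lack design rows")
    X = df[list(FEATURE_NAMES)].to_numpy()
    groups = df["period"].to_numpy()
    dm = dissimilarity_matrix(X, ids=df["recording_id"].tolist())
    global_res = anosim(dm, groups, permutations=permutations, seed=seed)
    pair_res = pairwise_anosim(dm, groups, permutations=permutations, seed=seed)
    means = group_mean_fingerprints(df)
    dm_means = dissimilarity_matrix(means.to_numpy(), ids=list(means.index))
    ordination = nmds(dm_means, n_restarts=nmds_restarts, seed=seed)
    return {
        "global": global_res,
        "pairwise": pair_res,
        "group_means": means,
        "ordination": ordination,
        "dissimilarity": dm,
    }


def run_parametric_experiment(
    config: PipelineConfig | None = None, seed: int | None = None
) -> dict:
    """Full pipeline on a synthetic experiment (parametric motion records).

    Returns a results bundle with the spectral route (ANOSIM, nMDS), the
    count route (flick detection, RM-ANOVA), the concordance report and the
    generator ground truth.
    """
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    design = make_design(n_embryos=cfg.n_embryos)
    base = SyntheticConfig(fps=cfg.fps, n_frames=cfg.canonical_length + 1)
    records, truths, multipliers = generate_experiment(
        design,
        per_period_rates=cfg.per_period_rates,
        base_cfg=base,
        seed=cfg.seed,
        embryo_sigma=cfg.embryo_sigma,
    )

    fps_list = []
    events = {}
    for rid, rec in records.items():
        canon = canonicalize(rec, cfg.canonical_length)
        fps_list.append(log_transform(fingerprint(canon)))
        events[rid] = detect_tail_flicks(
            canon, z_threshold=cfg.z_threshold, refractory_s=cfg.refractory_s
        )
    fp_df = fingerprint_table(fps_list).merge(
        design[["recording_id", "period"]], on="recording_id"
    )
    spectral = analyse_fingerprints(
        fp_df,
        design,
        permutations=cfg.permutations,
        nmds_restarts=cfg.nmds_restarts,
        seed=cfg.seed,
    )

    counts = aggregate_counts(events, design)
    anova = rm_anova(counts)
    concordance = concordance_report(
        {k: v.p_value for k, v in spectral["pairwise"].items()},
        {k: v["p_adjusted"] for k, v in anova.pairwise.items()},
    )
    true_counts = counts.copy()
    true_counts["count"] = true_counts["recording_id"].map(
        {rid: t.flick_count for rid, t in truths.items()}
    )
    return {
        "config": cfg,
        "design": design,
        "records": records,
        "truths": truths,
        "multipliers": multipliers,
        "fingerprints": fp_df,
        "spectral": spectral,
        "counts": counts,
        "true_counts": true_counts,
        "rm_anova": anova,
        "concordance": concordance,
    }


def results_to_report(results: dict) -> dict:
    """Condense a results bundle into a JSON-serialisable report."""
    cfg: PipelineConfig = results["config"]
    spectral = results["spectral"]
    anova = results["rm_anova"]
    counts = results["counts"]
    period_means = counts.groupby("period")["count"].mean()
    report = {
        "versions": {"embryoflow": __version__, "python": platform.python_version()},
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "anosim_global": {
            "R": spectral["global"].R,
            "p": spectral["global"].p_value,
            "permutations": spectral["global"].n_permutations,
        },
        "anosim_pairwise": {
            "__".join(k): {"R": v.R, "p": v.p_value}
            for k, v in spectral["pairwise"].items()
        },
        "nmds": {
            "stress": spectral["ordination"].stress,
            "coordinates": {
                label: [float(x) for x in row]
                for label, row in zip(
                    list(spectral["group_means"].index),
                    spectral["ordination"].coordinates,
                )
            },
        },
        "rm_anova": {
            "F": anova.F,
            "df": [anova.df_effect, anova.df_error],
            "p": anova.p_value,
            "pairwise": {
                "__".join(k): v for k, v in anova.pairwise.items()
            },
        },
        "mean_counts_per_period": {
            p: float(period_means[p]) for p in PERIODS if p in period_means.index
        },
        "concordance": results["concordance"],
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
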