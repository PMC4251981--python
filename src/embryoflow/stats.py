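"""Multivariate comparison of spectral fingerprints across exposure periods.

Recordings are compared through Bray-Curtis dissimilarities of their
(log-transformed) fingerprints; differences between exposure periods are
tested with ANOSIM — a rank-based permutation test whose R statistic contrasts
mean between-group and within-group dissimilarity ranks — and visualised by
non-metric multidimensional scaling (nMDS) of the period-mean fingerprints.
Because ANOSIM and nMDS depend only on the rank order of the dissimilarities,
working with dissimilarities (1 - similarity) is equivalent to the classic
percent-similarity workflow.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .design import PERIODS
from .spectral import FEATURE_NAMES

_PERM_CHUNK = 500


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) of non-negative vectors.

    0 means identical, 1 disjoint support.  Two all-zero vectors have no
    defined dissimilarity; by convention 0 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D with equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    denom = (a + b).sum()
    if denom == 0:
        warnings.warn("both vectors all-zero; Bray-Curtis defined as 0", stacklevel=2)
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def dissimilarity_matrix(X: np.ndarray, ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities over the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    condensed = pdist(X, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn(
            "all-zero row pair(s); their Bray-Curtis dissimilarity set to 0",
            stacklevel=2,
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    ids = ids if ids is not None else [str(i) for i in range(len(X))]
    return DistanceMatrix(squareform(condensed), ids=ids)


@dataclass
class AnosimResult:
    """ANOSIM R statistic and permutation p-value."""

    R: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.R <= 1.0 + 1e-12:
            raise ValueError(f"R out of range: {self.R}")


def _as_square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return np.asarray(d.data, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarities must be a square matrix or DistanceMatrix")
    return d


def _anosim_r_from_ranks(rank_sq: np.ndarray, within_mask: np.ndarray) -> float:
    n = len(rank_sq)
    iu = np.triu_indices(n, k=1)
    within = within_mask[iu]
    ranks = rank_sq[iu]
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def anosim(
    d,
    groups,
    permutations: int | str = 9999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities over a dissimilarity matrix.

    All n(n-1)/2 dissimilarities are ranked with mid-ranks for ties;
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    so R is 1 when every between-group dissimilarity exceeds every
    within-group one and near 0 under exchangeability.  The p-value comes
    from random label permutations, p = (#{R_perm >= R_obs} + 1) /
    (permutations + 1), reproducible bit-for-bit for a given ``seed``.
    ``permutations="exact"`` enumerates every distinct label arrangement
    instead (p = fraction of arrangements with R_perm >= R_obs).
    """
    dm = _as_square(d)
    groups = np.asarray(groups)
    n = len(dm)
    if len(groups) != n:
        raise ValueError("groups length must match matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"every group needs at least 2 members; too small: {small}")

    iu = np.triu_indices(n, k=1)
    rank_sq = np.zeros((n, n))
    rank_sq[iu] = rankdata(dm[iu])
    rank_sq = rank_sq + rank_sq.T

    within_mask = groups[:, None] == groups[None, :]
    r_obs = _anosim_r_from_ranks(rank_sq, within_mask)

    group_positions = [np.nonzero(groups == g)[0] for g in labels]
    n_within_pairs = int(sum(c * (c - 1) // 2 for c in counts))
    n_between_pairs = n * (n - 1) // 2 - n_within_pairs
    total_rank_sum = rank_sq[iu].sum()
    denom = n * (n - 1) / 4.0

    def r_for_index_perms(perm_idx: np.ndarray) -> np.ndarray:
        # perm_idx: (m, n) rows of permuted sample indices; group g's members
        # are perm_idx[:, positions_of_g].  Within-group rank sums via gather.
        within_sum = np.zeros(len(perm_idx))
        for pos in group_positions:
            members = perm_idx[:, pos]
            sub = rank_sq[members[:, :, None], members[:, None, :]]
            within_sum += sub.sum(axis=(1, 2)) / 2.0
        r_w = within_sum / n_within_pairs
        r_b = (total_rank_sum - within_sum) / n_between_pairs
        return (r_b - r_w) / denom

    if permutations == "exact":
        from sympy.utilities.iterables import multiset_permutations

        r_perms = []
        for perm_labels in multiset_permutations(list(groups)):
            pl = np.asarray(perm_labels)
            mask = pl[:, None] == pl[None, :]
            r_perms.append(_anosim_r_from_ranks(rank_sq, mask))
        r_perms = np.asarray(r_perms)
        p = float(np.mean(r_perms >= r_obs - 1e-12))
        return AnosimResult(R=r_obs, p_value=p, n_permutations=len(r_perms), seed=None, n=n)

    permutations = int(permutations)
    if permutations < 1:
        raise ValueError("permutations must be >= 1 or 'exact'")
    rng = np.random.default_rng(seed)
    count_ge = 0
    done = 0
    while done < permutations:
        m = min(_PERM_CHUNK, permutations - done)
        perm_idx = np.array([rng.permutation(n) for _ in range(m)])
        r_perm = r_for_index_perms(perm_idx)
        count_ge += int(np.sum(r_perm >= r_obs - 1e-12))
        done += m
    p = (count_ge + 1) / (permutations + 1)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=permutations, seed=seed, n=n)


def pairwise_anosim(
    d,
    groups,
    pairs: list[tuple[str, str]] | None = None,
    permutations: int | str = 9999,
    seed: int | None = None,
) -> dict[tuple[str, str], AnosimResult]:
    """ANOSIM restricted to each unordered pair of groups (10 pairs for 5)."""
    dm = _as_square(d)
    groups = np.asarray(groups)
    if pairs is None:
        seen = list(dict.fromkeys(groups.tolist()))
        ordered = [p for p in PERIODS if p in seen] + [p for p in seen if p not in PERIODS]
        pairs = list(itertools.combinations(ordered, 2))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(pairs)).astype(np.int64)
    results: dict[tuple[str, str], AnosimResult] = {}
    for (ga, gb), child in zip(pairs, child_seeds):
        sel = np.nonzero((groups == ga) | (groups == gb))[0]
        sub = dm[np.ix_(sel, sel)]
        child_seed = None if permutations == "exact" else int(child % (2**31))
        results[(ga, gb)] = anosim(
            sub, groups[sel], permutations=permutations, seed=child_seed
        )
    return results


def group_mean_fingerprints(
    fp_table: pd.DataFrame, periods: tuple[str, ...] = PERIODS
) -> pd.DataFrame:
    """Arithmetic per-feature mean of (log-transformed) fingerprints per period.

    ``fp_table`` must carry a ``period`` column plus the 72 feature columns;
    returns one row per period in chronological order.
    """
    if "period" not in fp_table.columns:
        raise ValueError("fingerprint table needs a 'period' column")
    missing = [c for c in FEATURE_NAMES if c not in fp_table.columns]
    if missing:
        raise ValueError(f"fingerprint table missing feature columns: {missing[:4]}...")
    present = set(fp_table["period"])
    empty = [p for p in periods if p not in present]
    if empty:
        raise ValueError(f"no recordings in period(s): {empty}")
    means = fp_table.groupby("period")[list(FEATURE_NAMES)].mean()
    return means.loc[list(periods)]


@dataclass
class Ordination:
    """A low-dimensional nMDS configuration and its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    n_restarts: int
    seed: int | None = None


def nmds(
    d,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
) -> Ordination:
    """Non-metric MDS minimising Kruskal stress-1.

    Configuration distances are monotonically regressed on the rank order of
    the input dissimilarities (SMACOF with isotonic regression); the best of
    ``n_restarts`` random starts is returned.
    """
    dm = _as_square(d)
    n = len(dm)
    if n < 3:
        raise ValueError("nMDS needs at least 3 samples")
    iu = np.triu_indices(n, k=1)
    if np.allclose(dm[iu], dm[iu][0]):
        warnings.warn("all dissimilarities equal; configuration is arbitrary", stacklevel=2)
    model = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=1e-12,
        random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(dm)
    return Ordination(
        coordinates=coords, stress=float(model.stress_), n_restarts=n_restarts, seed=seed
    )


def plot_ordination(
    ordination: Ordination,
    labels: list[str],
    sizes: list[float] | None = None,
    path: str | None = None,
):
    """Scatter the nMDS configuration; marker area may encode e.g. flick rate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ordination.coordinates
    s = 80.0 if sizes is None else 40.0 + 40.0 * np.asarray(sizes, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords[:, 0], coords[:, 1], s=s, alpha=0.7)
    for (x, y), lab in zip(coords, labels):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("nMDS 1")
    ax.set_ylabel("nMDS 2")
    ax.set_title(f"nMDS (stress = {ordination.stress:.3f})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
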