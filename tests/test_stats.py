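"""Bray-Curtis, ANOSIM (vs brute-force enumeration and skbio), nMDS, group means."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from embryoflow.design import PERIODS, make_design
from embryoflow.spectral import FEATURE_NAMES
from embryoflow.stats import (
    anosim,
    bray_curtis,
    dissimilarity_matrix,
    group_mean_fingerprints,
    nmds,
    pairwise_anosim,
)


def brute_force_anosim(dm, groups):
    """Independent ANOSIM oracle: direct rank arithmetic plus exhaustive
    enumeration of every distinct label arrangement."""
    groups = np.asarray(groups)
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu])

    def r_stat(labels):
        within = (labels[:, None] == labels[None, :])[iu]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    r_obs = r_stat(groups)
    arrangements = sorted(set(itertools.permutations(groups.tolist())))
    r_all = np.array([r_stat(np.asarray(a)) for a in arrangements])
    p_exact = float(np.mean(r_all >= r_obs - 1e-12))
    return r_obs, p_exact, len(arrangements)


def kruskal_stress(dm, coords):
    """Stress-1 of a configuration, via isotonic regression on rank order."""
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    d = pdist(coords)
    order = np.argsort(dm[iu])
    disp = IsotonicRegression().fit_transform(np.arange(len(d)), d[order])
    dhat = np.empty_like(d)
    dhat[order] = disp
    return np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())


class TestBrayCurtis:
    def test_identical_vectors_are_zero(self):
        assert bray_curtis(np.array([2.0, 5, 1]), np.array([2.0, 5, 1])) == 0.0

    def test_hand_example(self):
        assert bray_curtis(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == pytest.approx(
            4 / 12
        )

    def test_disjoint_supports_are_maximal(self):
        assert bray_curtis(np.array([1.0, 0]), np.array([0.0, 2])) == 1.0

    def test_double_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert bray_curtis(np.zeros(3), np.zeros(3)) == 0.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(np.array([-1.0, 1]), np.array([1.0, 1]))

    @given(st.floats(0.01, 100.0), st.integers(0, 500))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(10), rng.random(10)
        assert bray_curtis(c * a, c * b) == pytest.approx(bray_curtis(a, b), rel=1e-9)
        assert 0.0 <= bray_curtis(a, b) <= 1.0

    def test_matrix_is_symmetric_zero_diagonal(self):
        X = np.random.default_rng(1).random((6, 4))
        dm = np.asarray(dissimilarity_matrix(X).data)
        assert np.allclose(dm, dm.T)
        assert not np.diag(dm).any()
        assert ((dm >= 0) & (dm <= 1)).all()


class TestAnosim:
    def test_identical_group_multisets_are_null(self):
        X = np.vstack([np.random.default_rng(2).random((5, 3))] * 2)
        dm = squareform(pdist(X))
        res = anosim(dm, ["a"] * 5 + ["b"] * 5, permutations=999, seed=0)
        assert res.p_value > 0.05
        assert abs(res.R) <= 0.25

    def test_fully_separated_clusters_reach_r_one(self):
        X = np.vstack(
            [np.random.default_rng(3).random((4, 2)), 100 + np.random.default_rng(4).random((4, 2))]
        )
        dm = squareform(pdist(X))
        res = anosim(dm, ["a"] * 4 + ["b"] * 4, permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_exhaustive_enumeration_for_six_samples(self):
        rng = np.random.default_rng(5)
        dm = squareform(rng.random(15))
        groups = ["a"] * 3 + ["b"] * 3
        r_oracle, p_oracle, n_arr = brute_force_anosim(dm, groups)
        res = anosim(dm, groups, permutations="exact")
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == n_arr
        # seeded Monte-Carlo p agrees within 2 standard errors
        mc = anosim(dm, groups, permutations=999, seed=11)
        se = np.sqrt(p_oracle * (1 - p_oracle) / 999)
        assert abs(mc.p_value - p_oracle) <= 2 * se + 1 / 999

    def test_matches_skbio_r_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(6)
        X = rng.random((12, 5))
        X[6:] += 0.4
        dm = squareform(pdist(X, metric="braycurtis"))
        groups = ["a"] * 6 + ["b"] * 6
        ours = anosim(dm, groups, permutations=99, seed=0)
        theirs = skbio_anosim(DistanceMatrix(dm), grouping=groups, permutations=0)
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_seeded_permutation_p_is_bit_reproducible(self):
        rng = np.random.default_rng(7)
        dm = squareform(rng.random(45))
        groups = ["a"] * 5 + ["b"] * 5
        a = anosim(dm, groups, permutations=499, seed=42)
        b = anosim(dm, groups, permutations=499, seed=42)
        assert a.R == b.R and a.p_value == b.p_value

    @given(st.integers(0, 300))
    def test_r_and_p_ranges(self, seed):
        rng = np.random.default_rng(seed)
        dm = squareform(rng.random(28))
        res = anosim(dm, ["a", "a", "a", "a", "b", "b", "b", "b"], permutations=49, seed=seed)
        assert -1.0 <= res.R <= 1.0
        assert 0.0 < res.p_value <= 1.0

    def test_singleton_group_rejected(self):
        dm = squareform(np.random.default_rng(8).random(10))
        with pytest.raises(ValueError, match="at least 2 members"):
            anosim(dm, ["a", "a", "a", "a", "b"], permutations=9, seed=0)


class TestPairwiseAnosim:
    def test_five_periods_give_ten_pairs(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 4))
        dm = squareform(pdist(X))
        groups = np.repeat(PERIODS, 4)
        res = pairwise_anosim(dm, groups, permutations=49, seed=0)
        assert len(res) == 10
        assert set(res) == set(itertools.combinations(PERIODS, 2))

    def test_duplicated_period_data_is_null(self):
        # period b is an exact copy of period a: the test must not reject
        rng = np.random.default_rng(10)
        base = rng.random((6, 4))
        X = np.vstack([base, base, rng.random((6, 4)) + 2.0])
        dm = squareform(pdist(X))
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        for seed in range(10):
            res = pairwise_anosim(dm, groups, pairs=[("a", "b")], permutations=199, seed=seed)
            assert res[("a", "b")].p_value > 0.05

    def test_strong_shift_detected_at_high_confidence(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.random((10, 4)), rng.random((10, 4)) + 10.0])
        dm = squareform(pdist(X))
        res = pairwise_anosim(
            dm, ["a"] * 10 + ["b"] * 10, pairs=[("a", "b")], permutations=9999, seed=1
        )
        assert res[("a", "b")].p_value <= 0.001


class TestGroupMeans:
    def _table(self, n_embryos=2):
        design = make_design(n_embryos=n_embryos)
        rng = np.random.default_rng(12)
        df = design.copy()
        for name in FEATURE_NAMES:
            df[name] = rng.random(len(df))
        return df

    def test_single_recording_per_period_equals_itself(self):
        df = self._table(n_embryos=1).groupby("period", as_index=False).first()
        means = group_mean_fingerprints(df)
        for period in PERIODS:
            row = df[df["period"] == period].iloc[0]
            assert np.allclose(means.loc[period], row[list(FEATURE_NAMES)].astype(float))

    def test_means_average_all_recordings_in_period(self):
        df = self._table(n_embryos=3)
        means = group_mean_fingerprints(df)
        sub = df[df["period"] == "pre"]
        assert len(sub) == 12
        assert np.allclose(means.loc["pre"], sub[list(FEATURE_NAMES)].mean())

    def test_empty_period_is_hard_error(self):
        df = self._table()
        with pytest.raises(ValueError, match="no recordings"):
            group_mean_fingerprints(df[df["period"] != "recovery2"])


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        dm = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="all dissimilarities equal"):
            o = nmds(dm, n_restarts=4, seed=0)
        assert o.stress <= 1e-6

    def test_planar_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 1, (5, 2))
        dm = squareform(pdist(pts))
        o = nmds(dm, n_restarts=10, seed=1)
        assert o.stress <= 0.01
        assert kruskal_stress(dm, o.coordinates) <= 0.01

    def test_reported_stress_matches_independent_recomputation(self):
        rng = np.random.default_rng(14)
        A = rng.uniform(0.2, 1.0, (7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        o = nmds(A, n_restarts=8, seed=2)
        assert o.stress == pytest.approx(kruskal_stress(A, o.coordinates), abs=0.02)

    def test_stress_invariant_under_rotation_of_configuration(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 1, (6, 2))
        dm = squareform(pdist(pts))
        o = nmds(dm, n_restarts=5, seed=3)
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = o.coordinates @ R.T
        assert kruskal_stress(dm, rotated) == pytest.approx(
            kruskal_stress(dm, o.coordinates), abs=1e-10
        )

    def test_best_of_restarts_no_worse_than_single(self):
        rng = np.random.default_rng(16)
        A = rng.uniform(0.2, 1.0, (8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        multi = nmds(A, n_restarts=8, seed=4)
        single = nmds(A, n_restarts=1, seed=4)
        assert multi.stress <= single.stress + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nmds(np.zeros((2, 2)))
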