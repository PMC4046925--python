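import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from succession import AbundanceTable, to_relative
from succession import ordination as ordn


def _rel(columns):
    arr = np.asarray(columns, dtype=float).T
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    t = AbundanceTable(df.round().astype(int)) if np.allclose(arr, np.round(arr)) else None
    return df


class TestDistances:
    def test_bray_curtis_hand_case(self):
        df = pd.DataFrame({"x": [1, 2], "y": [2, 1]}, index=["a", "b"])
        d = ordn.bray_curtis_matrix(df)
        assert d["x", "y"] == pytest.approx(2 / 6)

    def test_bray_curtis_identical_and_disjoint(self):
        df = pd.DataFrame({"x": [1, 0], "y": [1, 0], "z": [0, 3]}, index=["a", "b"])
        d = ordn.bray_curtis_matrix(df)
        assert d["x", "y"] == 0
        assert d["x", "z"] == 1

    def test_gower_hand_cases(self):
        df = pd.DataFrame({"x": [0.0], "y": [4.0]}, index=["a"])
        assert ordn.gower_matrix(df)["x", "y"] == pytest.approx(1.0)
        # 3 samples, 2 features, manual computation
        df = pd.DataFrame({"x": [0.0, 1.0], "y": [2.0, 3.0], "z": [4.0, 2.0]},
                          index=["a", "b"])
        d = ordn.gower_matrix(df)
        # ranges: a -> 4, b -> 2
        assert d["x", "y"] == pytest.approx((2 / 4 + 2 / 2) / 2, abs=1e-12)
        assert d["x", "z"] == pytest.approx((4 / 4 + 1 / 2) / 2, abs=1e-12)
        assert d["y", "z"] == pytest.approx((2 / 4 + 1 / 2) / 2, abs=1e-12)

    def test_gower_drops_zero_range_features(self, caplog):
        df = pd.DataFrame({"x": [1.0, 5.0], "y": [1.0, 7.0]}, index=["const", "var"])
        with caplog.at_level("WARNING"):
            d = ordn.gower_matrix(df)
        assert d["x", "y"] == pytest.approx(1.0)


def _brute_force_anosim_r(D, groups):
    """Independent ANOSIM R: midranks computed from scratch."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [D[i, j] for i, j in pairs]
    order = sorted(range(len(dists)), key=lambda k: dists[k])
    ranks = [0.0] * len(dists)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and dists[order[j + 1]] == dists[order[k]]:
            j += 1
        mid = (k + j) / 2 + 1
        for idx in order[k:j + 1]:
            ranks[idx] = mid
        k = j + 1
    between = [groups[i] != groups[j] for i, j in pairs]
    rb = np.mean([r for r, b in zip(ranks, between) if b])
    rw = np.mean([r for r, b in zip(ranks, between) if not b])
    return (rb - rw) / (len(pairs) / 2)


class TestAnosim:
    def _toy(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 4))
        X[n // 2:] += 0.8
        D = squareform(pdist(X), checks=False)
        groups = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return DistanceMatrix(D, ids=[f"s{i}" for i in range(n)]), groups

    def test_perfect_separation_r_one(self):
        D = np.array([
            [0, 0.1, 0.9, 0.9],
            [0.1, 0, 0.9, 0.9],
            [0.9, 0.9, 0, 0.1],
            [0.9, 0.9, 0.1, 0],
        ])
        res = ordn.anosim(DistanceMatrix(D, ids=list("abcd")), ["g1", "g1", "g2", "g2"],
                          n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_r_matches_brute_force(self):
        dm, groups = self._toy()
        res = ordn.anosim(dm, groups, n_permutations=9, seed=1)
        assert res.R == pytest.approx(_brute_force_anosim_r(dm.data, groups), abs=1e-12)

    def test_p_matches_exhaustive_enumeration(self):
        """Monte-Carlo p agrees with full enumeration over relabelings."""
        dm, groups = self._toy(seed=3)
        r_obs = _brute_force_anosim_r(dm.data, groups)
        perms = set(itertools.permutations(groups))
        exact = np.mean([
            _brute_force_anosim_r(dm.data, list(p)) >= r_obs for p in perms
        ])
        res = ordn.anosim(dm, groups, n_permutations=9999, seed=5)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_r_invariant_under_monotone_transform(self):
        dm, groups = self._toy(seed=9)
        r1 = ordn.anosim(dm, groups, n_permutations=9, seed=0).R
        dm2 = DistanceMatrix(np.sqrt(dm.data), ids=dm.ids)
        r2 = ordn.anosim(dm2, groups, n_permutations=9, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_skbio(self):
        dm, groups = self._toy(seed=11, n=10)
        res = ordn.anosim(dm, groups, n_permutations=999, seed=0)
        sk = skbio_anosim(dm, grouping=groups, permutations=999)
        assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        dm, _ = self._toy()
        with pytest.raises(ValueError, match="fewer than 2"):
            ordn.anosim(dm, ["a", "b", "b", "b", "b", "b"])


class TestPairwiseAnosim:
    def test_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 3))
        dm = DistanceMatrix(squareform(pdist(X), checks=False),
                            ids=[f"s{i}" for i in range(12)])
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = ordn.pairwise_anosim(dm, groups, n_permutations=99, seed=0)
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
        assert len(out) == 3

    def test_planted_pair_has_minimal_adjusted_p(self):
        rng = np.random.default_rng(6)
        X = rng.random((18, 3))
        X[12:] += 2.0  # only group c is shifted
        dm = DistanceMatrix(squareform(pdist(X), checks=False),
                            ids=[f"s{i}" for i in range(18)])
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        out = ordn.pairwise_anosim(dm, groups, n_permutations=199, seed=0)
        ab = out[(out["group_a"] == "a") & (out["group_b"] == "b")]["p_adjusted"].iloc[0]
        others = out[(out["group_a"] != "a") | (out["group_b"] != "b")]["p_adjusted"]
        assert (others < ab).all()


class TestPermanova:
    def test_equals_classical_anova_on_1d(self):
        rng = np.random.default_rng(8)
        ya, yb, yc = rng.normal(0, 1, 7), rng.normal(1, 1, 5), rng.normal(2, 1, 6)
        y = np.concatenate([ya, yb, yc])
        groups = ["a"] * 7 + ["b"] * 5 + ["c"] * 6
        D = np.abs(y[:, None] - y[None, :])
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(len(y))])
        res = ordn.permanova(dm, groups, n_permutations=9, seed=0)
        f_classic = f_oneway(ya, yb, yc).statistic
        assert res.pseudo_F == pytest.approx(f_classic, abs=1e-9)

    def test_no_group_effect_r2_near_zero(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.random((4, 3))] * 2)  # duplicated identical groups
        dm = DistanceMatrix(squareform(pdist(X), checks=False),
                            ids=[f"s{i}" for i in range(8)])
        res = ordn.permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=0)
        assert res.R2 == pytest.approx(0.0, abs=1e-9)

    def test_planted_shift_significant(self):
        rng = np.random.default_rng(4)
        X = rng.random((16, 3))
        X[8:] += 3.0
        dm = DistanceMatrix(squareform(pdist(X), checks=False),
                            ids=[f"s{i}" for i in range(16)])
        res = ordn.permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=999, seed=0)
        assert res.p <= 0.001 + 1e-9

    def test_matches_skbio(self):
        rng = np.random.default_rng(13)
        X = rng.random((10, 4))
        dm = DistanceMatrix(squareform(pdist(X), checks=False),
                            ids=[f"s{i}" for i in range(10)])
        groups = ["a"] * 5 + ["b"] * 5
        res = ordn.permanova(dm, groups, n_permutations=9, seed=0)
        sk = skbio_permanova(dm, grouping=groups, permutations=9)
        assert res.pseudo_F == pytest.approx(sk["test statistic"], abs=1e-9)


class TestPcoa:
    def test_points_on_a_line_single_axis(self):
        y = np.array([0.0, 1.0, 2.5, 4.0])
        D = np.abs(y[:, None] - y[None, :])
        res = ordn.pcoa(DistanceMatrix(D, ids=list("abcd")))
        assert res.proportion_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_planar_isometry(self):
        rng = np.random.default_rng(0)
        P = rng.random((8, 2))
        D = squareform(pdist(P), checks=False)
        res = ordn.pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(8)]))
        rec = squareform(pdist(res.coordinates.to_numpy()[:, :2]), checks=False)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.random((7, 5))
        D = squareform(pdist(X, metric="braycurtis"), checks=False)
        dm = DistanceMatrix(D, ids=[f"s{i}" for i in range(7)])
        res = ordn.pcoa(dm)
        from skbio.stats.ordination import pcoa as skbio_pcoa
        sk = skbio_pcoa(dm)
        np.testing.assert_allclose(
            res.eigenvalues[:4], sk.eigvals.to_numpy()[:4], atol=1e-9
        )


class TestCca:
    Y = np.array([  # samples x features, fixed oracle table
        [10, 0, 3, 1],
        [2, 8, 1, 0],
        [0, 3, 7, 2],
        [5, 1, 0, 9],
        [1, 6, 2, 3],
        [4, 2, 5, 1],
    ])
    GROUPS = ["a", "a", "b", "b", "c", "c"]
    # frozen from an independent constrained-correspondence fit of this table
    VEGAN_TOTAL = 0.7965217
    VEGAN_CONSTRAINED = 0.216281
    VEGAN_EIG = (0.1872123, 0.02906867)

    def _df(self):
        return pd.DataFrame(self.Y.T, index=[f"f{i}" for i in range(4)],
                            columns=[f"s{j}" for j in range(6)])

    def test_against_frozen_reference(self):
        res = ordn.cca(self._df(), self.GROUPS)
        assert res.total_inertia == pytest.approx(self.VEGAN_TOTAL, abs=1e-6)
        assert res.constrained_inertia == pytest.approx(self.VEGAN_CONSTRAINED, abs=1e-6)
        np.testing.assert_allclose(res.eigenvalues, self.VEGAN_EIG, atol=1e-7)

    def test_eigenvalue_oracle(self):
        """Canonical eigenvalues equal the eigenvalues of the projected
        chi-square residual cross-product, computed independently."""
        F = self.Y.astype(float)
        P = F / F.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        X = pd.get_dummies(pd.Series(self.GROUPS), drop_first=True, dtype=float).to_numpy()
        Xc = (X - r @ X) * np.sqrt(r)[:, None]
        H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
        Qh = H @ Q
        expected = np.sort(np.linalg.eigvalsh(Qh.T @ Qh))[::-1][:2]
        res = ordn.cca(self._df(), self.GROUPS)
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_saturated_design_captures_total_inertia(self):
        res = ordn.cca(self._df(), [f"g{i}" for i in range(6)])
        assert res.constrained_inertia == pytest.approx(res.total_inertia, abs=1e-9)

    def test_constrained_at_most_total(self):
        res = ordn.cca(self._df(), self.GROUPS)
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_constant_constraint_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ordn.cca(self._df(), ["a"] * 6)


class TestHulls:
    def _ord(self, points):
        coords = pd.DataFrame(points, columns=["PCo1", "PCo2"])
        return ordn.OrdinationResult(
            method="pcoa", coordinates=coords,
            eigenvalues=np.ones(2), proportion_explained=np.array([50.0, 50.0]),
        )

    def test_identical_and_disjoint(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        far = [(10, 10), (11, 10), (11, 11), (10, 11)]
        res = ordn.hull_dissimilarity(self._ord(square + square), ["a"] * 4 + ["b"] * 4)
        assert res[0].dissimilarity == pytest.approx(0.0)
        res = ordn.hull_dissimilarity(self._ord(square + far), ["a"] * 4 + ["b"] * 4)
        assert res[0].dissimilarity == pytest.approx(1.0)

    def test_overlapping_unit_squares(self):
        a = [(0, 0), (1, 0), (1, 1), (0, 1)]
        b = [(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)]
        res = ordn.hull_dissimilarity(self._ord(a + b), ["a"] * 4 + ["b"] * 4)
        assert res[0].dissimilarity == pytest.approx(1 - 0.5 / 1.5, abs=1e-12)
        assert res[0].overlap_area == pytest.approx(0.5)

    def test_collinear_group_named_in_error(self):
        pts = [(0, 0), (1, 1), (2, 2)] + [(0, 1), (1, 0), (2, 5)]
        with pytest.raises(ValueError, match="flat"):
            ordn.hull_dissimilarity(self._ord(pts), ["flat"] * 3 + ["ok"] * 3)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        pts = rng.random((12, 2))
        res = ordn.hull_dissimilarity(self._ord(pts), ["a"] * 6 + ["b"] * 6)
        assert 0.0 <= res[0].dissimilarity <= 1.0
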