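"""Alpha diversity closed forms, UniFrac oracles, PCoA geometry, PERMANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from fmtrack import (
    CountTable,
    alpha_diversity,
    compare_alpha,
    pcoa,
    permanova,
    weighted_unifrac,
)


def _table(matrix, samples, asvs) -> CountTable:
    return CountTable(pd.DataFrame(matrix, index=samples, columns=asvs))


def brute_force_unifrac(table: CountTable, tree: TreeNode, normalized: bool) -> np.ndarray:
    """Independent oracle: explicit per-branch loop over every sample pair."""
    rel = table.relative_abundance()
    n = table.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for node in tree.postorder(include_self=False):
                tips_below = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
                pa = sum(rel.iloc[i].get(t, 0.0) for t in tips_below)
                pb = sum(rel.iloc[j].get(t, 0.0) for t in tips_below)
                b = node.length or 0.0
                num += b * abs(pa - pb)
                den += b * (pa + pb)
            out[i, j] = num / den if normalized and den > 0 else num if not normalized else 0.0
    return out


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        table = _table([[5, 5, 5, 5]], ["s"], list("abcd"))
        res = alpha_diversity(table)
        assert res.loc["s", "observed_asvs"] == 4
        assert res.loc["s", "shannon"] == pytest.approx(math.log(4), abs=1e-12)
        assert res.loc["s", "simpson"] == pytest.approx(0.75, abs=1e-12)

    def test_single_asv_sample(self):
        res = alpha_diversity(_table([[9, 0]], ["s"], ["a", "b"]))
        assert res.loc["s", "observed_asvs"] == 1
        assert res.loc["s", "shannon"] == 0.0
        assert res.loc["s", "simpson"] == 0.0

    def test_hand_computed_entropy(self):
        res = alpha_diversity(_table([[50, 30, 20]], ["s"], list("abc")))
        expected = -sum(p * math.log(p) for p in (0.5, 0.3, 0.2))
        assert res.loc["s", "shannon"] == pytest.approx(expected, abs=1e-12)

    def test_reciprocal_simpson_flag(self):
        res = alpha_diversity(_table([[5, 5]], ["s"], ["a", "b"]), simpson_form="reciprocal")
        assert res.loc["s", "simpson"] == pytest.approx(2.0)

    def test_relabeling_invariance(self, rng):
        counts = rng.integers(1, 50, size=(3, 8))
        t1 = _table(counts, ["x", "y", "z"], [f"a{i}" for i in range(8)])
        t2 = _table(counts, ["x", "y", "z"], [f"b{i}" for i in range(8)])
        assert np.allclose(alpha_diversity(t1).to_numpy(), alpha_diversity(t2).to_numpy())

    def test_zero_depth_sample_errors(self):
        with pytest.raises(ValueError, match="zero-depth"):
            alpha_diversity(_table([[0, 0], [1, 2]], ["bad", "ok"], ["a", "b"]))


class TestCompareAlpha:
    def test_identical_groups_ranksum_p_one(self):
        # constant groups are non-normal by convention -> rank-sum, no signal
        res = compare_alpha([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert res.test == "ranksum"
        assert res.p_value == 1.0

    def test_separated_normals_select_t_test(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        res = compare_alpha(a, b)
        assert res.test == "t"
        assert res.p_value < 0.01
        # the statistic matches the standard pooled-variance formula
        ref = stats.ttest_ind(a, b)
        assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-12)

    def test_heavy_tails_select_ranksum(self):
        rng = np.random.default_rng(8)
        a = rng.standard_cauchy(30)
        b = rng.standard_cauchy(30)
        # Shapiro rejection verified independently
        assert stats.shapiro(a).pvalue < 0.05 or stats.shapiro(b).pvalue < 0.05
        assert compare_alpha(a, b).test == "ranksum"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_alpha([1, 2], [1, 2, 3])


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = TreeNode.read(["((a:1,b:2):0.5,c:3);"])
        table = _table([[5, 5, 5], [10, 10, 10]], ["s1", "s2"], list("abc"))
        dm = weighted_unifrac(table, tree)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_single_tips_normalized_one(self):
        tree = TreeNode.read(["(a:1.7,b:0.4);"])
        table = _table([[10, 0], [0, 25]], ["s1", "s2"], ["a", "b"])
        dm = weighted_unifrac(table, tree, normalized=True)
        assert dm["s1", "s2"] == pytest.approx(1.0, abs=1e-12)

    def test_caterpillar_tree_hand_computation(self):
        # (((a:1,b:2):1,c:3):1,d:4); with p_A=(.5,.5,0,0), p_B=(0,.25,.25,.5)
        tree = TreeNode.read(["(((a:1,b:2):1,c:3):1,d:4);"])
        table = _table([[2, 2, 0, 0], [0, 1, 1, 2]], ["A", "B"], list("abcd"))
        # per-branch b*|pA-pB|: a:1*.5; b:2*.25; (ab):1*.75; c:3*.25; (abc):1*.5; d:4*.5
        raw = 1 * 0.5 + 2 * 0.25 + 1 * 0.75 + 3 * 0.25 + 1 * 0.5 + 4 * 0.5
        # per-branch b*(pA+pB): a:1*.5; b:2*.75; (ab):1*1.25; c:3*.25; (abc):1*1.5; d:4*.5
        den = 1 * 0.5 + 2 * 0.75 + 1 * 1.25 + 3 * 0.25 + 1 * 1.5 + 4 * 0.5
        dm_raw = weighted_unifrac(table, tree, normalized=False)
        dm_norm = weighted_unifrac(table, tree, normalized=True)
        assert dm_raw["A", "B"] == pytest.approx(raw, abs=1e-12)
        assert dm_norm["A", "B"] == pytest.approx(raw / den, abs=1e-12)

    def test_matches_brute_force_and_skbio(self, rng):
        from fmtrack import generate_tree

        asvs = [f"Fam{i % 3}_{i:04d}" for i in range(12)]
        tree = generate_tree(asvs, seed=3)
        counts = rng.integers(0, 40, size=(5, 12))
        counts[:, 0] += 1
        table = _table(counts, [f"s{i}" for i in range(5)], asvs)
        for normalized in (True, False):
            dm = weighted_unifrac(table, tree, normalized=normalized)
            oracle = brute_force_unifrac(table, tree, normalized)
            assert np.allclose(dm.data, oracle, atol=1e-10)
            sk = beta_diversity(
                "weighted_unifrac", counts, ids=table.sample_ids, taxa=asvs,
                tree=tree, normalized=normalized,
            )
            assert np.allclose(dm.data, sk.data, atol=1e-10)

    def test_missing_tip_named(self):
        tree = TreeNode.read(["(a:1,b:1);"])
        table = _table([[1, 2]], ["s"], ["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            weighted_unifrac(table, tree)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-10)
        axis = np.sort(res.coordinates["PC1"].to_numpy())
        assert np.allclose(axis, [-1, 0, 1], atol=1e-10)

    def test_reconstructs_euclidean_distances(self, rng):
        points = rng.normal(size=(7, 2))
        d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        res = pcoa(d)
        emb = res.coordinates.to_numpy()[:, :2]
        back = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
        assert np.allclose(back, d, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array(
            [[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]], dtype=float
        )
        res = pcoa(d)
        assert np.allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy(), atol=1e-10
        )

    def test_explained_proportions_match_skbio(self, rng):
        points = rng.normal(size=(9, 3))
        d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(9)])
        mine = pcoa(dm)
        theirs = skbio_pcoa(dm)
        k = len(mine.proportion_explained)
        assert np.allclose(
            mine.proportion_explained,
            theirs.proportion_explained.to_numpy()[:k],
            atol=1e-8,
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))


class TestPermanova:
    @staticmethod
    def _cloud_dm(rng, n_per=10, separation=0.0):
        pts = np.vstack(
            [rng.normal(0, 1, size=(n_per, 2)), rng.normal(separation, 1, size=(n_per, 2))]
        )
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        labels = ["A"] * n_per + ["B"] * n_per
        return d, labels

    def test_complete_separation_minimum_p(self, rng):
        d, labels = self._cloud_dm(rng, separation=50.0)
        res = permanova(d, labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(0.001)
        assert res.r_squared > 0.9

    def test_statistic_matches_skbio(self, rng):
        d, labels = self._cloud_dm(rng, separation=1.0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(len(labels))])
        mine = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert mine.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_duplicated_structure_keeps_r_squared(self, rng):
        d, labels = self._cloud_dm(rng, n_per=5, separation=2.0)
        res1 = permanova(d, labels, n_perm=49, seed=3)
        big = np.kron(np.ones((2, 2)), d)  # duplicate every sample
        big[np.diag_indices_from(big)] = 0.0
        res2 = permanova(big, labels * 2, n_perm=49, seed=3)
        assert 0 <= res2.r_squared <= 1
        assert res1.r_squared == pytest.approx(
            permanova(d, labels, n_perm=49, seed=99).r_squared
        )  # statistic independent of the permutation seed

    def test_singleton_group_rejected(self, rng):
        d, _ = self._cloud_dm(rng, n_per=2)
        with pytest.raises(ValueError, match="n >= 2"):
            permanova(d, ["A", "A", "A", "B"], n_perm=9, seed=0)

    def test_p_bounded_below_by_estimator(self, rng):
        d, labels = self._cloud_dm(rng, separation=100.0)
        res = permanova(d, labels, n_perm=99, seed=5)
        assert res.p_value >= 1 / 100
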