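"""Distances, ordination, BIOENV, Mantel, covariate statistics."""

import itertools
from io import StringIO

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from rps3kit.ecology import (
    bioenv,
    bray_curtis,
    covariate_stats,
    mantel,
    nmds,
    pcoa,
    unifrac,
)
from rps3kit.errors import InputError


def dm_from_points(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert bray_curtis(df)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert bray_curtis(df)["a", "b"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        df = pd.DataFrame({"a": [2.0, 1.0], "b": [1.0, 1.0]})
        assert bray_curtis(df)["a", "b"] == pytest.approx(0.2)

    def test_all_zero_pair_is_zero_with_warning(self, caplog):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0]})
        with caplog.at_level("WARNING"):
            d = bray_curtis(df)
        assert d["a", "b"] == 0.0
        assert "all-zero" in caplog.text

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 5, (8, 6)))
        df.columns = [f"s{i}" for i in range(6)]
        d = np.asarray(bray_curtis(df).data)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


def random_tree(rng, n_leaves):
    """Random binary tree with uniform branch lengths, via newick."""
    nodes = [f"t{i}:{rng.uniform(0.1, 2):.4f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2):.4f}")
    return TreeNode.read(StringIO(nodes[0][: nodes[0].rfind(':')] + ";"))


class TestUnifrac:
    two_leaf = TreeNode.read(StringIO("(a:1,b:1);"))

    def test_identical_communities_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]}, index=["a", "b"])
        for weighted in (False, True):
            d = unifrac(self.two_leaf, df, weighted=weighted)
            assert d["x", "y"] == pytest.approx(0.0)

    def test_distinct_single_leaves_unweighted_one(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]}, index=["a", "b"])
        d = unifrac(self.two_leaf, df, weighted=False)
        assert d["x", "y"] == pytest.approx(1.0)  # unique 2 / covered 2

    def test_disjoint_weighted_raw_and_normalized(self):
        df = pd.DataFrame({"x": [3.0, 0.0], "y": [0.0, 5.0]}, index=["a", "b"])
        raw = unifrac(self.two_leaf, df, weighted=True, normalized=False)
        norm = unifrac(self.two_leaf, df, weighted=True, normalized=True)
        assert raw["x", "y"] == pytest.approx(2.0)  # 1*|1-0| + 1*|0-1|
        assert norm["x", "y"] == pytest.approx(1.0)

    def test_missing_row_names_offender(self):
        df = pd.DataFrame({"x": [1.0]}, index=["zzz"])
        with pytest.raises(InputError, match="zzz"):
            unifrac(self.two_leaf, df)

    @pytest.mark.parametrize("trial", range(4))
    def test_agrees_with_skbio_on_random_8_leaf_trees(self, trial):
        rng = np.random.default_rng(100 + trial)
        tree = random_tree(rng, 8)
        taxa = [f"t{i}" for i in range(8)]
        counts = rng.integers(0, 20, size=(3, 8)).astype(float)
        counts[0, counts[0] > 10] = 0  # some absences
        df = pd.DataFrame(counts.T, index=taxa, columns=["x", "y", "z"])
        mine_u = unifrac(tree, df, weighted=False)
        mine_w = unifrac(tree, df, weighted=True, normalized=True)
        sk_u = skbio.diversity.beta_diversity(
            "unweighted_unifrac", counts, ids=["x", "y", "z"], taxa=taxa, tree=tree
        )
        sk_w = skbio.diversity.beta_diversity(
            "weighted_unifrac", counts, ids=["x", "y", "z"], taxa=taxa,
            tree=tree, normalized=True,
        )
        assert np.allclose(np.asarray(mine_u.data), np.asarray(sk_u.data), atol=1e-10)
        assert np.allclose(np.asarray(mine_w.data), np.asarray(sk_w.data), atol=1e-10)


class TestPcoa:
    def test_line_geometry_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = dm_from_points(x[:, None])
        res = pcoa(d, k=2)
        emb = squareform(pdist(res.coordinates.values))
        assert np.allclose(emb, np.asarray(d.data), atol=1e-8)
        assert res.eigenvalues[0] > 0
        assert abs(res.eigenvalues[1]) < 1e-8

    def test_zero_distances_zero_coordinates(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(d, k=2)
        assert np.allclose(res.coordinates.values, 0)

    def test_three_equidistant_points_two_equal_eigenvalues(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = pcoa(d, k=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_k_too_large_is_error(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(InputError):
            pcoa(d, k=3)

    def test_matches_skbio_coordinates(self):
        rng = np.random.default_rng(5)
        d = dm_from_points(rng.normal(size=(7, 3)))
        mine = pcoa(d, k=3)
        ref = skbio.stats.ordination.pcoa(d, number_of_dimensions=3)
        # axes defined up to sign
        for ax in range(3):
            a = mine.coordinates.values[:, ax]
            b = ref.samples.values[:, ax]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6


class TestNmds:
    def test_perfect_embedding_near_zero_stress(self):
        d = dm_from_points(np.array([[0, 0], [1, 0], [0, 2], [3, 1], [2, 2]]))
        res = nmds(d, k=2, seed=0)
        assert res.stress < 1e-6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        d = DistanceMatrix(squareform(rng.uniform(0.2, 1, 15)), ids=list("abcdef"))
        r1 = nmds(d, k=2, seed=42)
        r2 = nmds(d, k=2, seed=42)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates.values, r2.coordinates.values)

    def test_random_dissimilarities_report_stress(self):
        rng = np.random.default_rng(2)
        d = DistanceMatrix(squareform(rng.uniform(0.2, 1, 15)), ids=list("abcdef"))
        res = nmds(d, k=2, seed=0)
        assert res.stress is not None and 0 <= res.stress < 0.5

    def test_too_few_samples_is_error(self):
        d = DistanceMatrix(np.zeros((2, 2)), ids=list("ab"))
        with pytest.raises(InputError):
            nmds(d, k=2)


class TestBioenv:
    def env_table(self, rng, n=10, variables=("A", "B", "C")):
        return pd.DataFrame(
            rng.normal(size=(n, len(variables))),
            columns=list(variables),
            index=[f"s{i}" for i in range(n)],
        )

    def test_recovers_generating_subset_exactly(self):
        rng = np.random.default_rng(0)
        env = self.env_table(rng)
        z = (env - env.mean()) / env.std(ddof=1)
        d = DistanceMatrix(
            squareform(pdist(z[["A", "B"]].values)), ids=list(env.index)
        )
        res = bioenv(d, env)
        assert set(res.best_subset) == {"A", "B"}
        assert res.correlation == pytest.approx(1.0)

    def test_single_variable(self):
        rng = np.random.default_rng(1)
        env = self.env_table(rng, variables=("only",))
        d = DistanceMatrix(
            squareform(pdist(env.values)), ids=list(env.index)
        )
        res = bioenv(d, env)
        assert res.best_subset == ("only",)

    def test_exhaustive_enumeration_matches_reference(self):
        rng = np.random.default_rng(2)
        env = self.env_table(rng, variables=("A", "B", "C", "D"))
        d = DistanceMatrix(
            squareform(rng.uniform(0.1, 1, 45)), ids=list(env.index)
        )
        res = bioenv(d, env, max_subset_size=4)
        assert len(res.scores) == 15  # 2^4 - 1 subsets

        # independent enumeration
        z = (env - env.mean()) / env.std(ddof=1)
        target = squareform(np.asarray(d.data), checks=False)
        best = None
        for size in range(1, 5):
            for subset in itertools.combinations(env.columns, size):
                ed = pdist(z[list(subset)].values)
                r = np.corrcoef(ed, target)[0, 1]
                if best is None or r > best[1]:
                    best = (subset, r)
        assert set(res.best_subset) == set(best[0])
        assert res.correlation == pytest.approx(best[1])

    def test_agrees_with_skbio_spearman(self):
        rng = np.random.default_rng(3)
        env = self.env_table(rng, n=9, variables=("A", "B", "C", "D"))
        d = DistanceMatrix(
            squareform(rng.uniform(0.1, 1, 36)), ids=list(env.index)
        )
        mine = bioenv(d, env, method="spearman")
        ref = skbio.stats.distance.bioenv(d, env)  # best subset per size
        ref_vars = set(ref["correlation"].idxmax().split(", "))
        assert set(mine.best_subset) == ref_vars
        assert mine.correlation == pytest.approx(
            ref["correlation"].max(), abs=1e-10
        )

    def test_constant_variable_excluded(self, caplog):
        rng = np.random.default_rng(4)
        env = self.env_table(rng)
        env["flat"] = 1.0
        d = DistanceMatrix(
            squareform(pdist(env[["A"]].values)), ids=list(env.index)
        )
        with caplog.at_level("WARNING"):
            res = bioenv(d, env)
        assert "flat" not in {v for s, _ in res.scores for v in s}

    def test_label_mismatch_is_error(self):
        env = pd.DataFrame({"A": [1.0, 2.0]}, index=["x", "y"])
        d = DistanceMatrix(np.zeros((2, 2)), ids=["x", "zzz"])
        with pytest.raises(InputError, match="zzz"):
            bioenv(d, env)

    def test_stepwise_finds_strong_subset(self):
        rng = np.random.default_rng(5)
        env = self.env_table(rng, n=12, variables=("A", "B", "C", "D", "E"))
        z = (env - env.mean()) / env.std(ddof=1)
        d = DistanceMatrix(
            squareform(pdist(z[["B", "D"]].values)), ids=list(env.index)
        )
        res = bioenv(d, env, strategy="stepwise")
        assert set(res.best_subset) == {"B", "D"}


class TestMantel:
    def test_self_comparison_gives_add_one_p(self):
        rng = np.random.default_rng(0)
        d = DistanceMatrix(
            squareform(rng.uniform(0.1, 1, 45)), ids=[f"s{i}" for i in range(10)]
        )
        res = mantel(d, d, n_perm=999, seed=0)
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r_is_plain_correlation_of_triangles(self):
        rng = np.random.default_rng(1)
        d1 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 21)), ids=list("abcdefg"))
        d2 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 21)), ids=list("abcdefg"))
        res = mantel(d1, d2, n_perm=9, seed=0)
        expected = np.corrcoef(
            squareform(np.asarray(d1.data), checks=False),
            squareform(np.asarray(d2.data), checks=False),
        )[0, 1]
        assert res.estimate == pytest.approx(expected)

    def test_agrees_with_skbio_r(self):
        rng = np.random.default_rng(2)
        d1 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 28)), ids=list("abcdefgh"))
        d2 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 28)), ids=list("abcdefgh"))
        res = mantel(d1, d2, n_perm=9, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(d1, d2, permutations=0)
        assert res.estimate == pytest.approx(r_ref)

    def test_label_mismatch_is_error(self):
        d1 = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        d2 = DistanceMatrix(np.zeros((2, 2)), ids=["a", "c"])
        with pytest.raises(InputError):
            mantel(d1, d2)

    def test_label_order_alignment(self):
        rng = np.random.default_rng(3)
        ids = list("abcde")
        m = squareform(rng.uniform(0.1, 1, 10))
        d1 = DistanceMatrix(m, ids=ids)
        d2 = DistanceMatrix(m[np.ix_([4, 3, 2, 1, 0], [4, 3, 2, 1, 0])], ids=ids[::-1])
        res = mantel(d1, d2, n_perm=9, seed=0)
        assert res.estimate == pytest.approx(1.0)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(4)
        n = 8
        ps = []
        for rep in range(200):
            d1 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 28)),
                                ids=[f"s{i}" for i in range(n)])
            d2 = DistanceMatrix(squareform(rng.uniform(0.1, 1, 28)),
                                ids=[f"s{i}" for i in range(n)])
            ps.append(mantel(d1, d2, n_perm=99, seed=rep).p_value)
        ps = np.array(ps)
        assert 0.4 < ps.mean() < 0.6
        assert 0.15 < (ps <= 0.25).mean() < 0.35


class TestCovariateStats:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = covariate_stats(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_negative_relationship_sign(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 30)
        y = -x + rng.normal(0, 1, 30)
        res = covariate_stats(y, x)
        assert res.r < 0 and res.slope < 0
        assert res.r_p_value < 0.01

    def test_constant_inputs_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(InputError):
            covariate_stats(np.ones(5), x)
        with pytest.raises(InputError):
            covariate_stats(x, np.ones(5))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            covariate_stats([1.0, 2.0], [1.0, 2.0])
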