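"""Metric feature vectors against hand examples and brute-force oracles."""
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylolandscape as pl
from oracles import (
    mask_to_side,
    oracle_branch_score,
    oracle_dd_path,
    oracle_kc_pair,
    oracle_path_edges,
    oracle_splits,
    scale_lengths,
)


class TestKendallColijn:
    def test_topological_vector(self, abc_tree):
        v = pl.kc_vector(abc_tree, 0.0)
        assert v.feature_names == ["A|B", "A|C", "B|C", "A", "B", "C"]
        assert np.array_equal(v.entries, [1, 0, 0, 1, 1, 1])

    def test_length_vector(self, abc_tree):
        v = pl.kc_vector(abc_tree, 1.0)
        assert np.array_equal(v.entries, [1, 0, 0, 1, 1, 2])

    def test_blend_is_convex_combination(self, abc_tree):
        v0 = pl.kc_vector(abc_tree, 0.0).entries
        v1 = pl.kc_vector(abc_tree, 1.0).entries
        vh = pl.kc_vector(abc_tree, 0.3).entries
        assert np.allclose(vh, 0.7 * v0 + 0.3 * v1)

    def test_unrooted_tree_rejected(self):
        star = pl.trees_from_string("(A,B,C);")[0]
        with pytest.raises(pl.UnrootedTreeError):
            pl.kc_vector(star, 0.0)

    def test_lambda_without_lengths_rejected(self):
        t = pl.trees_from_string("((A,B),C);")[0]
        with pytest.raises(pl.MissingBranchLengthsError):
            pl.kc_vector(t, 0.5)
        # topology-only blend is fine
        assert pl.kc_vector(t, 0.0).entries[0] == 1

    def test_lambda_out_of_range(self, abc_tree):
        with pytest.raises(ValueError):
            pl.kc_vector(abc_tree, 1.5)

    def test_topology_part_invariant_under_rescaling(self, rng):
        for _ in range(100):
            t = pl.random_tree(10, rng)
            s = scale_lengths(t, 7.3)
            assert np.array_equal(
                pl.kc_vector(t, 0.0).entries, pl.kc_vector(s, 0.0).entries
            )

    def test_matches_mrca_oracle(self, rng):
        """m and M entries agree exactly with ancestor-set MRCA values."""
        from itertools import combinations

        for _ in range(30):
            n = int(rng.integers(4, 15))
            t = pl.random_tree(n, rng)
            labels = sorted(f"t{i+1}" for i in range(n))
            m = pl.kc_vector(t, 0.0).entries
            M = pl.kc_vector(t, 1.0).entries
            for p, (a, b) in enumerate(combinations(labels, 2)):
                em, eM = oracle_kc_pair(t, a, b)
                assert m[p] == em
                assert M[p] == eM

    def test_multifurcation_below_root_accepted(self):
        t = pl.trees_from_string("((A,B,C),D);")[0]
        v = pl.kc_vector(t, 0.0)
        # all pairs among A,B,C share the depth-1 multifurcation as MRCA
        assert np.array_equal(v.entries, [1, 1, 0, 1, 0, 0, 1, 1, 1, 1])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(n=st.integers(2, 50), seed=st.integers(0, 2**31 - 1))
    def test_vector_length(self, n, seed):
        v = pl.kc_vector(pl.random_tree(n, seed), 0.0)
        assert v.entries.shape == (n * (n - 1) // 2 + n,)


class TestPathDifference:
    def test_three_tip_example(self):
        t = pl.trees_from_string("((A,B),C);")[0]
        assert np.array_equal(pl.path_vector(t).entries, [2, 3, 3])

    def test_two_tip_tree(self):
        t = pl.trees_from_string("(A,B);")[0]
        assert np.array_equal(pl.path_vector(t).entries, [2])

    def test_caterpillar_differs_from_balanced(self):
        cat = pl.trees_from_string(
            "(((((((A,B),C),D),E),F),G),H);")[0]
        bal = pl.trees_from_string(
            "(((A,B),(C,D)),((E,F),(G,H)));")[0]
        assert not np.array_equal(
            pl.path_vector(cat).entries, pl.path_vector(bal).entries
        )

    def test_matches_bfs_oracle(self, rng):
        from itertools import combinations

        for _ in range(20):
            n = int(rng.integers(4, 12))
            t = pl.random_tree(n, rng)
            labels = sorted(f"t{i+1}" for i in range(n))
            v = pl.path_vector(t).entries
            for p, (a, b) in enumerate(combinations(labels, 2)):
                assert v[p] == oracle_path_edges(t, a, b)


class TestDescendantMetrics:
    def test_abouheif_three_tip(self):
        t = pl.trees_from_string("((A,B),C);")[0]
        assert np.array_equal(pl.abouheif_vector(t).entries, [2, 4, 4])

    def test_abouheif_star(self):
        t = pl.trees_from_string("(A,B,C);")[0]
        assert np.array_equal(pl.abouheif_vector(t).entries, [3, 3, 3])

    def test_sum_dd_three_tip(self):
        # path A--C crosses the cherry parent (2 children) and the root
        # (2 children): summed child counts 2 + 2 = 4
        t = pl.trees_from_string("((A,B),C);")[0]
        assert np.array_equal(pl.sum_dd_vector(t).entries, [2, 4, 4])

    def test_sum_dd_star_and_two_tips(self):
        star = pl.trees_from_string("(A,B,C);")[0]
        assert np.array_equal(pl.sum_dd_vector(star).entries, [3, 3, 3])
        two = pl.trees_from_string("(A,B);")[0]
        assert np.array_equal(pl.sum_dd_vector(two).entries, [2])

    @pytest.mark.parametrize("op,fn", [("prod", pl.abouheif_vector),
                                       ("sum", pl.sum_dd_vector)])
    def test_matches_path_walk_oracle(self, op, fn, rng):
        from itertools import combinations

        for _ in range(15):
            n = int(rng.integers(4, 12))
            t = pl.random_tree(n, rng)
            labels = sorted(f"t{i+1}" for i in range(n))
            v = fn(t).entries
            for p, (a, b) in enumerate(combinations(labels, 2)):
                assert v[p] == oracle_dd_path(t, a, b, op)

    def test_topological_invariance(self, rng):
        t = pl.random_tree(8, rng)
        s = scale_lengths(t, 0.01)
        assert np.array_equal(pl.abouheif_vector(t).entries,
                              pl.abouheif_vector(s).entries)
        assert np.array_equal(pl.sum_dd_vector(t).entries,
                              pl.sum_dd_vector(s).entries)


class TestBranchScore:
    def test_identical_trees_distance_zero(self, abc_tree):
        coll = pl.trees_from_string("((A:1,B:1):1,C:2);\n((A:1,B:1):1,C:2);")
        assert pl.distance_matrix(coll, "branch_score").values[0, 1] == 0

    def test_single_length_change_gives_delta(self):
        coll = pl.trees_from_string(
            "((A:1,B:1):1,C:2);\n((A:1,B:1):1,C:2.75);")
        assert pl.distance_matrix(coll, "branch_score").values[0, 1] == \
            pytest.approx(0.75)

    def test_missing_lengths_rejected(self):
        t = pl.trees_from_string("((A,B),C);")[0]
        with pytest.raises(pl.MissingBranchLengthsError):
            pl.branch_score_vector(t)

    def test_split_map_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            t = pl.random_tree(8, rng)
            labels = sorted(f"t{i+1}" for i in range(8))
            mine = {
                mask_to_side(mask, labels): length
                for mask, length in pl.split_lengths(t).items()
            }
            ref = oracle_splits(t, include_trivial=True)
            assert set(mine) == set(ref)
            for s in ref:
                assert mine[s] == pytest.approx(ref[s], abs=1e-12)

    def test_distance_matches_split_union_oracle(self, rng):
        import dendropy

        tns = dendropy.TaxonNamespace()
        for _ in range(10):
            t1 = pl.random_tree(8, rng, taxon_namespace=tns)
            t2 = pl.random_tree(8, rng, taxon_namespace=tns)
            coll = pl.TreeCollection([t1, t2])
            mine = pl.distance_matrix(coll, "branch_score").values[0, 1]
            assert mine == pytest.approx(oracle_branch_score(t1, t2), abs=1e-9)


def test_branch_score_and_rf_match_phangorn(tmp_path, rng):
    """Cross-check against the R reference implementations (KF.dist, RF.dist)."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    trees = [pl.random_tree(10, rng, taxon_namespace=tns) for _ in range(6)]
    coll = pl.TreeCollection(trees)
    p = tmp_path / "trees.nwk"
    pl.write_trees(coll, p)
    script = (
        f'suppressMessages(library(phangorn)); tr <- read.tree("{p}"); '
        'kf <- as.matrix(KF.dist(tr)); rf <- as.matrix(RF.dist(tr)); '
        'cat(sprintf("%.12f", kf[lower.tri(kf)]), "\\n"); '
        'cat(rf[lower.tri(rf)], "\\n")'
    )
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    lines = [l for l in res.stdout.strip().splitlines() if l.strip()]
    kf_ref = np.array([float(x) for x in lines[0].split()])
    rf_ref = np.array([float(x) for x in lines[1].split()])
    kf_mine = pl.distance_matrix(coll, "branch_score").condensed
    rf_mine = pl.distance_matrix(coll, "rf").condensed
    # R's lower.tri column-major order equals condensed row-major order
    assert np.abs(np.sort(kf_mine) - np.sort(kf_ref)).max() < 1e-9
    assert np.array_equal(np.sort(rf_mine), np.sort(rf_ref))


def test_identical_trees_have_identical_vectors(rng):
    t = pl.random_tree(9, rng)
    u = t.clone(depth=1)
    for fn in (lambda x: pl.kc_vector(x, 0.4), pl.path_vector,
               pl.abouheif_vector, pl.sum_dd_vector):
        assert np.array_equal(fn(t).entries, fn(u).entries)


def test_vectorizer_estimator(random_collection):
    vec = pl.TreeVectorizer(metric="kc", lam=0.25)
    assert vec.get_params() == {"metric": "kc", "lam": 0.25}
    X = vec.fit_transform(random_collection)
    n = random_collection.n_tips
    assert X.shape == (len(random_collection), n * (n - 1) // 2 + n)
    X2, names = pl.collection_vectors(random_collection, "kc", 0.25)
    assert np.array_equal(X, X2)
    assert vec.feature_names_ == names
    # transform of the same collection reproduces fit_transform
    assert np.array_equal(vec.transform(random_collection), X)
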