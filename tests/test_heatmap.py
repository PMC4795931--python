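import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genesetnet.heatmap import (
    average_linkage,
    build_binary_matrix,
    cluster_rows,
    euclidean_distances,
    export_matrix,
    matrix_from_file,
)
from genesetnet.types import GenesetnetError

from .oracles import upgma_heights_naive


class TestBinaryMatrix:
    def test_identity_pattern(self):
        m = build_binary_matrix([("g1", "t1"), ("g2", "t2")])
        assert list(m.index) == ["g1", "g2"]
        assert m.to_numpy().tolist() == [[1, 0], [0, 1]]

    def test_duplicate_pairs_collapse(self):
        m1 = build_binary_matrix([("g1", "t1"), ("g1", "t1")])
        m2 = build_binary_matrix([("g1", "t1")])
        pd.testing.assert_frame_equal(m1, m2)

    def test_no_all_zero_rows(self):
        m = build_binary_matrix([("g1", "t1"), ("g2", "t1")])
        assert (m.sum(axis=1) > 0).all()


class TestDistances:
    def test_identical_profiles_zero(self):
        m = pd.DataFrame([[1, 0], [1, 0]], index=["a", "b"])
        assert euclidean_distances(m)[0, 1] == 0.0

    def test_disjoint_singletons(self):
        m = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["a", "b"])
        assert euclidean_distances(m)[0, 1] == pytest.approx(np.sqrt(2))

    def test_opposite_profiles(self):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"])
        assert euclidean_distances(m)[0, 1] == pytest.approx(np.sqrt(2))

    def test_single_row_errors(self):
        with pytest.raises(GenesetnetError):
            euclidean_distances(pd.DataFrame([[1, 0]], index=["a"]))


def _square(vals):
    return np.asarray(vals, dtype=float)


class TestUPGMA:
    def test_three_leaf_worked_example(self):
        d = _square([[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        dg = average_linkage(d)
        assert [(i, j) for i, j, _, _ in dg.merges] == [(0, 1), (3, 2)]
        assert [h for _, _, h, _ in dg.merges] == pytest.approx([1.0, 4.0])

    def test_four_leaf_size_weighted_average(self):
        d = _square([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 8],
            [8, 8, 8, 0],
        ])
        dg = average_linkage(d)
        assert dg.merges[0][:3] == (0, 1, 2.0)
        # d((01), 2) must stay (8+8)/2 = 8 after the first merge
        assert dg.merges[1][2] == pytest.approx(8.0)

    def test_all_equal_distances_merge_by_index(self):
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        dg = average_linkage(d)
        assert dg.merges[0][:2] == (0, 1)
        assert dg.merges[1][:2] == (4, 2)  # cluster {0,1} then leaf 2
        assert dg.leaf_order == [0, 1, 2, 3]

    @pytest.mark.parametrize("seed", range(25))
    def test_heights_match_recompute_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a = rng.uniform(0.1, 10, size=(n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        got = [h for _, _, h, _ in average_linkage(d).merges]
        expected = upgma_heights_naive(d.tolist())
        assert got == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_scipy_linkage(self, seed):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        n = 7
        a = rng.uniform(0.1, 10, size=(n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        got = sorted(h for _, _, h, _ in average_linkage(d).merges)
        ref = sorted(linkage(squareform(d), method="average")[:, 2])
        assert got == pytest.approx(ref, abs=1e-9)

    def test_row_permutation_equivariance(self):
        # continuous distances are generically tie-free, so the tree is
        # permutation-equivariant (with ties only the tie-break convention
        # may reshape it)
        rng = np.random.default_rng(7)
        n = 6
        a = rng.uniform(1, 10, size=(n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"g{i}" for i in range(n)]
        dg = average_linkage(d, labels=labels)
        perm = [3, 0, 5, 1, 4, 2]
        dp = d[np.ix_(perm, perm)]
        dgp = average_linkage(dp, labels=[labels[i] for i in perm])
        assert sorted(h for *_, h, _ in dg.merges) == pytest.approx(
            sorted(h for *_, h, _ in dgp.merges), abs=1e-12)
        assert set(map(frozenset, _leaf_clusters(dg, labels))) == set(
            map(frozenset, _leaf_clusters(dgp, [labels[i] for i in perm])))

    def test_identical_profiles_adjacent_in_leaf_order(self):
        m = pd.DataFrame(
            [[1, 0, 1], [0, 1, 0], [1, 0, 1], [0, 0, 1]],
            index=["a", "b", "c", "d"],
        )
        order = cluster_rows(m).ordered_labels()
        assert abs(order.index("a") - order.index("c")) == 1

    def test_newick_is_parseable_ultrametric(self):
        d = _square([[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        nwk = average_linkage(d, labels=["a", "b", "c"]).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        depths = tree.depths()
        leaf_depths = [v for k, v in depths.items() if k.name]
        assert leaf_depths == pytest.approx([2.0, 2.0, 2.0])


def _leaf_clusters(dg, labels):
    """Sets of labels merged at each internal node (tree shape fingerprint)."""
    members = {i: {labels[i]} for i in range(dg.n_leaves)}
    out = []
    for i, j, _, new in dg.merges:
        members[new] = members[i] | members[j]
        out.append(members[new])
    return out


class TestExport:
    @pytest.fixture
    def matrix(self):
        return build_binary_matrix(
            [("g2", "t1"), ("g1", "t2"), ("g3", "t1"), ("g3", "t2")])

    def test_sort_by_name(self, matrix):
        out = export_matrix(matrix, sort="name")
        assert list(out.index) == ["g1", "g2", "g3"]

    def test_sort_none_keeps_input_order(self, matrix):
        out = export_matrix(matrix, sort="none")
        assert list(out.index) == ["g2", "g1", "g3"]

    def test_sort_cluster_uses_leaf_order(self, matrix):
        dg = cluster_rows(matrix)
        out = export_matrix(matrix, dg, sort="cluster")
        assert list(out.index) == dg.ordered_labels()

    def test_tsv_round_trip_and_coercion_warning(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tt1\tt2\ng1\t1\t0\ng2\t0\t2\n")
        m = matrix_from_file(p)
        assert m.loc["g2", "t2"] == 1  # nonzero coerced to 1

    def test_image_written(self, matrix, tmp_path):
        img = tmp_path / "h.png"
        export_matrix(matrix, sort="name", image_path=img)
        assert img.stat().st_size > 0
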