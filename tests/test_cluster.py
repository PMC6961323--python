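import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import peddrugsafe as pds
from peddrugsafe.cluster import DegenerateInputWarning, hierarchy_to_newick


def block_binmat(block_sizes, dx_per_block):
    """Disjoint diagnosis blocks: drugs in block b are associated with
    exactly the b-th diagnosis slice."""
    n_dx = dx_per_block * len(block_sizes)
    rows, names, truth = [], [], []
    for b, size in enumerate(block_sizes):
        row = np.zeros(n_dx, dtype=int)
        row[b * dx_per_block : (b + 1) * dx_per_block] = 1
        for i in range(size):
            rows.append(row)
            names.append(f"B{b}_{i}")
            truth.append(b)
    return (
        pd.DataFrame(rows, index=names, columns=[f"G{j}" for j in range(n_dx)]),
        np.array(truth),
    )


@pytest.fixture
def two_block_distmat():
    mat, truth = block_binmat([6, 6], 5)
    return pds.distance_matrix(mat), truth


class TestClusterDrugs:
    def test_recovers_two_disjoint_blocks(self, two_block_distmat):
        dist, truth = two_block_distmat
        part = pds.cluster_drugs(dist, k=2, seed=0)
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_partition_total_with_near_maximal_k(self, two_block_distmat):
        dist, _ = two_block_distmat
        # more clusters than distinct rows: deterministic degenerate split
        with pytest.warns(DegenerateInputWarning):
            part = pds.cluster_drugs(dist, k=len(dist) - 1, seed=0)
        assert set(part.labels.index) == set(dist.index)
        assert (part.labels.value_counts() >= 1).all()
        assert part.labels.nunique() == len(dist) - 1

    def test_same_seed_same_partition(self, two_block_distmat):
        dist, _ = two_block_distmat
        a = pds.cluster_drugs(dist, k=2, seed=123)
        b = pds.cluster_drugs(dist, k=2, seed=123)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_invalid_k_rejected(self, two_block_distmat):
        dist, _ = two_block_distmat
        with pytest.raises(ValueError):
            pds.cluster_drugs(dist, k=1)
        with pytest.raises(ValueError):
            pds.cluster_drugs(dist, k=len(dist))

    def test_degenerate_identical_rows_warn_but_split(self):
        mat = pd.DataFrame(0, index=[f"D{i}" for i in range(6)], columns=list("abc"))
        dist = pds.distance_matrix(mat)
        with pytest.warns(DegenerateInputWarning):
            part = pds.cluster_drugs(dist, k=3, seed=0)
        assert part.labels.nunique() == 3

    def test_pam_method_recovers_blocks(self, two_block_distmat):
        dist, truth = two_block_distmat
        part = pds.cluster_drugs(dist, k=2, seed=0, method="pam")
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0


class TestBootstrapStability:
    def test_perfect_pairs_fully_stable(self):
        mat, _ = block_binmat([2, 2], 4)
        dist = pds.distance_matrix(mat)
        s = pds.bootstrap_stability(dist, k=2, B=2, seed=0)
        assert s == 1.0

    def test_separated_blocks_highly_stable(self, two_block_distmat):
        dist, _ = two_block_distmat
        s = pds.bootstrap_stability(dist, k=2, B=20, seed=1)
        assert s >= 0.9

    def test_deterministic_under_seed(self, two_block_distmat):
        dist, _ = two_block_distmat
        a = pds.bootstrap_stability(dist, k=3, B=10, seed=7)
        b = pds.bootstrap_stability(dist, k=3, B=10, seed=7)
        assert a == b

    def test_bounded(self, two_block_distmat):
        dist, _ = two_block_distmat
        for k in (2, 3, 5):
            assert 0.0 <= pds.bootstrap_stability(dist, k, B=5, seed=0) <= 1.0


class TestSelectK:
    def test_single_candidate_returned(self, two_block_distmat):
        dist, _ = two_block_distmat
        cfg = pds.ClusteringConfig(k_min=3, k_max=3, B=3, seed=0)
        k, profile = pds.select_k(dist, cfg)
        assert k == 3 and len(profile) == 1

    def test_finds_planted_block_count(self):
        mat, _ = block_binmat([8, 8, 8], 6)
        dist = pds.distance_matrix(mat)
        cfg = pds.ClusteringConfig(k_min=2, k_max=6, B=10, seed=4)
        k, profile = pds.select_k(dist, cfg)
        assert k == 3
        assert profile.loc[profile["k"] == 3, "mean_jaccard"].iloc[0] == 1.0

    def test_tie_breaks_to_smallest_k(self, monkeypatch):
        dist = pds.distance_matrix(block_binmat([5, 5], 4)[0])
        monkeypatch.setattr(pds.cluster, "bootstrap_stability", lambda *a, **kw: 0.5)
        cfg = pds.ClusteringConfig(k_min=2, k_max=5, B=2, seed=0)
        k, _ = pds.select_k(dist, cfg)
        assert k == 2

    def test_invalid_range_rejected(self, two_block_distmat):
        dist, _ = two_block_distmat
        with pytest.raises(ValueError):
            pds.select_k(dist, pds.ClusteringConfig(k_min=2, k_max=len(dist), B=2))


class TestKernelDiagnoses:
    def test_union_intersection_and_empty(self):
        mat = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 0]],
            index=["d1", "d2", "d3"],
            columns=["a", "b", "c"],
        )
        part = pds.DrugClustering(
            labels=pd.Series([1, 1, 2], index=mat.index, name="cluster_id"), k=2
        )
        union = pds.kernel_diagnoses(part, mat, min_share=0.0)
        assert union[1] == {"a", "b"}
        assert union[2] == frozenset()  # no-association cluster
        inter = pds.kernel_diagnoses(part, mat, min_share=1.0)
        assert inter[1] == frozenset()


class TestHierarchy:
    def test_identical_kernels_merge_at_zero(self):
        kernels = {1: frozenset("ab"), 2: frozenset("ab")}
        Z, ids = pds.cluster_hierarchy(kernels)
        assert ids == [1, 2]
        assert Z[0, 2] == 0.0

    def test_sharing_pair_merges_first(self):
        # pairwise Jaccard by hand: d(1,2)=1-3/5=0.4; d(1,3)=d(2,3)=1
        kernels = {
            1: frozenset("abcd"),
            2: frozenset("abce"),
            3: frozenset("xyz"),
        }
        Z, ids = pds.cluster_hierarchy(kernels)
        first = {ids[int(Z[0, 0])], ids[int(Z[0, 1])]}
        assert first == {1, 2}
        assert Z[0, 2] == pytest.approx(0.4)

    def test_linkage_choice_irrelevant_for_equidistant_inputs(self):
        kernels = {1: frozenset("a"), 2: frozenset("b"), 3: frozenset("c")}
        Za, _ = pds.cluster_hierarchy(kernels, linkage="single")
        Zb, _ = pds.cluster_hierarchy(kernels, linkage="average")
        np.testing.assert_allclose(Za[:, 2], Zb[:, 2])

    def test_newick_rendering_contains_all_leaves(self):
        kernels = {1: frozenset("ab"), 2: frozenset("bc"), 3: frozenset("xy")}
        Z, ids = pds.cluster_hierarchy(kernels)
        nwk = hierarchy_to_newick(Z, [f"c{i}" for i in ids])
        assert nwk.endswith(";")
        for i in ids:
            assert f"c{i}:" in nwk


class TestEmbed2D:
    def test_equidistant_triple_embeds_equilateral(self):
        dist = pd.DataFrame(
            1 - np.eye(3), index=list("ABC"), columns=list("ABC")
        )
        xy = pds.embed_2d(dist)
        d = lambda a, b: np.linalg.norm(xy.loc[a] - xy.loc[b])
        assert d("A", "B") == pytest.approx(d("B", "C"), abs=1e-9)
        assert d("A", "B") == pytest.approx(d("A", "C"), abs=1e-9)

    def test_blocks_separate_in_embedding(self):
        mat, truth = block_binmat([6, 6], 5)
        xy = pds.embed_2d(pds.distance_matrix(mat)).to_numpy()
        within = np.linalg.norm(xy[0] - xy[1])
        between = np.linalg.norm(xy[0] - xy[-1])
        assert between > within

    def test_duplicate_rows_coincide(self):
        mat, _ = block_binmat([3, 3], 4)
        xy = pds.embed_2d(pds.distance_matrix(mat))
        np.testing.assert_allclose(
            xy.loc["B0_0"].to_numpy(), xy.loc["B0_1"].to_numpy(), atol=1e-6
        )

    def test_too_small_matrix_rejected(self):
        dist = pd.DataFrame(1 - np.eye(2), index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            pds.embed_2d(dist)

    def test_deterministic(self):
        mat, _ = block_binmat([4, 4], 3)
        dist = pds.distance_matrix(mat)
        pd.testing.assert_frame_equal(pds.embed_2d(dist), pds.embed_2d(dist))
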