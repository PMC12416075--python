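import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from larvascreen import (
    hcluster,
    pearson_matrix,
    subcluster_correlation,
    to_newick,
)
from larvascreen.cluster import Dendrogram, export_heatmap_tables
from larvascreen.errors import ConfigurationError, InsufficientDataError


def brute_force_complete_linkage_heights(values: np.ndarray) -> list[float]:
    """Independent O(n^3) agglomeration: at each step merge the pair of
    clusters whose maximum pairwise leaf distance is smallest."""
    n = len(values)
    base = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            base[i, j] = np.sqrt(((values[i] - values[j]) ** 2).sum())
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(base[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def _frame(values, labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"t{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=labels,
                        columns=[f"b{j}" for j in range(values.shape[1])])


class TestPearsonMatrix:
    def test_self_correlation_unit_diagonal(self, rng):
        corr = pearson_matrix(_frame(rng.normal(0, 1, (4, 6))))
        assert (np.diag(corr.to_numpy()) == 1.0).all()
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_row_and_negated_row(self):
        row = np.array([1.0, 2.0, 5.0, -1.0])
        corr = pearson_matrix(_frame([row, -row]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula_on_fixed_matrix(self):
        values = np.array(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 5.0, 3.0], [9.0, -1.0, 0.0, 2.0]]
        )
        corr = pearson_matrix(_frame(values))
        for i in range(3):
            for j in range(3):
                x, y = values[i], values[j]
                expected = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum())
                    / np.sqrt(((y - y.mean()) ** 2).sum())
                )
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_is_missing_with_warning(self, caplog):
        values = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            corr = pearson_matrix(_frame(values))
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[1, 1] == 1.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_too_few_columns(self):
        with pytest.raises(InsufficientDataError):
            pearson_matrix(_frame(np.zeros((3, 1))))


class TestHCluster:
    def test_identical_rows_merge_at_height_zero(self):
        dend = hcluster(_frame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]]))
        assert dend.merges[0][2] == 0.0

    def test_one_dimensional_hand_example(self):
        # rows at 0, 1 and 10: first merge (0,1) at height 1, then the
        # complete-linkage distance to the far row is 10
        dend = hcluster(_frame([[0.0], [1.0], [10.0]], labels=["a", "b", "c"]))
        heights = [m[2] for m in dend.merges]
        assert heights == [1.0, 10.0]
        assert set(dend.leaves_under(3)) == {"a", "b"}

    def test_permuting_rows_preserves_height_multiset(self, rng):
        values = rng.normal(0, 5, (7, 4))
        frame = _frame(values)
        perm = rng.permutation(7)
        dend_a = hcluster(frame)
        dend_b = hcluster(frame.iloc[perm])
        assert sorted(m[2] for m in dend_a.merges) == pytest.approx(
            sorted(m[2] for m in dend_b.merges)
        )

    def test_duplicate_labels_rejected(self):
        frame = _frame(np.zeros((2, 2)), labels=["x", "x"])
        with pytest.raises(ConfigurationError):
            hcluster(frame)

    def test_heights_non_decreasing(self, rng):
        dend = hcluster(_frame(rng.normal(0, 5, (9, 4))))
        heights = [m[2] for m in dend.merges]
        assert heights == sorted(heights)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(2, 9)
            values = rng.normal(0, 5, (int(n), int(rng.integers(1, 5))))
            dend = hcluster(_frame(values))
            assert [m[2] for m in dend.merges] == brute_force_complete_linkage_heights(
                values
            )

    def test_matches_scipy_heights(self, rng):
        values = rng.normal(0, 5, (10, 4))
        dend = hcluster(_frame(values))
        Z = linkage(values, method="complete")
        np.testing.assert_allclose(
            sorted(m[2] for m in dend.merges), sorted(Z[:, 2]), rtol=1e-12
        )

    def test_cophenetic_dominates_euclidean(self, rng):
        # complete linkage: the merge height of any two leaves is at
        # least their pointwise distance
        values = rng.normal(0, 5, (8, 3))
        dend = hcluster(_frame(values))
        coph = squareform(cophenet(dend.to_scipy_linkage()))
        direct = squareform(pdist(values))
        assert (coph >= direct - 1e-12).all()


class TestSubclusterCorrelation:
    def test_two_identical_rows(self):
        frame = _frame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, -1.0, 0.0]])
        dend = hcluster(frame)
        node = dend.find_node({"t0", "t1"})
        assert subcluster_correlation(dend, frame, node) == pytest.approx(1.0)

    def test_row_and_negation(self):
        frame = _frame([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0], [50.0, 0.0, 0.0]])
        dend = hcluster(frame)
        node = dend.find_node({"t0", "t1"})
        assert subcluster_correlation(dend, frame, node) == pytest.approx(-1.0)

    def test_three_leaf_mean_of_pairwise(self, rng):
        values = rng.normal(0, 3, (3, 5))
        frame = _frame(values)
        dend = hcluster(frame)
        expected = np.mean(
            [
                np.corrcoef(values[i], values[j])[0, 1]
                for i, j in [(0, 1), (0, 2), (1, 2)]
            ]
        )
        assert subcluster_correlation(dend, frame, dend.root) == pytest.approx(expected)

    def test_singleton_rejected(self):
        frame = _frame(np.eye(3))
        dend = hcluster(frame)
        with pytest.raises(InsufficientDataError):
            subcluster_correlation(dend, frame, 0)


class TestExport:
    def test_leaf_order_is_permutation(self, rng):
        frame = _frame(rng.normal(0, 2, (6, 3)))
        dend = hcluster(frame)
        assert sorted(dend.leaf_order()) == sorted(frame.index)

    def test_newick_round_trip_preserves_heights(self, rng, tmp_path):
        frame = _frame(rng.normal(0, 2, (6, 3)))
        dend = hcluster(frame)
        paths = export_heatmap_tables(frame, dend, tmp_path / "cluster")
        tree = TreeNode.read(paths["tree"])
        # leaf-to-root distance in an ultrametric tree equals the root
        # merge height
        root_height = dend.merges[-1][2]
        for tip in tree.tips():
            assert tip.accumulate_to_ancestor(tree) == pytest.approx(
                root_height, abs=1e-9
            )
        ordered = pd.read_csv(paths["ordered_delta"], index_col=0)
        assert list(ordered.index) == dend.leaf_order()

    def test_two_leaf_cherry(self):
        frame = _frame([[0.0, 0.0], [3.0, 4.0]], labels=["a", "b"])
        dend = hcluster(frame)
        newick = to_newick(dend)
        tree = TreeNode.read(io.StringIO(newick))
        assert sorted(t.name for t in tree.tips()) == ["a", "b"]
        for tip in tree.tips():
            assert tip.length == pytest.approx(5.0)
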