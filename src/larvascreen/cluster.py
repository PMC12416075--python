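"""Hierarchical clustering and correlation of treatment profiles.

Treatment rows are clustered agglomeratively on Euclidean distance
with complete linkage, on the raw percentage-point deltas (no
standardization: the profile values already share a scale).  Ties in
the agglomeration are broken lexicographically by the smallest member
label so the tree is reproducible.  Similarity between treatments is
summarized by pairwise Pearson correlation across behaviors, and a
subtree's cohesion by the mean of all pairwise correlations among its
leaves.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ConfigurationError, InsufficientDataError
from .matrix import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomeration result.

    Leaves are nodes ``0 .. n-1`` in label order of the input; merge k
    creates node ``n + k``.  ``merges`` lists (node_a, node_b, height)
    with non-decreasing heights (complete linkage is monotone).
    """

    leaves: tuple[str, ...]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        a, b, _ = self.merges[node - self.n_leaves]
        return a, b

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def leaves_under(self, node: int) -> list[str]:
        kids = self.children(node)
        if kids is None:
            return [self.leaves[node]]
        return self.leaves_under(kids[0]) + self.leaves_under(kids[1])

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the drawn tree."""
        return self.leaves_under(self.root)

    def find_node(self, labels: set[str]) -> int | None:
        """Smallest node whose leaf set contains ``labels``, if any."""
        best = None
        for node in range(self.n_leaves + len(self.merges)):
            under = set(self.leaves_under(node))
            if labels <= under and (
                best is None or len(under) < len(set(self.leaves_under(best)))
            ):
                best = node
        return best

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix compatible with scipy.cluster.hierarchy."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + k] = size
            Z[k] = [a, b, h, size]
        return Z


def _as_delta(profiles) -> pd.DataFrame:
    if isinstance(profiles, ProfileMatrix):
        return profiles.delta
    return profiles


def pearson_matrix(profiles) -> pd.DataFrame:
    """Treatment x treatment Pearson correlation across behaviors.

    Rows with zero variance have no defined correlation; their entries
    are emitted as NaN with a warning (their diagonal too).
    """
    delta = _as_delta(profiles)
    if delta.shape[1] < 2:
        raise InsufficientDataError("need >=2 behavior columns")
    values = delta.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        logger.warning(
            "zero-variance profile rows: %s; correlations undefined",
            [delta.index[i] for i in np.flatnonzero(degenerate)],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    out = pd.DataFrame(corr, index=delta.index, columns=delta.index)
    # exact unit diagonal for the non-degenerate rows
    for i in np.flatnonzero(~degenerate):
        out.iloc[i, i] = 1.0
    return out


def hcluster(profiles) -> Dendrogram:
    """Complete-linkage agglomeration on Euclidean row distances.

    O(n^3), which is ample at screen scale (tens of treatments).
    Among equal-distance candidate pairs the one whose smallest member
    label (then the partner's smallest label) sorts first is merged.
    """
    delta = _as_delta(profiles)
    labels = [str(x) for x in delta.index]
    if len(labels) != len(set(labels)):
        raise ConfigurationError("duplicate treatment labels")
    if len(labels) < 2:
        raise InsufficientDataError("need >=2 rows to cluster")
    values = delta.to_numpy(dtype=float)
    n = len(labels)

    # pairwise Euclidean distances between current clusters (complete
    # linkage: distance between clusters = max pairwise leaf distance)
    base = np.sqrt(
        ((values[:, None, :] - values[None, :, :]) ** 2).sum(axis=2)
    )
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): base[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_key, best_d, best_tie = None, np.inf, None
        for key, d in dist.items():
            a, b = sorted(key, key=lambda k: min_label[k])
            tie = (min_label[a], min_label[b])
            if d < best_d or (d == best_d and tie < best_tie):
                best_key, best_d, best_tie = key, d, tie
        a, b = sorted(best_key)
        members = active.pop(a) + active.pop(b)
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        for other, other_members in active.items():
            d = max(
                base[i, j] for i in members for j in other_members
            )
            dist[frozenset((next_id, other))] = d
        active[next_id] = members
        min_label[next_id] = min(min_label[a], min_label[b])
        lo, hi = sorted((a, b), key=lambda k: min_label[k])
        merges.append((lo, hi, float(best_d)))
        next_id += 1
    return Dendrogram(tuple(labels), merges)


def subcluster_correlation(dend: Dendrogram, profiles, node: int) -> float:
    """Mean pairwise Pearson correlation among a node's leaf profiles.

    This is a transparent stand-in for the node "correlation values"
    that desktop clustering tools annotate on their trees; treat it as
    a cohesion score, not a reproduction of any particular tool.
    """
    leaves = dend.leaves_under(node)
    if len(leaves) < 2:
        raise InsufficientDataError("node has fewer than 2 leaves")
    delta = _as_delta(profiles)
    corr = pearson_matrix(delta.loc[leaves])
    vals = corr.to_numpy()
    iu = np.triu_indices(len(leaves), k=1)
    return float(np.nanmean(vals[iu]))


# -- Newick / table export -------------------------------------------------

def to_tree(dend: Dendrogram) -> TreeNode:
    """Ultrametric tree; child branch length = parent height - child height."""
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=label) for i, label in enumerate(dend.leaves)
    }
    for k, (a, b, h) in enumerate(dend.merges):
        parent = TreeNode(name=None)
        for child_id in (a, b):
            child = nodes[child_id]
            child.length = h - dend.height(child_id)
            parent.append(child)
        nodes[dend.n_leaves + k] = parent
    return nodes[dend.root]


def to_newick(dend: Dendrogram) -> str:
    buf = io.StringIO()
    to_tree(dend).write(buf, format="newick")
    return buf.getvalue()


def export_heatmap_tables(profiles, dend: Dendrogram, basepath) -> dict[str, str]:
    """Write the leaf-ordered delta matrix and the tree in Newick form.

    Returns the written paths keyed by artifact name.
    """
    delta = _as_delta(profiles)
    ordered = delta.loc[dend.leaf_order()]
    table_path = f"{basepath}_ordered.csv"
    tree_path = f"{basepath}_tree.nwk"
    try:
        ordered.to_csv(table_path, index_label="treatment")
        with open(tree_path, "w") as fh:
            fh.write(to_newick(dend))
    except OSError as exc:
        raise OSError(f"failed writing cluster artifacts at {basepath}: {exc}") from exc
    return {"ordered_delta": table_path, "tree": tree_path}
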