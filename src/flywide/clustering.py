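"""Hierarchical clustering of residual activity with held-out validation.

A Ward-linkage tree (Euclidean affinity) is built on the training frames of
the residual matrix. Every parent -> child split is then tested on held-out
frames: the child's intra-cluster variance is compared with that of
size-matched random subsets of the parent. A child is significant when its
held-out variance is smaller than the sampled subsets' (empirical p < 0.05),
so clusters can be significant at multiple nested scales simultaneously.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "ClusterNode",
    "ClusterTree",
    "ClusterSignificance",
    "build_tree",
    "intra_cluster_variance",
    "test_clusters",
    "size_distribution",
    "MAX_SAMPLES",
    "MIN_TESTABLE_SAMPLES",
]

MAX_SAMPLES = 100
#: Below 20 samples an empirical p < 0.05 is unattainable with the add-one
#: convention; such nodes are reported as untestable, not significant.
MIN_TESTABLE_SAMPLES = 20
ALPHA = 0.05


@dataclass
class ClusterNode:
    id: int
    members: np.ndarray
    children: tuple = ()  # node ids; empty for leaves
    parent: int | None = None
    height: float = 0.0

    @property
    def size(self) -> int:
        return self.members.size

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    nodes: dict
    root: int
    n_leaves: int

    def node(self, node_id: int) -> ClusterNode:
        return self.nodes[node_id]

    def internal_nodes(self):
        return [n for n in self.nodes.values() if not n.is_leaf]


@dataclass
class ClusterSignificance:
    """Held-out significance of one child cluster versus parent resamples."""

    node_id: int
    parent_id: int
    n_parent: int
    n_child: int
    n_samples: int
    child_variance: float
    sample_variances: np.ndarray = field(repr=False)
    p: float = 1.0
    significant: bool = False
    untestable_reason: str | None = None


def build_tree(residuals_train: np.ndarray) -> ClusterTree:
    """Agglomerative Ward tree on cells (rows), frames as features.

    Ties are broken deterministically by scipy's linkage given a fixed input
    order, so the tree depends on cell index order only through tie-breaks.
    """
    X = np.atleast_2d(np.asarray(residuals_train, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to build a cluster tree")
    Z = linkage(X, method="ward", metric="euclidean")
    nodes = {i: ClusterNode(id=i, members=np.array([i])) for i in range(n)}
    for k, (a, b, height, _) in enumerate(Z):
        a, b = int(a), int(b)
        nid = n + k
        members = np.sort(np.concatenate([nodes[a].members, nodes[b].members]))
        nodes[nid] = ClusterNode(id=nid, members=members, children=(a, b), height=float(height))
        nodes[a].parent = nid
        nodes[b].parent = nid
    return ClusterTree(nodes=nodes, root=n + len(Z) - 1, n_leaves=n)


def intra_cluster_variance(residuals_test: np.ndarray, members: np.ndarray) -> float:
    """Mean squared deviation of member cells from the cluster-mean time
    course, over held-out frames."""
    X = residuals_test[members]
    mu = X.mean(axis=0, keepdims=True)
    return float(np.mean((X - mu) ** 2))


def _sample_subsets(
    parent: np.ndarray, size: int, child: np.ndarray, rng: np.random.Generator
):
    """Size-matched subsets of the parent, without replacement within a subset.

    If the number of possible subsets is <= MAX_SAMPLES, all are enumerated
    (including the child set itself, to respect N_samples = min(C(Np,Nc), 100));
    otherwise MAX_SAMPLES distinct random subsets are drawn, excluding the
    exact child set since alternatives exist.
    """
    total = comb(parent.size, size)
    child_key = tuple(np.sort(child))
    if total <= MAX_SAMPLES:
        return [np.array(c) for c in itertools.combinations(parent, size)]
    subsets = []
    seen = set()
    while len(subsets) < MAX_SAMPLES:
        pick = np.sort(rng.choice(parent, size=size, replace=False))
        key = tuple(pick)
        if key == child_key or key in seen:
            continue
        seen.add(key)
        subsets.append(pick)
    return subsets


def test_clusters(
    tree: ClusterTree, residuals_test: np.ndarray, seed: int = 0
) -> dict:
    """Parent-resampling significance for every child cluster of size >= 2.

    For each internal parent node, each child with N_c >= 2 members is
    compared against N_samples = min(C(N_p, N_c), 100) size-matched subsets
    of the parent on held-out frames; p = (1 + #{subset variance <= child
    variance}) / (1 + N_samples). Nodes with fewer than 20 samples cannot
    reach p < 0.05 and are flagged untestable.
    """
    residuals_test = np.atleast_2d(np.asarray(residuals_test, dtype=float))
    results: dict = {}
    for parent in sorted(tree.internal_nodes(), key=lambda n: n.id):
        for child_id in parent.children:
            child = tree.node(child_id)
            if child.size < 2:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(child_id,))
            )
            n_samples = min(comb(parent.size, child.size), MAX_SAMPLES)
            child_var = intra_cluster_variance(residuals_test, child.members)
            subsets = _sample_subsets(parent.members, child.size, child.members, rng)
            sample_vars = np.array(
                [intra_cluster_variance(residuals_test, s) for s in subsets]
            )
            p = (1.0 + np.sum(sample_vars <= child_var)) / (1.0 + len(subsets))
            untestable = None
            if len(subsets) < MIN_TESTABLE_SAMPLES:
                untestable = (
                    f"only {len(subsets)} size-matched samples; p < {ALPHA} unattainable"
                )
            results[child_id] = ClusterSignificance(
                node_id=child_id,
                parent_id=parent.id,
                n_parent=parent.size,
                n_child=child.size,
                n_samples=len(subsets),
                child_variance=child_var,
                sample_variances=sample_vars,
                p=float(p),
                significant=bool(p < ALPHA and untestable is None),
                untestable_reason=untestable,
            )
    return results


def _has_significant_descendant(tree: ClusterTree, node_id: int, results: dict) -> bool:
    stack = list(tree.node(node_id).children)
    while stack:
        nid = stack.pop()
        r = results.get(nid)
        if r is not None and r.significant:
            return True
        stack.extend(tree.node(nid).children)
    return False


def size_distribution(tree: ClusterTree, results: dict) -> tuple[np.ndarray, np.ndarray]:
    """Member counts of (a) all significant clusters and (b) terminal
    significant clusters -- significant nodes with no significant cluster
    anywhere below them. Each terminal cluster is counted exactly once."""
    all_sizes = [
        tree.node(nid).size for nid, r in results.items() if r.significant
    ]
    terminal_sizes = [
        tree.node(nid).size
        for nid, r in results.items()
        if r.significant and not _has_significant_descendant(tree, nid, results)
    ]
    return np.array(sorted(all_sizes)), np.array(sorted(terminal_sizes))


def results_to_frame(tree: ClusterTree, results: dict) -> pd.DataFrame:
    rows = []
    for nid, r in sorted(results.items()):
        rows.append(
            {
                "node": nid,
                "parent": r.parent_id,
                "n_parent": r.n_parent,
                "n_child": r.n_child,
                "n_samples": r.n_samples,
                "child_variance": r.child_variance,
                "p": r.p,
                "significant": r.significant,
                "untestable_reason": r.untestable_reason or "",
                "members": ";".join(map(str, tree.node(nid).members)),
            }
        )
    return pd.DataFrame(rows)


def tree_to_json(tree: ClusterTree, results: dict | None = None) -> str:
    """Nested JSON export of the tree (and significance, if given)."""

    def serialize(nid: int):
        node = tree.node(nid)
        d = {
            "id": nid,
            "height": node.height,
            "members": node.members.tolist(),
        }
        if results is not None and nid in results:
            r = results[nid]
            d["p"] = r.p
            d["significant"] = r.significant
        if node.children:
            d["children"] = [serialize(c) for c in node.children]
        return d

    return json.dumps(serialize(tree.root))
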