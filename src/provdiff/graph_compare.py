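"""Comparison of provenance structures across executions.

Pipelines are data dependent: different subjects can take different
execution paths (an extra decompression step, a different number of
input images) and therefore yield structurally different process trees.
Before two executions can be compared process-by-process, the analyst
groups executions into structural families by clustering process trees
under the Zhang–Shasha ordered-tree edit distance, and establishes a
one-to-one process correspondence between the two conditions of a pair.

The tree edit distance here is the classical Zhang–Shasha dynamic
program over postorder keyroots with unit insert/delete/relabel costs.
"""

from __future__ import annotations

import posixpath
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .provenance import ProcessTree, ProvenanceGraph
from .trace_model import remap_path

__all__ = [
    "GraphMismatchError",
    "tree_edit_distance",
    "zhang_shasha_distance",
    "tree_distance_matrix",
    "cluster_process_trees",
    "match_processes",
]

LABEL_POLICIES = ("executable-name", "executable+argv")


class GraphMismatchError(ValueError):
    """Two provenance graphs violate the identical-structure assumption."""


# ---------------------------------------------------------------------------
# Zhang–Shasha ordered tree edit distance

def _postorder(tree: ProcessTree, label_of) -> tuple[list, list[int]]:
    """Postorder labels and leftmost-leaf indices (1-based) of the tree."""
    labels: list = []
    lml: list[int] = []

    def visit(pid: str) -> int:
        """Return the 1-based postorder index of pid's leftmost leaf."""
        kids = tree.children.get(pid, [])
        if not kids:
            labels.append(label_of(pid))
            lml.append(len(labels))
            return len(labels)
        first = None
        for c in kids:
            leaf = visit(c)
            if first is None:
                first = leaf
        labels.append(label_of(pid))
        lml.append(first)
        return first

    visit(tree.root)
    return labels, lml


def _keyroots(lml: list[int]) -> list[int]:
    """1-based postorder indices that are keyroots (rightmost of their lml)."""
    seen: dict[int, int] = {}
    for i, leaf in enumerate(lml, start=1):
        seen[leaf] = i
    return sorted(seen.values())


def zhang_shasha_distance(
    labels1: list, lml1: list[int], labels2: list, lml2: list[int]
) -> int:
    """Ordered tree edit distance from postorder label/leftmost-leaf arrays.

    Unit cost for insert, delete, and relabel of unequal labels.
    """
    n, m = len(labels1), len(labels2)
    if n == 0 or m == 0:
        return max(n, m)
    treedist = np.zeros((n + 1, m + 1), dtype=np.int64)
    kr1, kr2 = _keyroots(lml1), _keyroots(lml2)
    for i in kr1:
        li = lml1[i - 1]
        for j in kr2:
            lj = lml2[j - 1]
            rows = i - li + 2
            cols = j - lj + 2
            fd = np.zeros((rows, cols), dtype=np.int64)
            fd[:, 0] = np.arange(rows)
            fd[0, :] = np.arange(cols)
            for di in range(1, rows):
                i1 = li + di - 1  # postorder index in tree 1
                for dj in range(1, cols):
                    j1 = lj + dj - 1
                    if lml1[i1 - 1] == li and lml2[j1 - 1] == lj:
                        cost = 0 if labels1[i1 - 1] == labels2[j1 - 1] else 1
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[di - 1, dj - 1] + cost,
                        )
                        treedist[i1, j1] = fd[di, dj]
                    else:
                        p = lml1[i1 - 1] - li  # forest prefix before subtree i1
                        q = lml2[j1 - 1] - lj
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[p, q] + treedist[i1, j1],
                        )
    return int(treedist[n, m])


def _label_fn(tree: ProcessTree, label_policy: str):
    if label_policy not in LABEL_POLICIES:
        raise ValueError(f"unknown label policy {label_policy!r}")

    def label_of(pid: str):
        attrs = tree.labels[pid]
        base = posixpath.basename(attrs["executable"])
        if label_policy == "executable-name":
            return base
        return (base, tuple(attrs["argv"]))

    return label_of


def tree_edit_distance(
    a: ProcessTree, b: ProcessTree, label_policy: str = "executable-name"
) -> int:
    """Zhang–Shasha edit distance between two process trees.

    ``label_policy`` selects the node label compared by the relabel
    cost: the executable basename alone (default — argv is path-noisy)
    or the (basename, argv) pair.
    """
    la, lmla = _postorder(a, _label_fn(a, label_policy))
    lb, lmlb = _postorder(b, _label_fn(b, label_policy))
    return zhang_shasha_distance(la, lmla, lb, lmlb)


# ---------------------------------------------------------------------------
# Clustering of trees into structural families

def tree_distance_matrix(
    trees: list[ProcessTree],
    label_policy: str = "executable-name",
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise tree-edit-distance matrix as a DataFrame."""
    n = len(trees)
    names = names if names is not None else [f"tree{i}" for i in range(n)]
    post = [_postorder(t, _label_fn(t, label_policy)) for t in trees]
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = zhang_shasha_distance(*post[i], *post[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def cluster_process_trees(
    trees: list[ProcessTree],
    linkage_threshold: float = 0.0,
    label_policy: str = "executable-name",
) -> dict[int, int]:
    """Group trees into structural families by complete-linkage clustering.

    The pairwise Zhang–Shasha matrix is clustered agglomeratively
    (complete linkage) and cut at ``linkage_threshold``: every pair
    within a cluster is at distance ≤ threshold.  The default threshold
    0 yields exact-structure classes.  Returns {tree index → cluster
    id}, cluster ids numbered 0.. in order of first appearance.
    """
    if not trees:
        raise ValueError("at least one tree is required")
    if len(trees) == 1:
        return {0: 0}
    dm = tree_distance_matrix(trees, label_policy=label_policy).to_numpy()
    condensed = dm[np.triu_indices(len(trees), k=1)].astype(float)
    link = linkage(condensed, method="complete")
    raw = fcluster(link, t=linkage_threshold, criterion="distance")
    relabel: dict[int, int] = {}
    out: dict[int, int] = {}
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel)
        out[i] = relabel[c]
    return out


# ---------------------------------------------------------------------------
# Cross-condition process correspondence

@dataclass(frozen=True)
class ProcessCorrespondence:
    """Total one-to-one mapping between process ids of two graphs."""

    mapping: dict[str, str]

    def __getitem__(self, pid: str) -> str:
        return self.mapping[pid]

    def items(self):
        return self.mapping.items()


def match_processes(
    g1: ProvenanceGraph,
    g2: ProvenanceGraph,
    prefix_map: list[tuple[str, str]] | None = None,
) -> ProcessCorrespondence:
    """Pair the processes of two same-structure graphs one-to-one.

    Processes are paired in start-ordinal order (the spawn order, which
    equals depth-first tree order for sequentially spawned pipelines);
    each pair must agree on executable basename and on argv after
    applying ``prefix_map`` to g1's tokens.  Raises
    :class:`GraphMismatchError` at the first divergence — the signal
    that the identical-graph assumption is violated and the executions
    belong to different structural families.
    """
    ids1, ids2 = g1.process_ids(), g2.process_ids()
    if len(ids1) != len(ids2):
        raise GraphMismatchError(
            f"process count mismatch: {len(ids1)} vs {len(ids2)}"
        )
    prefix_map = prefix_map or []
    mapping: dict[str, str] = {}
    for p1, p2 in zip(ids1, ids2):
        a1, a2 = g1.process_attrs(p1), g2.process_attrs(p2)
        if a1["basename"] != a2["basename"]:
            raise GraphMismatchError(
                f"executable mismatch at pair ({p1}, {p2}): "
                f"{a1['basename']!r} vs {a2['basename']!r}"
            )
        argv1 = tuple(
            remap_path(tok, prefix_map) if tok.startswith("/") else tok
            for tok in a1["argv"]
        )
        argv2 = tuple(a2["argv"])
        if len(argv1) != len(argv2):
            raise GraphMismatchError(
                f"argv length mismatch at pair ({p1}, {p2})"
            )
        if argv1 != argv2:
            raise GraphMismatchError(
                f"argv mismatch at pair ({p1}, {p2}): {argv1!r} vs {argv2!r}"
            )
        mapping[p1] = p2
    return ProcessCorrespondence(mapping)
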