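"""Tree edit distance (vs brute-force oracle), clustering, correspondence."""

import itertools
import random
from pathlib import Path

import pytest

from conftest import make_tree
from provdiff.fixtures import make_brain_volume_spec, synthesize_trace
from provdiff.graph_compare import (
    GraphMismatchError,
    cluster_process_trees,
    match_processes,
    tree_distance_matrix,
    tree_edit_distance,
)
from provdiff.provenance import (
    DEFAULT_BLACKLIST,
    build_provenance_graph,
    filter_processes,
)


# ---------------------------------------------------------------------------
# Brute-force oracle: recursive ordered-forest edit distance.
# Trees are nested tuples (label, (child, ...)); independent of the
# Zhang–Shasha implementation under test.

def _forest_size(forest):
    return sum(1 + _forest_size(t[1]) for t in forest)


def _forest_distance(f1, f2, memo):
    key = (f1, f2)
    if key in memo:
        return memo[key]
    if not f1:
        result = _forest_size(f2)
    elif not f2:
        result = _forest_size(f1)
    else:
        l1, t1 = f1[:-1], f1[-1]
        l2, t2 = f2[:-1], f2[-1]
        delete = _forest_distance(l1 + t1[1], f2, memo) + 1
        insert = _forest_distance(f1, l2 + t2[1], memo) + 1
        relabel = (
            _forest_distance(l1, l2, memo)
            + _forest_distance(t1[1], t2[1], memo)
            + (0 if t1[0] == t2[0] else 1)
        )
        result = min(delete, insert, relabel)
    memo[key] = result
    return result


def oracle_distance(a, b):
    return _forest_distance((a,), (b,), {})


def _random_tuple_tree(rng, max_nodes):
    """Random ordered labeled tree with at most max_nodes nodes."""
    labels = "abc"
    n = rng.randint(1, max_nodes)

    def build(budget):
        label = rng.choice(labels)
        children = []
        remaining = budget - 1
        while remaining > 0 and rng.random() < 0.6:
            size = rng.randint(1, remaining)
            child, used = build(size)
            children.append(child)
            remaining -= used
        return (label, tuple(children)), budget - remaining

    tree, _ = build(n)
    return tree


def _tuple_to_nested(t):
    """Convert (label, (children,)) to the conftest make_tree format."""
    return (t[0], [_tuple_to_nested(c) for c in t[1]])


class TestTreeEditDistance:
    def test_identical_trees_zero(self):
        t = make_tree(("A", [("B", []), ("C", [("D", [])])]))
        assert tree_edit_distance(t, t) == 0

    def test_single_insertion_costs_one(self):
        # A(B) vs A(B,C): the only edit needed is inserting/deleting C
        a = make_tree(("A", [("B", [])]))
        b = make_tree(("A", [("B", []), ("C", [])]))
        assert tree_edit_distance(a, b) == 1
        assert tree_edit_distance(b, a) == 1

    def test_relabel_costs_one(self):
        a = make_tree(("A", [("B", [])]))
        b = make_tree(("A", [("X", [])]))
        assert tree_edit_distance(a, b) == 1

    def test_agrees_with_bruteforce_on_random_small_trees(self):
        rng = random.Random(20260927)
        for _ in range(50):
            ta = _random_tuple_tree(rng, 6)
            tb = _random_tuple_tree(rng, 6)
            expected = oracle_distance(ta, tb)
            got = tree_edit_distance(
                make_tree(_tuple_to_nested(ta)), make_tree(_tuple_to_nested(tb))
            )
            assert got == expected, (ta, tb)

    def test_metric_axioms_on_corpus(self):
        rng = random.Random(7)
        corpus = [
            make_tree(_tuple_to_nested(_random_tuple_tree(rng, 6)))
            for _ in range(8)
        ]
        d = {
            (i, j): tree_edit_distance(corpus[i], corpus[j])
            for i, j in itertools.product(range(8), repeat=2)
        }
        for i in range(8):
            assert d[(i, i)] == 0
        for i, j in itertools.combinations(range(8), 2):
            assert d[(i, j)] == d[(j, i)] >= 0
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[(i, k)] <= d[(i, j)] + d[(j, k)]

    def test_argv_label_policy_distinguishes_arguments(self):
        from provdiff.provenance import ProcessTree

        base = make_tree(("A", [("B", [])]))
        other = ProcessTree(
            root=base.root,
            children={k: list(v) for k, v in base.children.items()},
            labels={k: dict(v) for k, v in base.labels.items()},
        )
        kid = other.children[other.root][0]
        other.labels[kid] = dict(other.labels[kid], argv=("B", "--flag"))
        assert tree_edit_distance(base, other, "executable-name") == 0
        assert tree_edit_distance(base, other, "executable+argv") == 1


class TestClustering:
    def _family(self, with_decompression: bool, n: int):
        """Trees mirroring an optional leading decompression step."""
        prefix = [("gunzip", [])] if with_decompression else []
        return [
            make_tree(("driver", prefix + [("align", []), ("segment", [])]))
            for _ in range(n)
        ]

    def test_identical_trees_single_cluster(self):
        trees = self._family(False, 4)
        assignment = cluster_process_trees(trees, 0)
        assert set(assignment.values()) == {0}

    def test_two_structural_families_at_threshold_zero(self):
        trees = self._family(False, 3) + self._family(True, 2)
        assignment = cluster_process_trees(trees, 0)
        assert len(set(assignment.values())) == 2
        assert assignment[0] == assignment[1] == assignment[2]
        assert assignment[3] == assignment[4]
        assert assignment[0] != assignment[3]

    def test_large_threshold_merges_everything(self):
        trees = self._family(False, 3) + self._family(True, 2)
        dm = tree_distance_matrix(trees)
        assignment = cluster_process_trees(trees, float(dm.to_numpy().max()))
        assert set(assignment.values()) == {0}

    def test_invariant_to_input_order(self):
        trees = self._family(False, 2) + self._family(True, 2)
        fwd = cluster_process_trees(trees, 0)
        rev = cluster_process_trees(trees[::-1], 0)
        # same partition structure regardless of ordering
        fwd_partition = {
            frozenset(i for i in fwd if fwd[i] == c) for c in set(fwd.values())
        }
        rev_partition = {
            frozenset(len(trees) - 1 - i for i in rev if rev[i] == c)
            for c in set(rev.values())
        }
        assert fwd_partition == rev_partition

    def test_single_tree(self):
        assert cluster_process_trees(self._family(False, 1), 0) == {0: 0}

    def test_no_trees_rejected(self):
        with pytest.raises(ValueError):
            cluster_process_trees([], 0)


class TestMatchProcesses:
    def _graph(self, workdir):
        spec, _ = make_brain_volume_spec()
        records = synthesize_trace(spec, "c", workdir)
        return filter_processes(
            build_provenance_graph(records), DEFAULT_BLACKLIST
        )

    def test_self_match_is_identity(self):
        g = self._graph("/scratch/run1")
        corr = match_processes(g, g)
        assert all(a == b for a, b in corr.items())

    def test_same_pipeline_different_scratch_dirs(self):
        g1 = self._graph("/scratch/run1")
        g2 = self._graph("/scratch/run2")
        corr = match_processes(
            g1, g2, prefix_map=[("/scratch/run1", "/scratch/run2")]
        )
        assert len(dict(corr.items())) == 3
        for p1, p2 in corr.items():
            assert (
                g1.process_attrs(p1)["basename"]
                == g2.process_attrs(p2)["basename"]
            )

    def test_extra_process_raises_mismatch(self):
        from conftest import make_records

        g1 = self._graph("/scratch/run1")
        extra = make_records(
            [("q0", None, "/opt/bet2"), ("q1", "q0", "/opt/fslmaths"),
             ("q2", "q0", "/opt/fslstats"), ("q3", "q0", "/opt/extra")],
            [],
        )
        g2 = build_provenance_graph(extra)
        with pytest.raises(GraphMismatchError, match="count"):
            match_processes(g1, g2)

    def test_executable_mismatch_reported(self):
        from conftest import make_records

        a = build_provenance_graph(
            make_records([("p0", None, "/opt/toolA", ("toolA",))], [])
        )
        b = build_provenance_graph(
            make_records([("p0", None, "/opt/toolB", ("toolB",))], [])
        )
        with pytest.raises(GraphMismatchError, match="toolA"):
            match_processes(a, b)
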