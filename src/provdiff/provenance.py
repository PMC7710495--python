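"""Bipartite provenance graphs and process trees.

The raw provenance graph of one execution is a directed bipartite graph:
process nodes (one per traced OS process) and file nodes (one per
distinct path), with a file→process edge for each read and a
process→file edge for each write.  The process tree links processes by
their fork/clone spawning relation and is the structure compared across
executions (tree edit distance, clustering).

System utility processes (/bin, /usr/bin, ...) add noise to the
analysis; ``filter_processes`` removes them by executable-path pattern
before labeling, not merely at display time.
"""

from __future__ import annotations

import fnmatch
import posixpath
from dataclasses import dataclass, field

import networkx as nx

from .trace_model import TraceRecordSet, TraceValidationError

__all__ = [
    "ProvenanceGraph",
    "ProcessTree",
    "MalformedTraceError",
    "DEFAULT_BLACKLIST",
    "build_provenance_graph",
    "build_process_tree",
    "filter_processes",
]

#: Executable-path patterns removed from analysis by default.
DEFAULT_BLACKLIST = ("/bin/*", "/usr/bin/*", "/lib/*", "/usr/lib/*")


class MalformedTraceError(TraceValidationError):
    """The trace cannot form a valid tree/graph (two roots, cycles, ...)."""


def _proc_key(process_id: str) -> tuple[str, str]:
    return ("proc", process_id)


def _file_key(path: str) -> tuple[str, str]:
    return ("file", path)


@dataclass
class ProvenanceGraph:
    """Bipartite file/process graph backed by a :class:`networkx.DiGraph`.

    Node keys are ``("proc", process_id)`` and ``("file", path)``.
    Process nodes carry ``executable``, ``argv``, ``working_dir``,
    ``start_ordinal``, ``basename`` and ``instance`` (1-based index among
    same-named processes in start order).  Edges carry the first-access
    ``ordinal`` and, on write edges, the ``deleted`` flag.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- node accessors -----------------------------------------------------
    def process_ids(self) -> list[str]:
        return sorted(
            (n[1] for n in self.graph.nodes if n[0] == "proc"),
            key=lambda pid: self.graph.nodes[_proc_key(pid)]["start_ordinal"],
        )

    def file_paths(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "file"}

    def process_attrs(self, process_id: str) -> dict:
        return self.graph.nodes[_proc_key(process_id)]

    def read_edges(self) -> list[tuple[str, str]]:
        """(path, process_id) pairs, file → process."""
        return [
            (u[1], v[1])
            for u, v in self.graph.edges
            if u[0] == "file" and v[0] == "proc"
        ]

    def write_edges(self) -> list[tuple[str, str]]:
        """(process_id, path) pairs, process → file."""
        return [
            (u[1], v[1])
            for u, v in self.graph.edges
            if u[0] == "proc" and v[0] == "file"
        ]

    def writers_of(self, path: str) -> list[str]:
        """Writing processes of ``path`` ordered by first write ordinal."""
        node = _file_key(path)
        if node not in self.graph:
            return []
        preds = [
            (self.graph.edges[p, node]["ordinal"], p[1])
            for p in self.graph.predecessors(node)
        ]
        return [pid for _o, pid in sorted(preds)]

    def readers_of(self, path: str) -> list[str]:
        node = _file_key(path)
        if node not in self.graph:
            return []
        succs = [
            (self.graph.edges[node, s]["ordinal"], s[1])
            for s in self.graph.successors(node)
        ]
        return [pid for _o, pid in sorted(succs)]

    def is_bipartite(self) -> bool:
        return all(u[0] != v[0] for u, v in self.graph.edges)

    def copy(self) -> "ProvenanceGraph":
        return ProvenanceGraph(self.graph.copy())

    # -- DOT export ---------------------------------------------------------
    def to_dot(self) -> str:
        """Deterministic Graphviz text: processes as circles, files as boxes."""
        lines = ["digraph provenance {", "  rankdir=TB;"]
        for pid in self.process_ids():
            attrs = self.process_attrs(pid)
            label = attrs["basename"]
            lines.append(
                f'  "proc:{pid}" [shape=circle, label="{label}"];'
            )
        for path in sorted(self.file_paths()):
            name = posixpath.basename(path)
            lines.append(f'  "file:{path}" [shape=box, label="{name}"];')
        for path, pid in sorted(self.read_edges()):
            lines.append(f'  "file:{path}" -> "proc:{pid}";')
        for pid, path in sorted(self.write_edges()):
            lines.append(f'  "proc:{pid}" -> "file:{path}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class ProcessTree:
    """Rooted ordered tree of processes under the fork/clone relation.

    ``children`` lists are ordered by child start ordinal; ``labels``
    maps each process id to its trace attributes (executable, argv,
    spawn_kind, start_ordinal).
    """

    root: str
    children: dict[str, list[str]]
    labels: dict[str, dict]

    def node_ids(self) -> list[str]:
        out: list[str] = []

        def visit(pid: str) -> None:
            out.append(pid)
            for c in self.children.get(pid, []):
                visit(c)

        visit(self.root)
        return out

    def size(self) -> int:
        return len(self.labels)

    def to_dot(self) -> str:
        lines = ["digraph process_tree {"]
        for pid in self.node_ids():
            base = posixpath.basename(self.labels[pid]["executable"])
            lines.append(f'  "{pid}" [shape=circle, label="{base}"];')
        for pid in self.node_ids():
            for c in self.children.get(pid, []):
                kind = self.labels[c]["spawn_kind"]
                lines.append(f'  "{pid}" -> "{c}" [style=dashed, label="{kind}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_provenance_graph(records: TraceRecordSet) -> ProvenanceGraph:
    """Construct the raw bipartite provenance graph from a trace.

    One file node per distinct path; a read edge for every access whose
    merged mode includes a read and a write edge for every access whose
    mode includes a write (``read_write`` contributes both).
    """
    records.validate()
    g = nx.DiGraph()
    by_basename: dict[str, int] = {}
    for p in sorted(records.processes, key=lambda p: p.start_ordinal):
        by_basename[p.basename] = by_basename.get(p.basename, 0) + 1
        g.add_node(
            _proc_key(p.process_id),
            executable=p.executable_path,
            argv=p.argv,
            working_dir=p.working_dir,
            start_ordinal=p.start_ordinal,
            basename=p.basename,
            instance=by_basename[p.basename],
        )
    for a in records.accesses:
        fk = _file_key(a.path)
        if fk not in g:
            g.add_node(fk)
        pk = _proc_key(a.process_id)
        if a.mode in ("read", "read_write"):
            g.add_edge(fk, pk, ordinal=a.first_access_ordinal)
        if a.mode in ("write", "read_write"):
            g.add_edge(pk, fk, ordinal=a.first_access_ordinal,
                       deleted=a.deleted_by_process)
    return ProvenanceGraph(g)


def build_process_tree(records: TraceRecordSet) -> ProcessTree:
    """Construct the fork/clone process tree, children in start order."""
    records.validate()  # also enforces single root, parent-precedes-child
    roots = [p for p in records.processes if p.parent_id is None]
    if len(roots) != 1:
        raise MalformedTraceError(f"expected one root process, found {len(roots)}")
    children: dict[str, list[str]] = {p.process_id: [] for p in records.processes}
    labels = {
        p.process_id: {
            "executable": p.executable_path,
            "argv": p.argv,
            "spawn_kind": p.spawn_kind,
            "start_ordinal": p.start_ordinal,
        }
        for p in records.processes
    }
    for p in sorted(records.processes, key=lambda p: p.start_ordinal):
        if p.parent_id is not None:
            children[p.parent_id].append(p.process_id)
    return ProcessTree(root=roots[0].process_id, children=children, labels=labels)


def _matches(executable: str, patterns: tuple[str, ...]) -> bool:
    for pat in patterns:
        # a bare directory prefix acts as "<dir>/*"
        if not any(ch in pat for ch in "*?["):
            pat = pat.rstrip("/") + "/*"
        if fnmatch.fnmatchcase(executable, pat):
            return True
    return False


def filter_processes(
    graph: ProvenanceGraph, blacklist: tuple[str, ...] | list[str]
) -> ProvenanceGraph:
    """Remove processes whose executable path matches a blacklist pattern.

    Incident edges go with the process; file nodes are removed only if
    the removal leaves them isolated.  An empty blacklist is the
    identity.
    """
    patterns = tuple(blacklist)
    out = graph.copy()
    if not patterns:
        return out
    g = out.graph
    doomed = [
        _proc_key(pid)
        for pid in graph.process_ids()
        if _matches(graph.process_attrs(pid)["executable"], patterns)
    ]
    g.remove_nodes_from(doomed)
    isolated = [n for n in g.nodes if n[0] == "file" and g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return out
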