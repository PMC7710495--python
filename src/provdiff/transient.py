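"""Transient files: detection, version disambiguation, capture wrappers.

A *transient* file is one that cannot be compared across conditions by
looking at the final working directory: it was deleted during the run,
or it was written by more than one process so only its last version
survives.  This module

* detects transient files and verifies the no-concurrent-write
  assumption the whole approach rests on,
* splits each multi-writer path into per-writer *versions*, turning the
  (possibly cyclic) provenance graph into a DAG in which every written
  file version has exactly one writer (in-degree 1), and
* generates PATH-shim wrapper scripts that, prepended to the executable
  search path, transparently intercept each pipeline process, delegate
  to the genuine executable, and archive the file versions that process
  wrote into a write-once store.

Archive layout: ``store_dir/<basename>/<instance>/<version>/<sanitized
path>`` plus a per-instance ``manifest.json`` carrying the original
path, the version index and a SHA-256 checksum.
"""

from __future__ import annotations

import json
import os
import stat
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .provenance import ProvenanceGraph
from .trace_model import TraceRecordSet, remap_path

__all__ = [
    "TransientFileReport",
    "VersionedDAG",
    "WrapperSet",
    "AssumptionViolationError",
    "find_transient_files",
    "check_concurrent_writes",
    "disambiguate_versions",
    "generate_wrapper_scripts",
]


class AssumptionViolationError(ValueError):
    """The trace violates the sequential single-version file model."""


@dataclass
class TransientFileReport:
    """Paths needing capture before conditions can be compared.

    ``multi_writer_files`` maps each path written by ≥2 processes to its
    writers ordered by first write; ``warnings`` lists assumption
    violations that do not prevent analysis (e.g. a self-deleted file
    that other processes also use).
    """

    deleted_files: set[str] = field(default_factory=set)
    multi_writer_files: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def transient_paths(self) -> set[str]:
        return self.deleted_files | set(self.multi_writer_files)

    def is_empty(self) -> bool:
        return not self.deleted_files and not self.multi_writer_files


def find_transient_files(
    graph: ProvenanceGraph, records: TraceRecordSet
) -> TransientFileReport:
    """Identify deleted and multi-writer paths among the graph's files.

    Only paths and processes present in ``graph`` are considered, so
    system-utility accesses removed by filtering do not resurface.  A
    warning is recorded when a process deletes a file it created itself
    while other processes also use that file — the model requires a
    self-deleted file to be private to its creator.
    """
    report = TransientFileReport()
    graph_files = graph.file_paths()
    graph_procs = set(graph.process_ids())
    for path in graph_files:
        writers = [w for w in graph.writers_of(path) if w in graph_procs]
        if len(writers) >= 2:
            report.multi_writer_files[path] = writers
    for a in records.accesses:
        if not a.deleted_by_process:
            continue
        if a.path not in graph_files or a.process_id not in graph_procs:
            continue
        report.deleted_files.add(a.path)
        writers = graph.writers_of(a.path)
        others = (set(graph.readers_of(a.path)) | set(writers)) - {a.process_id}
        if writers and writers[0] == a.process_id and others:
            report.warnings.append(
                f"{a.path}: deleted by its creator {a.process_id} but used by "
                f"{sorted(others)}; this file must not be used by any other process"
            )
    return report


def check_concurrent_writes(
    records: TraceRecordSet, path: str
) -> list[tuple[str, str]]:
    """Return pairs of processes whose write intervals on ``path`` overlap.

    The write interval of a process is approximated from the trace
    ordinals as [first write ordinal on the path, last recorded ordinal
    of the process] — the open-for-write to close/exit window at the
    resolution the trace provides.  An empty list means the
    no-concurrent-write assumption holds for this path.
    """
    last_ordinal: dict[str, int] = {}
    for p in records.processes:
        last_ordinal[p.process_id] = 0
    for a in records.accesses:
        last_ordinal[a.process_id] = max(
            last_ordinal.get(a.process_id, 0), a.first_access_ordinal
        )
    intervals = [
        (a.first_access_ordinal, last_ordinal[a.process_id], a.process_id)
        for a in records.accesses
        if a.path == path and a.mode in ("write", "read_write")
    ]
    intervals.sort()
    violations = []
    for i, (s1, e1, p1) in enumerate(intervals):
        for s2, e2, p2 in intervals[i + 1:]:
            if s2 <= e1 and s1 <= e2:
                violations.append((p1, p2))
    return violations


# ---------------------------------------------------------------------------
# Version disambiguation

def _proc(pid: str) -> tuple[str, str]:
    return ("proc", pid)


def _filev(path: str, version: int) -> tuple[str, str, int]:
    return ("filev", path, version)


@dataclass
class VersionedDAG:
    """Provenance graph with per-writer file versions; acyclic by construction.

    File nodes are keyed ``("filev", path, version)``; version 0 is the
    pre-existing pipeline input (in-degree 0), versions 1..n are the
    successive writes of the path's n writers (in-degree exactly 1).
    Process node attributes are copied from the provenance graph.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def process_ids(self) -> list[str]:
        return sorted(
            (n[1] for n in self.graph.nodes if n[0] == "proc"),
            key=lambda pid: self.graph.nodes[_proc(pid)]["start_ordinal"],
        )

    def process_attrs(self, process_id: str) -> dict:
        return self.graph.nodes[_proc(process_id)]

    def file_version_nodes(self) -> list[tuple[str, int]]:
        return sorted((n[1], n[2]) for n in self.graph.nodes if n[0] == "filev")

    def outputs_of(self, process_id: str) -> list[tuple[str, int]]:
        """(path, version) pairs written by the process."""
        return sorted(
            (s[1], s[2]) for s in self.graph.successors(_proc(process_id))
        )

    def inputs_of(self, process_id: str) -> list[tuple[str, int]]:
        return sorted(
            (p[1], p[2]) for p in self.graph.predecessors(_proc(process_id))
        )

    def writer_of(self, path: str, version: int) -> str | None:
        preds = list(self.graph.predecessors(_filev(path, version)))
        return preds[0][1] if preds else None

    def max_file_in_degree(self) -> int:
        degrees = [
            self.graph.in_degree(n) for n in self.graph.nodes if n[0] == "filev"
        ]
        return max(degrees, default=0)

    def version_counts(self) -> dict[str, int]:
        """Number of *produced* versions (writers) per path."""
        counts: dict[str, int] = {}
        for path, version in self.file_version_nodes():
            if version >= 1:
                counts[path] = max(counts.get(path, 0), version)
        return counts

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def topological_processes(self) -> list[str]:
        """Process ids in dependency order, ties broken by start ordinal."""
        order = nx.lexicographical_topological_sort(
            self.graph,
            key=lambda n: (
                self.graph.nodes[n].get("start_ordinal", 0),
                str(n),
            ),
        )
        return [n[1] for n in order if n[0] == "proc"]


def disambiguate_versions(
    graph: ProvenanceGraph, report: TransientFileReport
) -> VersionedDAG:
    """Split multi-writer files into versions; return the single-writer DAG.

    For a path with writers P1..Pn (ordered by first write), Pi writes
    version i.  A reader is attached to the latest version whose write
    precedes the reader's first read; a process that reads and writes
    the same path as writer i reads version i−1.  Version 0 stands for
    pre-existing input content and is the only kind of file node allowed
    in-degree 0.

    Raises :class:`AssumptionViolationError` if a cycle survives
    versioning (a process released more than one version of a file to
    its peers).
    """
    g = nx.DiGraph()
    for pid in graph.process_ids():
        g.add_node(_proc(pid), **dict(graph.process_attrs(pid)))

    for path in sorted(graph.file_paths()):
        writers = graph.writers_of(path)
        writer_ordinal = {
            w: graph.graph.edges[_proc(w), ("file", path)]["ordinal"]
            for w in writers
        }
        deleted_flags = {
            w: graph.graph.edges[_proc(w), ("file", path)].get("deleted", False)
            for w in writers
        }
        for i, w in enumerate(writers, start=1):
            g.add_edge(
                _proc(w), _filev(path, i),
                ordinal=writer_ordinal[w], deleted=deleted_flags[w],
            )
        writer_index = {w: i for i, w in enumerate(writers, start=1)}
        for r in graph.readers_of(path):
            read_ordinal = graph.graph.edges[("file", path), _proc(r)]["ordinal"]
            if r in writer_index:
                version = writer_index[r] - 1
            else:
                version = 0
                for i, w in enumerate(writers, start=1):
                    if writer_ordinal[w] < read_ordinal:
                        version = i
            if version == 0 and _filev(path, 0) not in g:
                g.add_node(_filev(path, 0))
            g.add_edge(_filev(path, version), _proc(r), ordinal=read_ordinal)
        if not writers and _filev(path, 0) not in g:
            g.add_node(_filev(path, 0))

    dag = VersionedDAG(g)
    if not dag.is_acyclic():
        cycle = nx.find_cycle(g)
        raise AssumptionViolationError(
            f"provenance graph remains cyclic after versioning: {cycle}"
        )
    for n in g.nodes:
        if n[0] == "filev" and n[2] >= 1 and g.in_degree(n) != 1:
            raise AssumptionViolationError(
                f"file version {n[1]}@{n[2]} has in-degree {g.in_degree(n)}"
            )
    return dag


# ---------------------------------------------------------------------------
# PATH-shim wrapper generation

@dataclass
class WrapperSet:
    """Generated shim directory: one script per distinct executable basename."""

    wrapper_dir: Path
    store_dir: Path
    scripts: dict[str, Path]

    def path_prefix(self) -> str:
        """Value to prepend to PATH to activate interception."""
        return str(self.wrapper_dir)


_WRAPPER_TEMPLATE = """#!/bin/sh
# PATH shim for {base}: delegates to the genuine executable found on the
# search path with the shim directory removed, then archives the file
# versions this invocation wrote into the write-once store.
shim_dir={shim_dir_q}
base={base_q}

genuine=""
old_ifs=$IFS
IFS=:
for d in $PATH; do
    [ "$d" = "$shim_dir" ] && continue
    [ -z "$d" ] && continue
    if [ -x "$d/$base" ] && [ -f "$d/$base" ]; then
        genuine="$d/$base"
        break
    fi
done
IFS=$old_ifs
if [ -z "$genuine" ]; then
    echo "wrapper: cannot resolve genuine executable '$base' outside $shim_dir" >&2
    exit 127
fi

# per-basename invocation counter under an exclusive mkdir lock
state_dir="$shim_dir/.state"
lock="$state_dir/$base.lock"
tries=0
while ! mkdir "$lock" 2>/dev/null; do
    tries=$((tries + 1))
    [ "$tries" -gt 20000 ] && {{ echo "wrapper: lock timeout for $base" >&2; exit 125; }}
done
count_file="$state_dir/$base.count"
if [ -f "$count_file" ]; then n=$(cat "$count_file"); else n=0; fi
n=$((n + 1))
echo "$n" > "$count_file"
rmdir "$lock"

"$genuine" "$@"
status=$?

python3 -E -S "$shim_dir/_archive.py" "$shim_dir" "$base" "$n" || exit 124
exit $status
"""

# Stdlib-only helper executed by every wrapper after the genuine tool
# returns: copies this instance's declared output versions into the
# write-once store and records checksums.
_ARCHIVE_HELPER = '''\
import hashlib, json, os, shutil, stat, sys

shim_dir, base, instance = sys.argv[1], sys.argv[2], sys.argv[3]
with open(os.path.join(shim_dir, "_manifest.json")) as fh:
    manifest = json.load(fh)
store_dir = manifest["store_dir"]
entries = manifest["outputs"].get(base, {}).get(instance, [])
archived = []
for entry in entries:
    local = entry["local"]
    if not os.path.isfile(local):
        continue  # e.g. deleted by the process itself before exit
    sanitized = entry["path"].lstrip("/").replace("/", "__")
    dest_dir = os.path.join(store_dir, base, instance, str(entry["version"]))
    dest = os.path.join(dest_dir, sanitized)
    if os.path.exists(dest):
        sys.stderr.write("archive: store collision (write-once): %s\\n" % dest)
        sys.exit(1)
    os.makedirs(dest_dir, exist_ok=True)
    shutil.copyfile(local, dest)
    os.chmod(dest, stat.S_IRUSR | stat.S_IRGRP | stat.S_IROTH)
    h = hashlib.sha256()
    with open(dest, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    archived.append(
        {"path": entry["path"], "version": entry["version"],
         "file": os.path.relpath(dest, store_dir), "sha256": h.hexdigest()}
    )
inst_dir = os.path.join(store_dir, base, instance)
os.makedirs(inst_dir, exist_ok=True)
man = os.path.join(inst_dir, "manifest.json")
if os.path.exists(man):
    sys.stderr.write("archive: store collision (write-once): %s\\n" % man)
    sys.exit(1)
with open(man, "w") as fh:
    json.dump(archived, fh, indent=1)
'''


def _sh_quote(s: str) -> str:
    return "'" + s.replace("'", "'\\''") + "'"


def generate_wrapper_scripts(
    dag: VersionedDAG,
    wrapper_dir: str | os.PathLike,
    store_dir: str | os.PathLike,
    path_map: list[tuple[str, str]] | None = None,
) -> WrapperSet:
    """Write PATH-shim wrappers archiving each process's output versions.

    One POSIX shell script per distinct executable basename in the DAG.
    Each script resolves the genuine executable by searching PATH with
    the shim directory removed, increments a per-basename invocation
    counter under an exclusive lock, invokes the genuine executable with
    identical arguments and environment, archives the (path, version)
    outputs recorded in the DAG for that (basename, instance) into the
    write-once store, and propagates the genuine exit status.

    ``path_map`` remaps DAG paths (recorded in the traced run's working
    directory) to the directory the wrapped run executes in.
    """
    wrapper_dir, store_dir = Path(wrapper_dir).resolve(), Path(store_dir).resolve()
    wrapper_dir.mkdir(parents=True, exist_ok=True)
    (wrapper_dir / ".state").mkdir(exist_ok=True)
    store_dir.mkdir(parents=True, exist_ok=True)
    path_map = path_map or []

    outputs: dict[str, dict[str, list[dict]]] = {}
    basenames: set[str] = set()
    for pid in dag.process_ids():
        attrs = dag.process_attrs(pid)
        base, instance = attrs["basename"], str(attrs["instance"])
        basenames.add(base)
        entries = [
            {
                "path": path,
                "version": version,
                "local": remap_path(path, path_map),
            }
            for path, version in dag.outputs_of(pid)
        ]
        outputs.setdefault(base, {})[instance] = entries

    (wrapper_dir / "_manifest.json").write_text(
        json.dumps({"store_dir": str(store_dir), "outputs": outputs}, indent=1)
    )
    (wrapper_dir / "_archive.py").write_text(_ARCHIVE_HELPER)

    scripts: dict[str, Path] = {}
    for base in sorted(basenames):
        script = wrapper_dir / base
        script.write_text(
            _WRAPPER_TEMPLATE.format(
                base=base,
                base_q=_sh_quote(base),
                shim_dir_q=_sh_quote(str(wrapper_dir)),
            )
        )
        script.chmod(script.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
        scripts[base] = script
    return WrapperSet(wrapper_dir=wrapper_dir, store_dir=store_dir, scripts=scripts)
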