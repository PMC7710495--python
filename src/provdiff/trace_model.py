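"""Trace data model and trace I/O.

A *trace* is the record of one pipeline execution under one computational
condition: the processes the pipeline created and the files each process
read, wrote, or deleted.  Traces are the sole input to provenance-graph
construction; two ingestion routes are supported:

* ReproZip-style SQLite databases (``processes`` / ``executed_files`` /
  ``opened_files`` tables, v1.x layout), the format produced by
  system-call interception of real pipelines;
* a portable JSON dialect (documented below) used by the synthetic
  fixture tracer and for archival.

JSON trace dialect
------------------
A single top-level object::

    {
      "condition": "<condition label>",
      "metadata": {"...": "..."},
      "processes": [
        {"process_id": "...", "parent_id": "..." | null,
         "executable_path": "/abs/path", "argv": ["...", ...],
         "working_dir": "/abs/path", "start_ordinal": 1,
         "spawn_kind": "fork" | "clone" | "exec-root"},
        ...
      ],
      "accesses": [
        {"process_id": "...", "path": "/abs/path",
         "mode": "read" | "write" | "read_write",
         "first_access_ordinal": 1, "deleted_by_process": false},
        ...
      ]
    }

``write_trace_json`` and ``read_trace_json`` are mutually inverse on
valid record sets.
"""

from __future__ import annotations

import json
import os
import posixpath
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProcessRecord",
    "FileAccessRecord",
    "TraceRecordSet",
    "TraceError",
    "TraceFormatError",
    "TraceValidationError",
    "EmptyTraceError",
    "merge_modes",
    "read_reprozip_trace",
    "read_trace_json",
    "write_trace_json",
    "normalize_paths",
    "remap_path",
]

SPAWN_KINDS = ("fork", "clone", "exec-root")
ACCESS_MODES = ("read", "write", "read_write")


class TraceError(ValueError):
    """Base class for trace-level errors."""


class TraceFormatError(TraceError):
    """The on-disk trace is missing or structurally corrupt."""


class TraceValidationError(TraceError):
    """A record violates the data-model invariants."""


class EmptyTraceError(TraceError):
    """The trace contains no processes."""


@dataclass(frozen=True)
class ProcessRecord:
    """One OS process observed during a traced pipeline execution."""

    process_id: str
    parent_id: str | None
    executable_path: str
    argv: tuple[str, ...]
    working_dir: str
    start_ordinal: int
    spawn_kind: str = "fork"

    def __post_init__(self) -> None:
        object.__setattr__(self, "argv", tuple(self.argv))

    @property
    def basename(self) -> str:
        return posixpath.basename(self.executable_path)


@dataclass(frozen=True)
class FileAccessRecord:
    """The merged access of one process to one path.

    ``mode`` is the union of all observed opens of that (process, path)
    pair: any write dominates, a read plus a write in either order is
    ``read_write``.  ``first_access_ordinal`` orders the access among all
    accesses of the trace.  ``deleted_by_process`` marks that this
    process removed the path before the pipeline finished.
    """

    process_id: str
    path: str
    mode: str
    first_access_ordinal: int
    deleted_by_process: bool = False


def merge_modes(a: str, b: str) -> str:
    """Combine two access modes for the same (process, path) pair.

    Idempotent and commutative; a write in either operand dominates.
    """
    if a not in ACCESS_MODES or b not in ACCESS_MODES:
        raise TraceValidationError(f"unknown access mode in merge: {a!r}, {b!r}")
    if a == b:
        return a
    return "read_write"


@dataclass
class TraceRecordSet:
    """All processes and merged file accesses of one traced execution."""

    processes: list[ProcessRecord] = field(default_factory=list)
    accesses: list[FileAccessRecord] = field(default_factory=list)
    condition_label: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def process_by_id(self) -> dict[str, ProcessRecord]:
        return {p.process_id: p for p in self.processes}

    @property
    def root(self) -> ProcessRecord:
        roots = [p for p in self.processes if p.parent_id is None]
        if len(roots) != 1:
            raise TraceValidationError(
                f"expected exactly one root process, found {len(roots)}"
            )
        return roots[0]

    def validate(self) -> None:
        """Check every data-model invariant; raise TraceValidationError."""
        if not self.processes:
            raise EmptyTraceError("trace contains no processes")
        by_id = {}
        for p in self.processes:
            if p.process_id in by_id:
                raise TraceValidationError(f"duplicate process id {p.process_id!r}")
            by_id[p.process_id] = p
            if not p.argv:
                raise TraceValidationError(f"process {p.process_id!r} has empty argv")
            if not p.executable_path.startswith("/"):
                raise TraceValidationError(
                    f"process {p.process_id!r} executable path not absolute"
                )
            if p.spawn_kind not in SPAWN_KINDS:
                raise TraceValidationError(
                    f"process {p.process_id!r} has unknown spawn kind {p.spawn_kind!r}"
                )
        self.root  # exactly-one-root check
        seen_ordinals = set()
        for p in self.processes:
            if p.start_ordinal in seen_ordinals:
                raise TraceValidationError(
                    f"duplicate process start ordinal {p.start_ordinal}"
                )
            seen_ordinals.add(p.start_ordinal)
            if p.parent_id is not None:
                parent = by_id.get(p.parent_id)
                if parent is None:
                    raise TraceValidationError(
                        f"process {p.process_id!r} references unknown parent "
                        f"{p.parent_id!r}"
                    )
                if parent.start_ordinal >= p.start_ordinal:
                    raise TraceValidationError(
                        f"parent {p.parent_id!r} does not precede child "
                        f"{p.process_id!r}"
                    )
        seen_access = set()
        seen_pairs = set()
        for a in self.accesses:
            if a.process_id not in by_id:
                raise TraceValidationError(
                    f"access to {a.path!r} references unknown process "
                    f"{a.process_id!r}"
                )
            if not a.path.startswith("/"):
                raise TraceValidationError(f"access path not absolute: {a.path!r}")
            if a.mode not in ACCESS_MODES:
                raise TraceValidationError(f"unknown access mode {a.mode!r}")
            if a.first_access_ordinal <= 0:
                raise TraceValidationError(
                    f"non-positive access ordinal for {a.path!r}"
                )
            if a.first_access_ordinal in seen_access:
                raise TraceValidationError(
                    f"duplicate access ordinal {a.first_access_ordinal}"
                )
            seen_access.add(a.first_access_ordinal)
            pair = (a.process_id, a.path)
            if pair in seen_pairs:
                raise TraceValidationError(
                    f"unmerged duplicate access for {pair!r}"
                )
            seen_pairs.add(pair)


# ---------------------------------------------------------------------------
# ReproZip SQLite ingestion

# opened_files.mode bit flags, ReproZip v1.x
_FILE_READ = 0x01
_FILE_WRITE = 0x02

_REQUIRED_TABLES = ("processes", "executed_files", "opened_files")


def read_reprozip_trace(
    trace_db_path: str | os.PathLike,
    deleted_paths: Iterable[str] = (),
) -> TraceRecordSet:
    """Read a ReproZip v1.x trace database into a :class:`TraceRecordSet`.

    Only the ``processes``, ``executed_files`` and ``opened_files``
    tables are consulted.  Accesses of one process to one path are
    merged (write dominates).  ReproZip does not record unlink events in
    ``opened_files``, so deletions are supplied by the caller as the set
    of paths found missing after the run (``deleted_paths``); each is
    attributed to its last accessor.

    Raises
    ------
    TraceFormatError
        If the database is missing or a required table is absent,
        naming the offending table.
    EmptyTraceError
        If the database contains no processes.
    """
    trace_db_path = Path(trace_db_path)
    if not trace_db_path.is_file():
        raise TraceFormatError(f"trace database not found: {trace_db_path}")
    con = sqlite3.connect(str(trace_db_path))
    try:
        tables = {
            row[0]
            for row in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        for required in _REQUIRED_TABLES:
            if required not in tables:
                raise TraceFormatError(
                    f"trace database missing table {required!r}: {trace_db_path}"
                )
        try:
            proc_rows = list(
                con.execute(
                    "SELECT id, parent, timestamp, is_thread FROM processes "
                    "ORDER BY timestamp, id"
                )
            )
            exec_rows = list(
                con.execute(
                    "SELECT process, name, argv, workingdir, timestamp "
                    "FROM executed_files ORDER BY timestamp"
                )
            )
            open_rows = list(
                con.execute(
                    "SELECT process, name, mode, timestamp, is_directory "
                    "FROM opened_files ORDER BY timestamp, id"
                )
            )
        except sqlite3.DatabaseError as exc:
            raise TraceFormatError(
                f"corrupt trace database {trace_db_path}: {exc}"
            ) from exc
    finally:
        con.close()

    if not proc_rows:
        raise EmptyTraceError(f"trace database has zero processes: {trace_db_path}")

    # First exec event per process carries executable/argv/workingdir;
    # processes that never exec inherit them from their parent (plain forks).
    execs: dict[str, tuple[str, tuple[str, ...], str]] = {}
    for pid, name, argv, workingdir, _ts in exec_rows:
        key = str(pid)
        if key not in execs:
            tokens = tuple(t for t in str(argv).split("\x00") if t != "")
            execs[key] = (str(name), tokens or (str(name),), str(workingdir))

    processes: list[ProcessRecord] = []
    known: dict[str, ProcessRecord] = {}
    for ordinal, (pid, parent, _ts, is_thread) in enumerate(proc_rows, start=1):
        key, parent_key = str(pid), (None if parent is None else str(parent))
        info = execs.get(key)
        if info is None and parent_key is not None and parent_key in known:
            parent_rec = known[parent_key]
            info = (parent_rec.executable_path, parent_rec.argv, parent_rec.working_dir)
        if info is None:
            raise TraceFormatError(
                f"process {key} has no executed_files row and no parent to "
                f"inherit from: {trace_db_path}"
            )
        rec = ProcessRecord(
            process_id=key,
            parent_id=parent_key,
            executable_path=info[0],
            argv=info[1],
            working_dir=info[2],
            start_ordinal=ordinal,
            spawn_kind="exec-root"
            if parent_key is None
            else ("clone" if is_thread else "fork"),
        )
        known[key] = rec
        processes.append(rec)

    merged: dict[tuple[str, str], tuple[str, int]] = {}
    for ordinal, (pid, name, mode, _ts, is_dir) in enumerate(open_rows, start=1):
        if is_dir:
            continue
        mode = int(mode)
        read, write = bool(mode & _FILE_READ), bool(mode & _FILE_WRITE)
        if not (read or write):
            continue  # stat / wdir-only events carry no dataflow
        access_mode = "read_write" if (read and write) else ("write" if write else "read")
        key = (str(pid), posixpath.normpath(str(name)))
        if key in merged:
            prev_mode, prev_ordinal = merged[key]
            merged[key] = (merge_modes(prev_mode, access_mode), prev_ordinal)
        else:
            merged[key] = (access_mode, ordinal)

    deleted = {posixpath.normpath(p) for p in deleted_paths}
    deleter: dict[str, tuple[int, str]] = {}
    for (pid, path), (_m, ordinal) in merged.items():
        if path in deleted:
            if path not in deleter or ordinal > deleter[path][0]:
                deleter[path] = (ordinal, pid)

    accesses = [
        FileAccessRecord(
            process_id=pid,
            path=path,
            mode=mode,
            first_access_ordinal=ordinal,
            deleted_by_process=(path in deleter and deleter[path][1] == pid),
        )
        for (pid, path), (mode, ordinal) in sorted(
            merged.items(), key=lambda kv: kv[1][1]
        )
    ]

    records = TraceRecordSet(processes=processes, accesses=accesses)
    records.validate()
    return records


# ---------------------------------------------------------------------------
# JSON dialect

_PROCESS_FIELDS = (
    "process_id",
    "parent_id",
    "executable_path",
    "argv",
    "working_dir",
    "start_ordinal",
    "spawn_kind",
)
_ACCESS_FIELDS = (
    "process_id",
    "path",
    "mode",
    "first_access_ordinal",
    "deleted_by_process",
)


def write_trace_json(records: TraceRecordSet, path: str | os.PathLike) -> None:
    """Serialize a record set to the JSON trace dialect."""
    doc = {
        "condition": records.condition_label,
        "metadata": dict(records.metadata),
        "processes": [
            {f: (list(getattr(p, f)) if f == "argv" else getattr(p, f))
             for f in _PROCESS_FIELDS}
            for p in records.processes
        ],
        "accesses": [
            {f: getattr(a, f) for f in _ACCESS_FIELDS} for a in records.accesses
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False))


def read_trace_json(path: str | os.PathLike) -> TraceRecordSet:
    """Read the JSON trace dialect; validates schema and invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise TraceFormatError(f"unreadable JSON trace {path}: {exc}") from exc
    if not isinstance(doc, dict) or "processes" not in doc or "accesses" not in doc:
        raise TraceValidationError(
            "JSON trace must be an object with 'processes' and 'accesses'"
        )
    processes = []
    for entry in doc["processes"]:
        for f in _PROCESS_FIELDS:
            if f not in entry:
                raise TraceValidationError(f"process entry missing field {f!r}")
        processes.append(
            ProcessRecord(**{f: (tuple(entry[f]) if f == "argv" else entry[f])
                             for f in _PROCESS_FIELDS})
        )
    accesses = []
    for entry in doc["accesses"]:
        for f in _ACCESS_FIELDS:
            if f not in entry:
                raise TraceValidationError(f"access entry missing field {f!r}")
        accesses.append(FileAccessRecord(**{f: entry[f] for f in _ACCESS_FIELDS}))
    records = TraceRecordSet(
        processes=processes,
        accesses=accesses,
        condition_label=doc.get("condition", ""),
        metadata={str(k): str(v) for k, v in doc.get("metadata", {}).items()},
    )
    records.validate()
    return records


# ---------------------------------------------------------------------------
# Path remapping

def remap_path(path: str, prefix_map: Sequence[tuple[str, str]]) -> str:
    """Rewrite ``path`` by the longest matching absolute prefix in the map.

    A prefix matches only at a path-component boundary; unmatched paths
    pass through unchanged.
    """
    best: tuple[str, str] | None = None
    for old, new in prefix_map:
        old = old.rstrip("/") or "/"
        if path == old or path.startswith(old + "/"):
            if best is None or len(old) > len(best[0]):
                best = (old, new)
    if best is None:
        return path
    old, new = best
    suffix = path[len(old):]
    return (new.rstrip("/") or "/") + suffix if suffix else new


def normalize_paths(
    records: TraceRecordSet, prefix_map: Sequence[tuple[str, str]]
) -> TraceRecordSet:
    """Return a copy with access, executable and working-dir paths remapped.

    ``prefix_map`` is an ordered sequence of (old, new) absolute prefixes;
    the longest matching old prefix wins.  All non-path fields are
    untouched.
    """
    for old, new in prefix_map:
        if not (old.startswith("/") and new.startswith("/")):
            raise TraceValidationError(
                f"prefix map entries must be absolute: {(old, new)!r}"
            )
    return TraceRecordSet(
        processes=[
            replace(
                p,
                executable_path=remap_path(p.executable_path, prefix_map),
                working_dir=remap_path(p.working_dir, prefix_map),
            )
            for p in records.processes
        ],
        accesses=[
            replace(a, path=remap_path(a.path, prefix_map)) for a in records.accesses
        ],
        condition_label=records.condition_label,
        metadata=dict(records.metadata),
    )
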