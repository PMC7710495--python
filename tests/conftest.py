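"""Shared builders for synthetic traces and trees."""

from __future__ import annotations

import pytest

from provdiff.provenance import ProcessTree
from provdiff.trace_model import FileAccessRecord, ProcessRecord, TraceRecordSet


def make_records(
    procs: list[tuple],
    accesses: list[tuple],
    condition: str = "test",
) -> TraceRecordSet:
    """Terse trace builder.

    procs: (pid, parent, executable[, argv]) in start order.
    accesses: (pid, path, mode[, deleted]) in event order.
    """
    processes = []
    for ordinal, entry in enumerate(procs, start=1):
        pid, parent, executable = entry[:3]
        argv = entry[3] if len(entry) > 3 else (executable.rsplit("/", 1)[-1],)
        processes.append(
            ProcessRecord(
                process_id=pid,
                parent_id=parent,
                executable_path=executable,
                argv=tuple(argv),
                working_dir="/work",
                start_ordinal=ordinal,
                spawn_kind="exec-root" if parent is None else "fork",
            )
        )
    access_records = []
    base = len(processes)
    for ordinal, entry in enumerate(accesses, start=base + 1):
        pid, path, mode = entry[:3]
        deleted = entry[3] if len(entry) > 3 else False
        access_records.append(
            FileAccessRecord(
                process_id=pid,
                path=path,
                mode=mode,
                first_access_ordinal=ordinal,
                deleted_by_process=deleted,
            )
        )
    records = TraceRecordSet(
        processes=processes, accesses=access_records, condition_label=condition
    )
    records.validate()
    return records


def make_tree(spec) -> ProcessTree:
    """Build a ProcessTree from nested ('label', [children...]) tuples."""
    children: dict[str, list[str]] = {}
    labels: dict[str, dict] = {}
    counter = [0]

    def visit(node, parent_id):
        counter[0] += 1
        pid = f"n{counter[0]}"
        label, kids = node
        labels[pid] = {
            "executable": f"/opt/{label}",
            "argv": (label,),
            "spawn_kind": "exec-root" if parent_id is None else "fork",
            "start_ordinal": counter[0],
        }
        children[pid] = []
        if parent_id is not None:
            children[parent_id].append(pid)
        for kid in kids:
            visit(kid, pid)
        return pid

    root = visit(spec, None)
    return ProcessTree(root=root, children=children, labels=labels)


@pytest.fixture
def chain_records() -> TraceRecordSet:
    """Three user processes chained through files, plus a /bin/sh root."""
    return make_records(
        procs=[
            ("p0", None, "/bin/sh"),
            ("p1", "p0", "/opt/tools/bet2"),
            ("p2", "p0", "/opt/tools/fslmaths"),
            ("p3", "p0", "/opt/tools/fslstats"),
        ],
        accesses=[
            ("p1", "/work/t1.nii", "read"),
            ("p1", "/work/brain.nii", "write"),
            ("p2", "/work/brain.nii", "read"),
            ("p2", "/work/masked.nii", "write"),
            ("p3", "/work/masked.nii", "read"),
            ("p3", "/work/volume.txt", "write"),
        ],
    )
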