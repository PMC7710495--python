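"""Two-condition process labeling with difference-propagation blocking.

The core question answered here: *which* process of a pipeline produces
different results when the pipeline is executed under two computational
conditions (e.g. two OS versions)?  Simply diffing the final outputs
cannot answer it, because a numerical difference created by one process
propagates through every downstream process and masks their own
behavior.

The protocol re-executes the pipeline *step by step* in the second
condition, in topological order of the versioned DAG.  After each
process runs, its output file versions are compared — via the pluggable
comparator registry — against the archived versions from the reference
condition.  If they match, the process is *reproducible*; if not, it is
*non-reproducible* and the reference versions are copied over the fresh
outputs before any successor runs, so downstream processes are judged
only on their own computation (propagation blocking).

Because the verdicts can depend on which condition serves as reference,
the comparison runs in both orders; a process is non-reproducible if it
differs in at least one order.  The complete evaluation of a pipeline
therefore costs exactly five executions: (1) trace recording in A,
(2) wrapped capture in A, (3) step-wise comparison in B, (4) wrapped
capture in B, (5) step-wise comparison in A.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

from .comparators import ComparatorRegistry
from .provenance import DEFAULT_BLACKLIST, build_provenance_graph, filter_processes
from .transient import (
    VersionedDAG,
    check_concurrent_writes,
    disambiguate_versions,
    find_transient_files,
    generate_wrapper_scripts,
)

__all__ = [
    "REPRODUCIBLE",
    "NON_REPRODUCIBLE",
    "NOT_RUN",
    "ConditionStore",
    "LabelRecord",
    "LabeledDAG",
    "StepExecutor",
    "ConditionRunner",
    "ExecutionLogEntry",
    "EvaluationConfig",
    "CoverageError",
    "StepExecutionError",
    "label_processes",
    "combine_orders",
    "evaluate_pipeline",
]

REPRODUCIBLE = "reproducible"
NON_REPRODUCIBLE = "non_reproducible"
NOT_RUN = "not_run"


class CoverageError(RuntimeError):
    """The reference store lacks an output version the DAG requires."""


class StepExecutionError(RuntimeError):
    """A pipeline process exited with a nonzero status during re-execution."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ConditionStore:
    """Read-only archive of the file versions written under one condition.

    Indexed by (executable basename, instance, path, version); entries
    carry the archived file and its SHA-256.  Populated by the
    wrapper-script capture run (:func:`transient.generate_wrapper_scripts`).
    """

    condition_label: str
    store_dir: Path
    index: dict[tuple[str, str, str, int], tuple[Path, str]] = field(
        default_factory=dict
    )

    @classmethod
    def load(cls, condition_label: str, store_dir: str | Path) -> "ConditionStore":
        store_dir = Path(store_dir)
        store = cls(condition_label=condition_label, store_dir=store_dir)
        for manifest in sorted(store_dir.glob("*/*/manifest.json")):
            base, instance = manifest.parent.parent.name, manifest.parent.name
            for entry in json.loads(manifest.read_text()):
                key = (base, instance, entry["path"], int(entry["version"]))
                store.index[key] = (store_dir / entry["file"], entry["sha256"])
        return store

    def lookup(
        self, basename: str, instance: int, path: str, version: int
    ) -> tuple[Path, str] | None:
        return self.index.get((basename, str(instance), path, version))


@dataclass
class LabelRecord:
    """Per-process verdicts for the two condition orders."""

    process_id: str
    label_order_ab: str = NOT_RUN
    label_order_ba: str = NOT_RUN
    differing_files: list[tuple[str, int]] = field(default_factory=list)

    @property
    def combined(self) -> str:
        labels = (self.label_order_ab, self.label_order_ba)
        if NON_REPRODUCIBLE in labels:
            return NON_REPRODUCIBLE
        if NOT_RUN in labels:
            return NOT_RUN
        return REPRODUCIBLE


@dataclass
class LabeledDAG:
    """Versioned DAG plus per-process labels from both condition orders."""

    dag: VersionedDAG
    records: dict[str, LabelRecord]
    condition_a: str = ""
    condition_b: str = ""

    def combined_label(self, process_id: str) -> str:
        return self.records[process_id].combined

    def non_reproducible(self) -> set[str]:
        return {
            pid for pid, r in self.records.items() if r.combined == NON_REPRODUCIBLE
        }

    def non_reproducible_basenames(self) -> set[str]:
        return {
            self.dag.process_attrs(pid)["basename"]
            for pid in self.non_reproducible()
        }

    def to_json_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "processes": [
                {
                    "process_id": pid,
                    "basename": self.dag.process_attrs(pid)["basename"],
                    "instance": self.dag.process_attrs(pid)["instance"],
                    "executable": self.dag.process_attrs(pid)["executable"],
                    "working_dir": self.dag.process_attrs(pid).get("working_dir", ""),
                    "start_ordinal": self.dag.process_attrs(pid)["start_ordinal"],
                    "label_order_ab": self.records[pid].label_order_ab,
                    "label_order_ba": self.records[pid].label_order_ba,
                    "combined": self.records[pid].combined,
                    "differing_files": [
                        list(t) for t in self.records[pid].differing_files
                    ],
                    "outputs": [list(t) for t in self.dag.outputs_of(pid)],
                    "inputs": [list(t) for t in self.dag.inputs_of(pid)],
                }
                for pid in self.dag.process_ids()
            ],
        }


@runtime_checkable
class StepExecutor(Protocol):
    """Runs single processes of the pipeline under one condition.

    ``prepare`` sets up a clean working directory seeded with the
    pipeline inputs; ``run`` executes one DAG process in it;
    ``resolve`` maps a DAG path (recorded in the reference condition's
    working directory) to this executor's local path.
    """

    def prepare(self) -> None: ...

    def run(self, process_id: str) -> None: ...

    def resolve(self, path: str) -> Path: ...


@runtime_checkable
class ConditionRunner(Protocol):
    """One computational condition able to run the pipeline."""

    label: str

    def run_traced(self): ...

    def run_wrapped(self, dag: VersionedDAG, wrapper_dir: Path,
                    store_dir: Path) -> None: ...

    def make_executor(self, dag: VersionedDAG) -> StepExecutor: ...


def label_processes(
    dag: VersionedDAG,
    reference: ConditionStore,
    executor: StepExecutor,
    comparators: ComparatorRegistry,
) -> dict[str, LabelRecord]:
    """Step-wise re-execution in one condition against a reference store.

    Processes are visited in topological order (ties broken by trace
    start ordinal, i.e. the original schedule).  Output versions are
    compared to the reference archive; on any difference the process is
    labeled non-reproducible and every differing output version is
    replaced by the reference content before successors run.  A process
    whose execution fails — and all its descendants — is ``not_run``.

    Returns one :class:`LabelRecord` per DAG process with the verdict in
    ``label_order_ab`` (the single-order slot; order combination happens
    in :func:`combine_orders`).
    """
    executor.prepare()
    records = {pid: LabelRecord(process_id=pid) for pid in dag.process_ids()}
    blocked: set[str] = set()

    for pid in dag.topological_processes():
        rec = records[pid]
        upstream = {
            dag.writer_of(path, version)
            for path, version in dag.inputs_of(pid)
            if version >= 1
        }
        if blocked & {u for u in upstream if u is not None}:
            rec.label_order_ab = NOT_RUN
            blocked.add(pid)
            continue
        attrs = dag.process_attrs(pid)
        try:
            executor.run(pid)
        except StepExecutionError:
            rec.label_order_ab = NOT_RUN
            blocked.add(pid)
            continue

        differing: list[tuple[str, int]] = []
        for path, version in dag.outputs_of(pid):
            local = executor.resolve(path)
            ref = reference.lookup(
                attrs["basename"], attrs["instance"], path, version
            )
            if ref is None:
                if local.is_file():
                    raise CoverageError(
                        f"reference store of condition {reference.condition_label!r}"
                        f" lacks {path}@{version} written by {pid}"
                    )
                continue  # invisible on both sides (self-deleted temp)
            ref_path, ref_sha = ref
            if not local.is_file():
                differing.append((path, version))
                continue
            if _sha256(local) == ref_sha:
                continue
            equal, _detail = comparators.compare(path, ref_path, local)
            if not equal:
                differing.append((path, version))

        if differing:
            rec.label_order_ab = NON_REPRODUCIBLE
            rec.differing_files = differing
            for path, version in differing:
                ref_path, _sha = reference.lookup(
                    attrs["basename"], attrs["instance"], path, version
                )
                local = executor.resolve(path)
                local.parent.mkdir(parents=True, exist_ok=True)
                shutil.copyfile(ref_path, local)
        else:
            rec.label_order_ab = REPRODUCIBLE
    return records


def combine_orders(
    ab: dict[str, LabelRecord], ba: dict[str, LabelRecord], dag: VersionedDAG,
    condition_a: str = "A", condition_b: str = "B",
) -> LabeledDAG:
    """Merge the two per-order labelings into the final labeled DAG.

    A process is non-reproducible if it produced different results in at
    least one condition order (set union).
    """
    if set(ab) != set(ba):
        raise ValueError(
            "process sets of the two orders differ: "
            f"{sorted(set(ab) ^ set(ba))}"
        )
    merged: dict[str, LabelRecord] = {}
    for pid in ab:
        rec = LabelRecord(
            process_id=pid,
            label_order_ab=ab[pid].label_order_ab,
            label_order_ba=ba[pid].label_order_ab,
        )
        rec.differing_files = sorted(
            set(ab[pid].differing_files) | set(ba[pid].differing_files)
        )
        merged[pid] = rec
    return LabeledDAG(
        dag=dag, records=merged, condition_a=condition_a, condition_b=condition_b
    )


@dataclass(frozen=True)
class ExecutionLogEntry:
    stage: int
    description: str
    condition: str


@dataclass
class EvaluationConfig:
    """Knobs of the five-execution protocol."""

    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST
    comparators: ComparatorRegistry = field(default_factory=ComparatorRegistry)
    work_root: Path | None = None


def evaluate_pipeline(
    runner_a: ConditionRunner,
    runner_b: ConditionRunner,
    config: EvaluationConfig | None = None,
) -> tuple[LabeledDAG, list[ExecutionLogEntry]]:
    """Run the full five-execution, two-order evaluation protocol.

    1. record a trace in condition A;
    2. re-run in A with capture wrappers, archiving every output version;
    3. re-run step by step in B, labeling against A's archive;
    4. re-run in B with capture wrappers;
    5. re-run step by step in A, labeling against B's archive;
    then combine the two orders.  Exactly five pipeline executions are
    performed regardless of pipeline size; the log records one entry per
    execution.
    """
    config = config or EvaluationConfig()
    root = Path(config.work_root).resolve() if config.work_root else Path(
        tempfile.mkdtemp(prefix="provdiff-eval-")
    )
    root.mkdir(parents=True, exist_ok=True)
    log: list[ExecutionLogEntry] = []

    records = runner_a.run_traced()
    log.append(ExecutionLogEntry(1, "trace recording", runner_a.label))

    graph = filter_processes(build_provenance_graph(records), config.blacklist)
    report = find_transient_files(graph, records)
    for path in report.multi_writer_files:
        violations = check_concurrent_writes(records, path)
        if violations:
            raise RuntimeError(
                f"stage 'transient analysis' failed: concurrent writes on "
                f"{path}: {violations}"
            )
    dag = disambiguate_versions(graph, report)

    store_a_dir = root / "store_a"
    runner_a.run_wrapped(dag, root / "wrappers_a", store_a_dir)
    log.append(ExecutionLogEntry(2, "wrapped capture", runner_a.label))
    store_a = ConditionStore.load(runner_a.label, store_a_dir)

    labels_ab = label_processes(
        dag, store_a, runner_b.make_executor(dag), config.comparators
    )
    log.append(ExecutionLogEntry(3, "step-wise comparison", runner_b.label))

    store_b_dir = root / "store_b"
    runner_b.run_wrapped(dag, root / "wrappers_b", store_b_dir)
    log.append(ExecutionLogEntry(4, "wrapped capture", runner_b.label))
    store_b = ConditionStore.load(runner_b.label, store_b_dir)

    labels_ba = label_processes(
        dag, store_b, runner_a.make_executor(dag), config.comparators
    )
    log.append(ExecutionLogEntry(5, "step-wise comparison", runner_a.label))

    labeled = combine_orders(
        labels_ab, labels_ba, dag,
        condition_a=runner_a.label, condition_b=runner_b.label,
    )
    return labeled, log
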