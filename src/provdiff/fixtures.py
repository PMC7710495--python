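"""Synthetic traced pipelines with known ground truth.

Real pipeline evaluations need containers, neuroimaging toolboxes and
hours of compute; every algorithm in this package is instead exercised
end-to-end on synthetic pipelines that *actually execute* as
subprocesses while recording their own trace.

A :class:`PipelineSpec` declares ordered steps — each reads input
files, writes outputs as a deterministic hash transform of the input
bytes, and may delete files.  Materializing a spec writes one POSIX
shell script per executable basename into a ``bin/`` directory; the
runner invokes the steps through the executable search path, so
PATH-shim wrappers genuinely intercept them.  A *condition-sensitive*
step emulates an OS-dependent numerical difference: a deterministic
pseudo-random perturbation of its output bytes keyed by (condition
label, noise seed), so two runs under the same condition are
byte-identical while runs under different conditions differ — the
controlled stand-in for library-update noise, which cannot be packaged.

The built-in tracer records the same information system-call
interception would provide (processes, merged file accesses, deletions,
ordinals) and emits the portable JSON trace dialect; a converter writes
a minimal ReproZip-layout SQLite database for testing that ingestion
route.
"""

from __future__ import annotations

import json
import os
import random
import shutil
import sqlite3
import stat
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path

from .labeling import StepExecutionError
from .trace_model import (
    FileAccessRecord,
    ProcessRecord,
    TraceRecordSet,
    merge_modes,
    remap_path,
)
from .transient import VersionedDAG, generate_wrapper_scripts

__all__ = [
    "StepSpec",
    "PipelineSpec",
    "GroundTruth",
    "FixtureError",
    "make_brain_volume_spec",
    "random_spec",
    "run_pipeline",
    "run_single_step",
    "synthesize_trace",
    "materialize",
    "write_reprozip_db",
    "FixtureConditionRunner",
    "FixtureStepExecutor",
]

#: environment variable carrying the condition label to step executables
CONDITION_ENV = "PIPELINE_CONDITION"


class FixtureError(RuntimeError):
    """Fixture construction or execution failure."""


@dataclass(frozen=True)
class StepSpec:
    """One pipeline step: a real subprocess with declared file I/O."""

    name: str
    executable: str  # basename; need not be unique across steps
    inputs: tuple[str, ...]  # workdir-relative paths read
    outputs: tuple[str, ...]  # workdir-relative paths written
    deletes: tuple[str, ...] = ()  # workdir-relative paths removed after the step
    transform: str = "hash-chain"
    condition_sensitive: bool = False
    noise_seed: int = 0
    output_size: int = 2048


@dataclass(frozen=True)
class PipelineSpec:
    """Declarative synthetic pipeline: ordered steps plus initial inputs."""

    steps: tuple[StepSpec, ...]
    pipeline_inputs: tuple[str, ...]
    input_size: int = 1024
    name: str = "fixture"

    def step_for(self, basename: str, instance: int) -> StepSpec:
        """The ``instance``-th (1-based) step invoking ``basename``."""
        same = [s for s in self.steps if s.executable == basename]
        if not 1 <= instance <= len(same):
            raise FixtureError(
                f"no step #{instance} with executable {basename!r}"
            )
        return same[instance - 1]

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "pipeline_inputs": list(self.pipeline_inputs),
            "input_size": self.input_size,
            "steps": [
                {
                    "name": s.name,
                    "executable": s.executable,
                    "inputs": list(s.inputs),
                    "outputs": list(s.outputs),
                    "deletes": list(s.deletes),
                    "transform": s.transform,
                    "condition_sensitive": s.condition_sensitive,
                    "noise_seed": s.noise_seed,
                    "output_size": s.output_size,
                }
                for s in self.steps
            ],
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "PipelineSpec":
        return cls(
            steps=tuple(
                StepSpec(
                    name=s["name"],
                    executable=s["executable"],
                    inputs=tuple(s["inputs"]),
                    outputs=tuple(s["outputs"]),
                    deletes=tuple(s.get("deletes", ())),
                    transform=s.get("transform", "hash-chain"),
                    condition_sensitive=s.get("condition_sensitive", False),
                    noise_seed=s.get("noise_seed", 0),
                    output_size=s.get("output_size", 2048),
                )
                for s in doc["steps"]
            ),
            pipeline_inputs=tuple(doc["pipeline_inputs"]),
            input_size=doc.get("input_size", 1024),
            name=doc.get("name", "fixture"),
        )


@dataclass(frozen=True)
class GroundTruth:
    """What a correct analysis must recover from the fixture."""

    non_reproducible_steps: frozenset[str]
    deleted_files: frozenset[str]  # workdir-relative
    multi_writer_files: frozenset[str]
    version_counts: dict[str, int]  # relative path → number of writers

    @property
    def transient_files(self) -> frozenset[str]:
        return self.deleted_files | self.multi_writer_files


def _ground_truth_of(spec: PipelineSpec) -> GroundTruth:
    writers: dict[str, int] = {}
    deleted: set[str] = set()
    for step in spec.steps:
        for out in step.outputs:
            writers[out] = writers.get(out, 0) + 1
        deleted.update(step.deletes)
    return GroundTruth(
        non_reproducible_steps=frozenset(
            s.name for s in spec.steps if s.condition_sensitive
        ),
        deleted_files=frozenset(deleted),
        multi_writer_files=frozenset(p for p, n in writers.items() if n >= 2),
        version_counts=writers,
    )


def make_brain_volume_spec(sensitive: bool = True) -> tuple[PipelineSpec, GroundTruth]:
    """Three-step brain-volume toy pipeline: mask extraction → masking → stats.

    Step 1 (``bet2``-shaped mask extraction) is condition-sensitive when
    ``sensitive`` is true; steps 2–3 are deterministic functions of
    their inputs, so exactly step 1 must come out non-reproducible.
    Step 2 deletes the auxiliary brain image, providing one transient
    file.
    """
    spec = PipelineSpec(
        name="brain-volume",
        pipeline_inputs=("t1.nii",),
        steps=(
            StepSpec(
                name="bet2",
                executable="bet2",
                inputs=("t1.nii",),
                outputs=("brain.nii", "brain_mask.nii"),
                condition_sensitive=sensitive,
                noise_seed=11,
            ),
            StepSpec(
                name="fslmaths",
                executable="fslmaths",
                inputs=("t1.nii", "brain_mask.nii"),
                outputs=("t1_masked.nii",),
                deletes=("brain.nii",),
            ),
            StepSpec(
                name="fslstats",
                executable="fslstats",
                inputs=("t1_masked.nii",),
                outputs=("volume.txt",),
            ),
        ),
    )
    return spec, _ground_truth_of(spec)


def random_spec(
    n_steps: int,
    seed: int,
    p_sensitive: float = 0.3,
    p_transient: float = 0.2,
    p_multiwriter: float = 0.2,
) -> tuple[PipelineSpec, GroundTruth]:
    """Random DAG-shaped pipeline with the stated marginal rates.

    Each step reads 1–2 previously produced files, writes one fresh
    file, and with probability ``p_multiwriter`` additionally rewrites
    an earlier step's file (creating a multi-writer path).  After the
    dataflow is fixed, each step-written file is, with probability
    ``p_transient``, deleted by its last accessor — never by one of its
    own writers, so every written version is observable at its writer's
    exit.  A fixed seed yields an identical spec.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    for name, p in (
        ("p_sensitive", p_sensitive),
        ("p_transient", p_transient),
        ("p_multiwriter", p_multiwriter),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = random.Random(seed)
    pipeline_inputs = ("input_0.dat",)
    available = list(pipeline_inputs)
    step_written: list[str] = []
    steps: list[StepSpec] = []
    for i in range(1, n_steps + 1):
        n_in = rng.randint(1, min(2, len(available)))
        inputs = tuple(rng.sample(available, n_in))
        outputs = [f"f{i}.dat"]
        if step_written and rng.random() < p_multiwriter:
            target = rng.choice(step_written)
            if target not in outputs:
                outputs.append(target)
        steps.append(
            StepSpec(
                name=f"step{i}",
                executable=rng.choice([f"tool{i}", f"tool{i}", "shared_tool"]),
                inputs=inputs,
                outputs=tuple(outputs),
                condition_sensitive=rng.random() < p_sensitive,
                noise_seed=rng.randrange(2**31),
                output_size=rng.choice([512, 1024, 2048]),
            )
        )
        step_written.append(f"f{i}.dat")
        available.append(f"f{i}.dat")

    # deletions: a file's last accessor may delete it, unless it wrote it
    last_accessor: dict[str, int] = {}
    writers_of: dict[str, set[int]] = {}
    for idx, step in enumerate(steps):
        for p in step.inputs:
            last_accessor[p] = idx
        for p in step.outputs:
            last_accessor[p] = idx
            writers_of.setdefault(p, set()).add(idx)
    deletions: dict[int, list[str]] = {}
    for path in step_written:
        idx = last_accessor[path]
        if idx in writers_of.get(path, set()):
            continue
        if rng.random() < p_transient:
            deletions.setdefault(idx, []).append(path)
    steps = [
        replace(s, deletes=tuple(sorted(deletions.get(i, []))))
        for i, s in enumerate(steps)
    ]
    spec = PipelineSpec(
        steps=tuple(steps),
        pipeline_inputs=pipeline_inputs,
        name=f"random-{seed}",
    )
    return spec, _ground_truth_of(spec)


# ---------------------------------------------------------------------------
# Materialization: step scripts + input files

# Stdlib-only step interpreter, written into the fixture bin directory and
# exec'd by every generated step script.  Outputs are a SHA-256 counter
# stream keyed by (step, output path, input digests); sensitive steps
# overwrite the leading bytes with a digest of (condition, noise seed).
_STEPRUN = '''\
import hashlib, json, os, sys


def stream(key, n):
    out = bytearray()
    counter = 0
    while len(out) < n:
        out += hashlib.sha256(key + counter.to_bytes(8, "big")).digest()
        counter += 1
    return bytes(out[:n])


cfg_path = sys.argv[1]
args = sys.argv[2:]
try:
    name = args[args.index("--step") + 1]
except (ValueError, IndexError):
    sys.stderr.write("step: missing --step NAME\\n")
    sys.exit(2)
with open(cfg_path) as fh:
    step = json.load(fh)[name]
if step["transform"] != "hash-chain":
    sys.stderr.write("step: unknown transform %r\\n" % step["transform"])
    sys.exit(2)
digest = hashlib.sha256()
for p in step["inputs"]:
    with open(p, "rb") as fh:
        digest.update(hashlib.sha256(fh.read()).digest())
in_key = digest.digest()
for out in step["outputs"]:
    key = name.encode() + b"\\0" + out.encode() + b"\\0" + in_key
    content = bytearray(stream(key, step["output_size"]))
    if step["condition_sensitive"]:
        cond = os.environ.get("PIPELINE_CONDITION", "")
        nk = hashlib.sha256(
            ("noise:%s:%d:%s" % (cond, step["noise_seed"], out)).encode()
        ).digest()
        content[: len(nk) // 2] = nk[: len(nk) // 2]
    d = os.path.dirname(out)
    if d:
        os.makedirs(d, exist_ok=True)
    with open(out, "wb") as fh:
        fh.write(bytes(content))
for path in step["deletes"]:
    os.remove(path)
'''

_STEP_SCRIPT = """#!/bin/sh
exec python3 -E -S {steprun_q} {cfg_q} "$@"
"""


def _sh_quote(s: str) -> str:
    return "'" + s.replace("'", "'\\''") + "'"


def _input_content(path: str, size: int) -> bytes:
    import hashlib

    key = b"pipeline-input:" + path.encode()
    out = bytearray()
    counter = 0
    while len(out) < size:
        out += hashlib.sha256(key + counter.to_bytes(8, "big")).digest()
        counter += 1
    return bytes(out[:size])


def materialize(spec: PipelineSpec, workdir: str | os.PathLike) -> Path:
    """Create the fixture working directory: inputs, bin/ scripts, configs.

    The directory must be clean (absent or empty).  Returns the bin
    directory to place on the executable search path.
    """
    workdir = Path(workdir).resolve()
    if workdir.exists() and any(workdir.iterdir()):
        raise FixtureError(f"workdir not clean: {workdir}")
    bindir = workdir / "bin"
    bindir.mkdir(parents=True, exist_ok=True)
    for rel in spec.pipeline_inputs:
        target = workdir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(_input_content(rel, spec.input_size))
    steprun = bindir / "_steprun.py"
    steprun.write_text(_STEPRUN)
    by_base: dict[str, dict[str, dict]] = {}
    for s in spec.steps:
        by_base.setdefault(s.executable, {})[s.name] = {
            "name": s.name,
            "inputs": list(s.inputs),
            "outputs": list(s.outputs),
            "deletes": list(s.deletes),
            "transform": s.transform,
            "condition_sensitive": s.condition_sensitive,
            "noise_seed": s.noise_seed,
            "output_size": s.output_size,
        }
    for base, steps in by_base.items():
        cfg = bindir / f"{base}.steps.json"
        cfg.write_text(json.dumps(steps, indent=1))
        script = bindir / base
        script.write_text(
            _STEP_SCRIPT.format(
                steprun_q=_sh_quote(str(steprun)), cfg_q=_sh_quote(str(cfg))
            )
        )
        script.chmod(
            script.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH
        )
    return bindir


def _step_argv(step: StepSpec) -> list[str]:
    return [step.executable, "--step", step.name, *step.inputs, *step.outputs]


def _run_step(
    step: StepSpec,
    workdir: Path,
    condition_label: str,
    extra_path: list[str],
) -> None:
    env = dict(os.environ)
    env["PATH"] = ":".join([*extra_path, env.get("PATH", "")])
    env[CONDITION_ENV] = condition_label
    argv = _step_argv(step)
    # resolve through the shell so PATH shims genuinely intercept
    proc = subprocess.run(
        ["/bin/sh", "-c", 'exec "$0" "$@"', *argv],
        cwd=str(workdir),
        env=env,
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise StepExecutionError(
            f"step {step.name!r} ({step.executable}) exited with "
            f"{proc.returncode}: {proc.stderr.strip()}"
        )


def run_single_step(
    spec: PipelineSpec,
    step: StepSpec,
    workdir: str | os.PathLike,
    condition_label: str,
    wrapper_dir: str | os.PathLike | None = None,
) -> None:
    """Execute one step of an already materialized fixture."""
    workdir = Path(workdir).resolve()
    path = [str(workdir / "bin")]
    if wrapper_dir is not None:
        path.insert(0, str(wrapper_dir))
    _run_step(step, workdir, condition_label, path)


def _build_trace(
    spec: PipelineSpec, workdir: Path, condition_label: str
) -> TraceRecordSet:
    ordinal = 1
    processes = [
        ProcessRecord(
            process_id="p0",
            parent_id=None,
            executable_path="/bin/sh",
            argv=("sh", str(workdir / "pipeline")),
            working_dir=str(workdir),
            start_ordinal=ordinal,
            spawn_kind="exec-root",
        )
    ]
    accesses: list[FileAccessRecord] = []
    for i, step in enumerate(spec.steps, start=1):
        ordinal += 1
        pid = f"p{i}"
        processes.append(
            ProcessRecord(
                process_id=pid,
                parent_id="p0",
                executable_path=str(workdir / "bin" / step.executable),
                argv=tuple(_step_argv(step)),
                working_dir=str(workdir),
                start_ordinal=ordinal,
                spawn_kind="fork",
            )
        )
        merged: dict[str, tuple[str, int, bool]] = {}
        for rel in step.inputs:
            ordinal += 1
            merged[rel] = ("read", ordinal, False)
        for rel in step.outputs:
            ordinal += 1
            if rel in merged:
                mode, first, deleted = merged[rel]
                merged[rel] = (merge_modes(mode, "write"), first, deleted)
            else:
                merged[rel] = ("write", ordinal, False)
        for rel in step.deletes:
            if rel in merged:
                mode, first, _ = merged[rel]
                merged[rel] = (mode, first, True)
            else:
                ordinal += 1
                merged[rel] = ("read", ordinal, True)
        for rel, (mode, first, deleted) in sorted(
            merged.items(), key=lambda kv: kv[1][1]
        ):
            accesses.append(
                FileAccessRecord(
                    process_id=pid,
                    path=str(workdir / rel),
                    mode=mode,
                    first_access_ordinal=first,
                    deleted_by_process=deleted,
                )
            )
    records = TraceRecordSet(
        processes=processes,
        accesses=accesses,
        condition_label=condition_label,
        metadata={"workdir": str(workdir), "pipeline": spec.name},
    )
    records.validate()
    return records


def synthesize_trace(
    spec: PipelineSpec,
    condition_label: str,
    workdir: str | os.PathLike,
) -> TraceRecordSet:
    """The trace :func:`run_pipeline` would record, without executing.

    Useful for graph-only analyses (construction, versioning,
    clustering) where the file contents are irrelevant.
    """
    return _build_trace(spec, Path(workdir).resolve(), condition_label)


def run_pipeline(
    spec: PipelineSpec,
    condition_label: str,
    workdir: str | os.PathLike,
    wrapper_dir: str | os.PathLike | None = None,
) -> TraceRecordSet:
    """Materialize and execute the full pipeline; return its trace.

    Steps run in declaration order as real subprocesses resolved
    through the executable search path (optionally behind PATH-shim
    wrappers).  The built-in tracer records the processes, merged file
    accesses and deletions with globally increasing ordinals.
    """
    workdir = Path(workdir).resolve()
    bindir = materialize(spec, workdir)
    path = [str(bindir)]
    if wrapper_dir is not None:
        path.insert(0, str(wrapper_dir))
    for step in spec.steps:
        _run_step(step, workdir, condition_label, path)
    return _build_trace(spec, workdir, condition_label)


# ---------------------------------------------------------------------------
# ReproZip-layout SQLite converter

def write_reprozip_db(
    records: TraceRecordSet, db_path: str | os.PathLike
) -> set[str]:
    """Write a minimal ReproZip v1.x layout database from a record set.

    ``read_write`` accesses become two ``opened_files`` rows (write then
    read) to exercise mode merging on ingestion.  ReproZip does not
    record unlinks, so the deleted-path set is returned for the caller
    to pass back into ``read_reprozip_trace``.
    """
    con = sqlite3.connect(str(db_path))
    try:
        con.executescript(
            """
            CREATE TABLE processes(
                id INTEGER PRIMARY KEY, run_id INTEGER, parent INTEGER,
                timestamp INTEGER, is_thread INTEGER, exitcode INTEGER);
            CREATE TABLE executed_files(
                id INTEGER PRIMARY KEY, name TEXT, run_id INTEGER,
                process INTEGER, argv TEXT, envp TEXT, workingdir TEXT,
                timestamp INTEGER);
            CREATE TABLE opened_files(
                id INTEGER PRIMARY KEY, run_id INTEGER, name TEXT,
                is_directory INTEGER, mode INTEGER, process INTEGER,
                timestamp INTEGER);
            """
        )
        pid_num = {
            p.process_id: i + 1
            for i, p in enumerate(
                sorted(records.processes, key=lambda p: p.start_ordinal)
            )
        }
        for p in records.processes:
            con.execute(
                "INSERT INTO processes(id, run_id, parent, timestamp, "
                "is_thread, exitcode) VALUES (?, 0, ?, ?, ?, 0)",
                (
                    pid_num[p.process_id],
                    None if p.parent_id is None else pid_num[p.parent_id],
                    p.start_ordinal * 10,
                    1 if p.spawn_kind == "clone" else 0,
                ),
            )
            con.execute(
                "INSERT INTO executed_files(name, run_id, process, argv, "
                "envp, workingdir, timestamp) VALUES (?, 0, ?, ?, '', ?, ?)",
                (
                    p.executable_path,
                    pid_num[p.process_id],
                    "\x00".join(p.argv),
                    p.working_dir,
                    p.start_ordinal * 10,
                ),
            )
        deleted: set[str] = set()
        for a in records.accesses:
            ts = a.first_access_ordinal * 10
            if a.mode == "read_write":
                rows = [(2, ts), (1, ts + 5)]
            else:
                rows = [(2 if a.mode == "write" else 1, ts)]
            for mode_bits, t in rows:
                con.execute(
                    "INSERT INTO opened_files(run_id, name, is_directory, "
                    "mode, process, timestamp) VALUES (0, ?, 0, ?, ?, ?)",
                    (a.path, mode_bits, pid_num[a.process_id], t),
                )
            if a.deleted_by_process:
                deleted.add(a.path)
        con.commit()
    finally:
        con.close()
    return deleted


# ---------------------------------------------------------------------------
# Condition runner / step executor for the labeling protocol

def _trace_root(dag: VersionedDAG) -> str:
    pids = dag.process_ids()
    if not pids:
        raise FixtureError("DAG has no processes")
    return dag.process_attrs(pids[0])["working_dir"]


@dataclass
class FixtureStepExecutor:
    """Runs single fixture steps in this condition's working directory."""

    spec: PipelineSpec
    condition_label: str
    workdir: Path
    dag: VersionedDAG

    def prepare(self) -> None:
        if self.workdir.exists():
            shutil.rmtree(self.workdir)
        materialize(self.spec, self.workdir)

    def run(self, process_id: str) -> None:
        attrs = self.dag.process_attrs(process_id)
        step = self.spec.step_for(attrs["basename"], attrs["instance"])
        run_single_step(self.spec, step, self.workdir, self.condition_label)

    def resolve(self, path: str) -> Path:
        return Path(
            remap_path(path, [(_trace_root(self.dag), str(self.workdir))])
        )


@dataclass
class FixtureConditionRunner:
    """One computational condition over a fixture pipeline.

    All executions of this condition reuse a single working directory
    (wiped before each run) so paths stay stable within the condition;
    cross-condition paths are reconciled by prefix remapping.
    """

    spec: PipelineSpec
    label: str
    root_dir: Path

    def __post_init__(self) -> None:
        self.root_dir = Path(self.root_dir).resolve()
        safe = "".join(c if c.isalnum() else "_" for c in self.label)
        self.workdir = self.root_dir / f"work_{safe}"

    def _clean(self) -> None:
        if self.workdir.exists():
            shutil.rmtree(self.workdir)

    def run_traced(self) -> TraceRecordSet:
        self._clean()
        return run_pipeline(self.spec, self.label, self.workdir)

    def run_wrapped(
        self, dag: VersionedDAG, wrapper_dir: Path, store_dir: Path
    ) -> None:
        wrappers = generate_wrapper_scripts(
            dag,
            wrapper_dir,
            store_dir,
            path_map=[(_trace_root(dag), str(self.workdir))],
        )
        self._clean()
        run_pipeline(
            self.spec, self.label, self.workdir,
            wrapper_dir=wrappers.path_prefix(),
        )

    def make_executor(self, dag: VersionedDAG) -> FixtureStepExecutor:
        return FixtureStepExecutor(
            spec=self.spec,
            condition_label=self.label,
            workdir=self.workdir,
            dag=dag,
        )
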