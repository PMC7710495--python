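# Methods

This note documents the model behind `provdiff`, its assumptions, the
numerical and design choices that were genuinely open, and what the
synthetic fixtures do and do not establish about real pipelines.

## Pipeline model and assumptions

A pipeline is a set of OS processes that exchange data exclusively
through files. The analysis assumes the pipeline can be arranged so
that:

* no two processes write the same file concurrently (processes may
  otherwise overlap);
* each process effectively reads its inputs, computes, and writes its
  outputs, releasing a *single* final version of every file it writes;
* a process that deletes a file it created itself is the file's only
  user;
* every process is identified by a command line (executable basename +
  argv), so it can be intercepted by a PATH shim.

Data passed in memory (e.g. results parsed from a child's stdout) is
invisible to a file-based analysis; differences created there are
attributed to the process that first writes them to a file. Equally,
the resolution is one OS process — a "non-reproducible" verdict points
at a process, not at a library or function inside it.

Cross-condition comparison additionally assumes the two conditions
produce *structurally identical* provenance graphs for the same input
data. This is checked, not assumed silently: `match_processes` errors
at the first divergence, and the tree-edit-distance clustering
(`cluster_process_trees`) groups executions into structural families so
that only same-family pairs are compared. When the assumption fails we
refuse to label rather than partially label.

## Trace ingestion

Traces come from ReproZip v1.x SQLite databases or from a JSON dialect
(documented in `trace_model`) emitted by the built-in fixture tracer.
Per (process, path) pair all opens are merged into one access whose
mode is the union (any write dominates; read+write in either order is
`read_write`); the graph needs only the direction of data flow, not the
open sequence. Paths are normalized lexically; symlink aliasing is not
resolved — two names for one inode would appear as two files, a known
ingestion limitation. ReproZip does not record unlink events, so
deletions are supplied by the caller as post-hoc existence checks and
attributed to the path's last accessor.

The trace data model carries one ordinal per process start and per
first access, not open/close intervals. The concurrent-write check
therefore approximates a writer's write interval as [first write on the
path, last recorded ordinal of that process]; with per-event ordinals
from a real tracer this is conservative in the right direction (it
flags interleavings). A reader whose reads straddle a rewrite of the
same path cannot be detected with first-access ordinals only; such
pipelines violate the single-released-version assumption anyway.

## Version disambiguation

For a path with writers P₁…Pₙ ordered by first write, writer Pᵢ
produces version *i*. A pure reader attaches to the latest version
whose write precedes the reader's first read; a reader that is itself
writer *i* reads version *i−1*. Version 0 denotes pre-existing input
content and is the only file node allowed in-degree 0; every produced
version has in-degree exactly 1, and the result must be acyclic — both
are asserted, and a surviving cycle raises an assumption violation
rather than being silently broken.

## Capture wrappers

`generate_wrapper_scripts` writes one POSIX-shell shim per executable
basename. A shim resolves the genuine executable by scanning `PATH`
with the shim directory removed, increments a per-basename invocation
counter under an exclusive mkdir lock, execs the genuine tool with
unchanged arguments and environment, archives the (path, version)
outputs the DAG attributes to that (basename, instance) into a
write-once store (SHA-256 checksums in a per-instance manifest, copies
chmod'd read-only), and propagates the tool's exit status. Instance
index *k* maps to the *k*-th same-named process in trace order, which
is well defined for the sequential pipelines the model covers. The
archive step runs through a small stdlib-only Python helper placed next
to the shims; checksumming and write-once enforcement are not portable
shell. Tools invoked by absolute path bypass any PATH shim; that is a
capture gap of the mechanism itself, not of this implementation.

A file whose creator deletes it before exiting cannot be archived by a
post-exit wrapper. Under the model such a file is private to its
creator, so it is also invisible to the cross-condition comparison;
the labeling step skips outputs absent from both sides.

## Labeling protocol

Step-wise re-execution visits processes in topological order of the
versioned DAG with ties broken by trace start ordinal — i.e. the
original schedule, which guarantees a reader of version *i* runs before
writer *i+1* rewrites the path. Output comparison is content-only
(mtime and permissions never count); the comparator registry dispatches
on path globs, first match wins, default SHA-256. A cheap
equal-checksum short-circuit runs before any type-aware comparator,
which can only agree with it. On any differing output the process is
labeled non-reproducible and *all* its differing output versions are
replaced by byte-exact reference copies before any successor starts.
A process that fails to execute is `not_run`, as are all its
descendants; no label is guessed. Combined labels are the union over
the two condition orders, which makes them symmetric in which condition
is called "first".

The protocol performs exactly five pipeline executions regardless of
pipeline length. The optimization of re-running only
transient-dependent processes is deliberately not implemented.

## Comparators and segmentation metrics

Built-in comparators: `checksum` (SHA-256), `skip-bytes` (ignore
configured byte windows, e.g. a fixed-size binary header),
`text-no-timestamps` (line-wise equality after dropping lines matching
timestamp patterns), and `nifti-data` (voxel-array equality via
nibabel, header ignored) — the last standing in for format-aware diff
tools in imaging toolchains. Unknown comparator ids are a configuration
error, not a silent fallback.

Dice is `2|X∩Y|/(|X|+|Y|)` over voxel sets of a chosen label (any
nonzero label when unspecified). Both-empty Dice is undefined and
raises rather than returning a convention value. Per-region tables
score a label present in only one mask as 0. The identity
`D = 2J/(1+J)` against the Jaccard index is property-tested on random
masks. Region correspondence is by label value; resampling volumes to
a common template before comparison is out of scope.

## Tree comparison

The ordered-tree edit distance is the Zhang–Shasha dynamic program
(postorder keyroots, unit insert/delete/relabel costs), implemented
in-package and validated in the tests against an independent
brute-force recursive forest-edit-distance oracle for trees of ≤6
nodes, together with the metric axioms. Node labels default to the
executable basename; argv is available as a label policy but inflates
distances with path noise. Clustering is agglomerative with complete
linkage on the pairwise matrix, cut at a user threshold; the default
threshold 0 yields exact-structure classes, matching how subjects
group into provenance-graph "types". The tie-break between same-named
sibling processes permuted across conditions is start-ordinal order; no
content-based disambiguation is attempted.

## Synthetic fixtures: what they emulate

Fixture steps are real subprocesses (generated shell scripts execing a
stdlib-only step interpreter) so that PATH interception, exit-status
propagation and the write-once store are exercised exactly as on a real
pipeline. Step outputs are SHA-256 counter streams keyed by (step,
output path, input digests): fully deterministic functions of input
*content*, so any upstream difference propagates — the property that
makes propagation blocking necessary. Condition-sensitive steps
additionally overwrite the leading 16 bytes of each output with a
digest of (condition label, noise seed): byte-identical within a
condition, guaranteed different across conditions. This emulates the
*effect* of an OS/library update (a deterministic, condition-keyed
perturbation), not its mechanism; fixtures cannot show how large
real-world perturbations are, only whether the localization machinery
recovers a known injection site exactly.

Default study conditions used by the tests and the acceptance script:
the three-step worked-example pipeline (one sensitive step, one
transient file); random pipelines of 2–5 steps with marginal rates
p(sensitive) = 0.35, p(transient) = 0.3, p(multi-writer) = 0.3 and
1–2 KB files, 100 pipelines per recovery suite. File sizes are small
and step count modest so a full five-execution evaluation stays below a
second; the recovered quantity (exact label-set equality) does not
depend on file size. The fixture tracer does not emulate kernel-level
capture corner cases (mmap I/O, fd inheritance, threads), and fixture
deletions are always performed by a later step or by the creator of a
private temp file — the configurations the model admits.

## Known limitations

* Process-level resolution; no sub-process attribution.
* In-memory data flow (pipes, stdout parsing) is invisible.
* Symlinked path aliasing is not reconciled at ingest.
* Reproducibility verdicts hold only for the tested dataset and
  conditions; a green label is evidence, not proof, while a pink label
  is definitive for that dataset.
* Absolute-path invocations escape PATH-shim capture.
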