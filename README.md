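# provdiff

Localize the origin of numerical differences in data-analysis pipelines
by comparing file-level provenance across computational conditions.

Complex scientific pipelines — neuroimaging is the motivating case —
chain hundreds of OS processes through intermediate files. A change of
computational condition (an OS upgrade, a rebuilt library) can perturb
floating-point results in one process, and that perturbation then
propagates through every downstream step, so diffing final outputs says
nothing about *where* the instability was created. `provdiff` answers
the "where" question at process resolution, without instrumenting the
pipeline's code: it only needs a system-call trace (processes + file
accesses, e.g. from ReproZip) and the ability to re-run the pipeline in
both conditions. It is aimed at pipeline developers and maintainers who
need to know which tool in a long chain is numerically fragile.

## Method

1. **Provenance graph.** From the trace, build a directed bipartite
   graph: process nodes and file nodes, with file→process edges for
   reads and process→file edges for writes. System utilities
   (`/bin`, `/usr/bin`, …) are filtered out by executable-path pattern.
   Process trees (fork/clone edges) from different executions are
   compared with the Zhang–Shasha ordered-tree edit distance and
   clustered (complete linkage) into structural families, since
   data-dependent branching can make graphs differ across subjects.
2. **Transient files.** Files deleted during the run, or written by
   several processes P₁…Pₙ, are not observable afterwards. After
   verifying that no two processes write a file concurrently, each
   multi-writer path is split into versions — Pᵢ writes version *i*,
   readers attach to the latest version written before their first
   read — giving an acyclic DAG in which every written file version has
   in-degree exactly 1. PATH-shim wrapper scripts (same basename as the
   real tool, placed earlier on `PATH`) transparently intercept each
   process and archive the versions it wrote into a write-once store.
3. **Labeling.** With condition A's archive as reference, the pipeline
   is re-run *step by step* in condition B (topological order). Each
   process's outputs are compared to the reference — by SHA-256
   checksum, or by type-aware comparators that ignore headers or
   timestamps. On a mismatch the process is labeled **non-reproducible**
   and the reference files are copied over its outputs, so downstream
   processes are judged only on their own computation (propagation
   blocking); otherwise it is **reproducible**. The comparison runs in
   both condition orders; a process is non-reproducible if it differs in
   at least one order. The whole protocol costs exactly **5** pipeline
   executions: trace in A, wrapped capture in A, step-wise comparison in
   B, wrapped capture in B, step-wise comparison in A.

For segmentation outputs, the package also provides the Dice overlap
`Dice = 2|X∩Y| / (|X|+|Y|)` (1 = perfect overlap, 0 = disjoint),
per-region Dice tables, and voxel-wise counts of differing subjects.

Because evaluating a real pipeline needs containers and hours of
compute, the package ships a synthetic-pipeline module: declarative
pipelines whose steps run as real subprocesses (so the PATH-shim
mechanism is exercised genuinely), with controllable condition-dependent
noise, transient files and multi-writer files — and known ground truth.

## Worked example

Evaluate the built-in three-step brain-volume toy pipeline
(mask extraction → masking → statistics), in which only the
mask-extraction step is condition-sensitive:

```sh
$ cat eval.json
{"pipeline": "brain-volume", "conditions": ["centos6", "centos7"],
 "work_root": "eval-work"}
$ provdiff evaluate eval.json --out-prefix labeled
execution 1: trace recording [centos6]
execution 2: wrapped capture [centos6]
execution 3: step-wise comparison [centos7]
execution 4: wrapped capture [centos7]
execution 5: step-wise comparison [centos6]
non-reproducible processes: 1 ['bet2']
```

The five log lines are the five executions of the protocol. The verdict
says exactly one process — `bet2`, the noisy mask extraction — produced
different results between the two conditions. `labeled.json` records the
per-order labels and the differing files:

```
bet2      non_reproducible   ['brain.nii', 'brain_mask.nii']
fslmaths  reproducible       []
fslstats  reproducible       []
```

`fslmaths` and `fslstats` stay reproducible even though their inputs
derive from `bet2`: propagation blocking restored the reference files
before they ran. `labeled.dot` is the labeled graph (one pink node, two
green) for rendering with Graphviz.

The same operations are available as a library
(`provdiff.evaluate_pipeline`, `provdiff.disambiguate_versions`,
`provdiff.dice_coefficient`, …) and as further subcommands
(`trace-import`, `graph`, `tree`, `cluster`, `capture`, `report`,
`fixture`).

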