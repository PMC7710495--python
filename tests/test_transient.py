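"""Transient-file detection, concurrency check, versioning, wrappers."""

import json
import os
import random
import subprocess
from pathlib import Path

import pytest

from conftest import make_records
from provdiff.fixtures import (
    make_brain_volume_spec,
    random_spec,
    run_pipeline,
    synthesize_trace,
)
from provdiff.provenance import (
    DEFAULT_BLACKLIST,
    build_provenance_graph,
    filter_processes,
)
from provdiff.transient import (
    check_concurrent_writes,
    disambiguate_versions,
    find_transient_files,
    generate_wrapper_scripts,
)


def _graph(records, blacklist=()):
    return filter_processes(build_provenance_graph(records), blacklist)


class TestFindTransientFiles:
    def test_overwritten_output_listed_with_ordered_writers(self):
        records = make_records(
            [("p0", None, "/opt/s1"), ("p1", "p0", "/opt/s2")],
            [("p0", "/w/f", "write"), ("p1", "/w/f", "write")],
        )
        report = find_transient_files(_graph(records), records)
        assert report.multi_writer_files == {"/w/f": ["p0", "p1"]}
        assert report.deleted_files == set()

    def test_clean_pipeline_empty_report(self, chain_records):
        report = find_transient_files(_graph(chain_records), chain_records)
        assert report.is_empty()

    def test_private_self_deleted_temp_no_warning(self):
        records = make_records(
            [("p0", None, "/opt/s1")],
            [("p0", "/w/tmp", "write", True), ("p0", "/w/out", "write")],
        )
        report = find_transient_files(_graph(records), records)
        assert report.deleted_files == {"/w/tmp"}
        assert report.warnings == []

    def test_shared_self_deleted_file_warns(self):
        records = make_records(
            [("p0", None, "/opt/s1"), ("p1", "p0", "/opt/s2")],
            [("p0", "/w/tmp", "write", True), ("p1", "/w/tmp", "read")],
        )
        report = find_transient_files(_graph(records), records)
        assert len(report.warnings) == 1
        assert "must not be used" in report.warnings[0]

    def test_filtered_processes_do_not_resurface(self):
        records = make_records(
            [("p0", None, "/opt/s1"), ("p1", "p0", "/bin/rm")],
            [("p0", "/w/f", "write"), ("p1", "/w/f", "write", True)],
        )
        report = find_transient_files(_graph(records, ["/bin/*"]), records)
        assert report.multi_writer_files == {}
        assert report.deleted_files == set()


class TestConcurrentWrites:
    def test_sequential_writers_pass(self):
        records = make_records(
            [("p0", None, "/opt/s1"), ("p1", "p0", "/opt/s2")],
            [("p0", "/w/f", "write"), ("p1", "/w/f", "write")],
        )
        assert check_concurrent_writes(records, "/w/f") == []

    def test_single_writer_passes(self, chain_records):
        assert check_concurrent_writes(chain_records, "/work/brain.nii") == []

    def test_interleaved_writes_violate(self):
        # p0 writes f (ordinal 3) and is still active at ordinal 5 (writes g)
        # while p1 writes f at ordinal 4 -> intervals [3,5] and [4,4] overlap
        records = make_records(
            [("p0", None, "/opt/s1"), ("p1", "p0", "/opt/s2")],
            [
                ("p0", "/w/f", "write"),
                ("p1", "/w/f", "write"),
                ("p0", "/w/g", "write"),
            ],
        )
        assert check_concurrent_writes(records, "/w/f") == [("p0", "p1")]


class TestDisambiguateVersions:
    def test_three_writers_reader_gets_last_version(self):
        records = make_records(
            [
                ("p1", None, "/opt/s1"),
                ("p2", "p1", "/opt/s2"),
                ("p3", "p1", "/opt/s3"),
                ("p4", "p1", "/opt/s4"),
            ],
            [
                ("p1", "/w/F", "write"),
                ("p2", "/w/F", "write"),
                ("p3", "/w/F", "write"),
                ("p4", "/w/F", "read"),
            ],
        )
        graph = _graph(records)
        dag = disambiguate_versions(graph, find_transient_files(graph, records))
        assert dag.is_acyclic()
        assert dag.max_file_in_degree() == 1
        assert dag.version_counts() == {"/w/F": 3}
        assert ("/w/F", 3) in dag.inputs_of("p4")
        assert dag.writer_of("/w/F", 2) == "p2"

    def test_single_writer_graph_is_identity_shaped(self, chain_records):
        graph = _graph(chain_records, DEFAULT_BLACKLIST)
        dag = disambiguate_versions(
            graph, find_transient_files(graph, chain_records)
        )
        assert set(dag.process_ids()) == set(graph.process_ids())
        written = {(p, v) for p, v in dag.file_version_nodes() if v >= 1}
        assert all(v == 1 for _p, v in written)
        assert len(written) == len(graph.write_edges())

    def test_self_read_then_write_reads_previous_version(self):
        # p1 creates F; p2 reads F and rewrites it in place
        records = make_records(
            [("p1", None, "/opt/s1"), ("p2", "p1", "/opt/s2")],
            [("p1", "/w/F", "write"), ("p2", "/w/F", "read_write")],
        )
        graph = _graph(records)
        dag = disambiguate_versions(graph, find_transient_files(graph, records))
        assert dag.is_acyclic()
        assert ("/w/F", 1) in dag.inputs_of("p2")
        assert ("/w/F", 2) in dag.outputs_of("p2")

    def test_reader_before_any_write_gets_input_version(self):
        records = make_records(
            [("p1", None, "/opt/s1"), ("p2", "p1", "/opt/s2")],
            [("p1", "/w/F", "read"), ("p2", "/w/F", "write")],
        )
        graph = _graph(records)
        dag = disambiguate_versions(graph, find_transient_files(graph, records))
        assert ("/w/F", 0) in dag.inputs_of("p1")
        assert dag.graph.in_degree(("filev", "/w/F", 0)) == 0

    def test_property_acyclic_in_degree_one_over_random_specs(self):
        rng = random.Random(424242)
        for _ in range(30):
            seed = rng.randrange(2**31)
            spec, truth = random_spec(
                n_steps=rng.randint(2, 8), seed=seed,
                p_transient=0.4, p_multiwriter=0.5,
            )
            records = synthesize_trace(spec, "c", "/work")
            graph = _graph(records, DEFAULT_BLACKLIST)
            dag = disambiguate_versions(
                graph, find_transient_files(graph, records)
            )
            assert dag.is_acyclic(), seed
            assert dag.max_file_in_degree() == 1, seed
            counts = {
                Path(p).name: n for p, n in dag.version_counts().items()
            }
            assert counts == dict(truth.version_counts), seed


class TestWrapperScripts:
    def _dag(self, records, blacklist=DEFAULT_BLACKLIST):
        graph = _graph(records, blacklist)
        return disambiguate_versions(
            graph, find_transient_files(graph, records)
        )

    def test_wrapped_fixture_archives_all_written_files(self, tmp_path):
        spec, truth = make_brain_volume_spec(sensitive=False)
        work = tmp_path / "work"
        records = run_pipeline(spec, "c1", work)
        dag = self._dag(records)
        wrappers = generate_wrapper_scripts(
            dag, tmp_path / "shims", tmp_path / "store"
        )
        # rerun the pipeline through the shims in the same directory
        import shutil

        shutil.rmtree(work)
        run_pipeline(spec, "c1", work, wrapper_dir=wrappers.path_prefix())
        archived = {
            (m.parent.parent.name, entry["path"], entry["version"])
            for m in (tmp_path / "store").glob("*/*/manifest.json")
            for entry in json.loads(m.read_text())
        }
        expected = {
            (dag.process_attrs(pid)["basename"], path, version)
            for pid in dag.process_ids()
            for path, version in dag.outputs_of(pid)
        }
        # every written version, including the later-deleted brain.nii
        assert archived == expected
        assert any("brain.nii" in p for _b, p, _v in archived)

    def test_rerun_wrapped_pipeline_is_byte_identical(self, tmp_path):
        spec, _ = make_brain_volume_spec(sensitive=False)
        digests = []
        for run in ("r1", "r2"):
            work = tmp_path / run / "work"
            records = run_pipeline(spec, "c1", work)
            dag = self._dag(records)
            wrappers = generate_wrapper_scripts(
                dag, tmp_path / run / "shims", tmp_path / run / "store"
            )
            import shutil

            shutil.rmtree(work)
            run_pipeline(spec, "c1", work, wrapper_dir=wrappers.path_prefix())
            manifest = {}
            for m in sorted((tmp_path / run / "store").glob("*/*/manifest.json")):
                for entry in json.loads(m.read_text()):
                    rel = str(Path(entry["path"]).relative_to(work))
                    manifest[(rel, entry["version"])] = entry["sha256"]
            digests.append(manifest)
        assert digests[0] == digests[1] and digests[0]

    def test_same_basename_twice_gets_separate_instances(self, tmp_path):
        records = make_records(
            [
                ("p0", None, "/bin/sh"),
                ("p1", "p0", "/opt/flirt"),
                ("p2", "p0", "/opt/flirt"),
            ],
            [("p1", "/w/a", "write"), ("p2", "/w/b", "write")],
        )
        dag = self._dag(records)
        wrappers = generate_wrapper_scripts(
            dag, tmp_path / "shims", tmp_path / "store"
        )
        assert list(wrappers.scripts) == ["flirt"]
        manifest = json.loads(
            (tmp_path / "shims" / "_manifest.json").read_text()
        )
        assert set(manifest["outputs"]["flirt"]) == {"1", "2"}
        assert manifest["outputs"]["flirt"]["1"][0]["path"] == "/w/a"
        assert manifest["outputs"]["flirt"]["2"][0]["path"] == "/w/b"

    def test_unresolvable_executable_fails_nonzero(self, tmp_path):
        records = make_records(
            [("p0", None, "/opt/ghost_tool")], [("p0", "/w/x", "write")]
        )
        dag = self._dag(records, blacklist=())
        wrappers = generate_wrapper_scripts(
            dag, tmp_path / "shims", tmp_path / "store"
        )
        env = dict(os.environ)
        env["PATH"] = f"{wrappers.path_prefix()}:/usr/bin:/bin"
        proc = subprocess.run(
            ["/bin/sh", "-c", 'exec "$0"', "ghost_tool"],
            env=env, capture_output=True, text=True,
        )
        assert proc.returncode == 127
        assert "cannot resolve" in proc.stderr

    def test_store_is_write_once(self, tmp_path):
        spec, _ = make_brain_volume_spec(sensitive=False)
        work = tmp_path / "work"
        records = run_pipeline(spec, "c1", work)
        dag = self._dag(records)
        wrappers = generate_wrapper_scripts(
            dag, tmp_path / "shims", tmp_path / "store"
        )
        import shutil

        shutil.rmtree(work)
        run_pipeline(spec, "c1", work, wrapper_dir=wrappers.path_prefix())
        # replaying the same instances against the same store must fail:
        # reset the invocation counters so instance indices repeat
        shutil.rmtree(work)
        shutil.rmtree(tmp_path / "shims" / ".state")
        (tmp_path / "shims" / ".state").mkdir()
        with pytest.raises(Exception):
            run_pipeline(spec, "c1", work, wrapper_dir=wrappers.path_prefix())
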