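"""Chunk planning, taxon-aware annotation and the end-to-end sample run."""

import random

import pytest
from click.testing import CliRunner

import consannot.workflow as wf
from consannot.cli import main as cli_main
from consannot.hits import ThresholdSpec
from consannot.synth import generate_sample
from consannot.workflow import (
    RunConfig,
    TableHitSource,
    TsaSetup,
    default_chunk_count,
    load_lineage_table,
    plan_chunks,
    read_consensus_tsv,
    run_sample,
    tsa_annotate,
)

from conftest import make_hit


class TestPlanChunks:
    def test_lpt_hand_trace(self):
        lengths = {f"s{i}": L for i, L in enumerate([100, 90, 50, 40, 10])}
        plan = plan_chunks(lengths, 2)
        assert sorted(plan.residue_totals) == [140, 150]
        assert plan.policy == "length_balanced"

    def test_single_chunk(self):
        lengths = {"a": 10, "b": 20}
        plan = plan_chunks(lengths, 1)
        assert plan.residue_totals == [30]
        assert sorted(plan.chunks[0]) == ["a", "b"]

    def test_one_sequence_per_chunk(self):
        lengths = {f"s{i}": 50 + i for i in range(4)}
        plan = plan_chunks(lengths, 4)
        assert all(len(c) == 1 for c in plan.chunks)

    def test_partition_property(self):
        rng = random.Random(2)
        lengths = {f"s{i}": rng.randint(50, 900) for i in range(200)}
        plan = plan_chunks(lengths, 7)
        flat = [s for chunk in plan.chunks for s in chunk]
        assert sorted(flat) == sorted(lengths)

    def test_balance_bound(self):
        """Greedy longest-first balancing: chunk residue totals differ by at
        most one sequence length."""
        rng = random.Random(3)
        lengths = {f"s{i}": rng.randint(50, 900) for i in range(300)}
        plan = plan_chunks(lengths, 8)
        spread = max(plan.residue_totals) - min(plan.residue_totals)
        assert spread <= max(lengths.values())

    def test_round_robin_above_size_cutoff(self, monkeypatch):
        monkeypatch.setattr(wf, "LENGTH_BALANCED_MAX_SEQS", 3)
        lengths = {"a": 100, "b": 1, "c": 1, "d": 100}
        plan = plan_chunks(lengths, 2)
        assert plan.policy == "round_robin"
        assert plan.chunks == [["a", "c"], ["b", "d"]]

    def test_rejects_bad_chunk_count(self):
        with pytest.raises(ValueError):
            plan_chunks({"a": 10}, 0)

    def test_default_chunk_count_floor(self):
        assert default_chunk_count(1000, workers=4) == 16
        assert default_chunk_count(120, workers=4) == 2
        assert default_chunk_count(10, workers=8) == 1


class TestTsaAnnotate:
    def _source(self, name, hits):
        return TableHitSource.from_hits(name, hits)

    def test_sequence_annotated_at_leaf_not_searched_above(self):
        leaf = self._source("tshmm_562", [make_hit(qid="q1", ev=1e-9)])
        parent_hits = [make_hit(qid="q1", ev=1e-9), make_hit(qid="q2", ev=1e-9)]
        parent = self._source("tshmm_561", parent_hits)
        out = tsa_annotate(
            ["q1", "q2"], ["561", "562"],
            {"562": leaf, "561": parent}, [], ThresholdSpec(),
        )
        assert {h.query_id for h in out["tshmm_562"]} == {"q1"}
        assert {h.query_id for h in out["tshmm_561"]} == {"q2"}

    def test_no_taxonomy_searches_general_only(self):
        general = self._source("eggnog", [make_hit(qid="q1", ev=1e-9)])
        out = tsa_annotate(["q1"], None, {}, [general], ThresholdSpec())
        assert set(out) == {"eggnog"}

    def test_unannotated_sequence_reaches_general_once(self):
        log: list[str] = []
        leaf = self._source("tshmm_562", [])
        general = self._source("eggnog", [make_hit(qid="q1", ev=1e-9)])
        out = tsa_annotate(
            ["q1"], ["561", "562"], {"562": leaf}, [general],
            ThresholdSpec(), log,
        )
        assert len(out["eggnog"]) == 1

    def test_unknown_lineage_falls_back_with_warning(self):
        log: list[str] = []
        general = self._source("eggnog", [make_hit(qid="q1", ev=1e-9)])
        out = tsa_annotate(
            ["q1"], ["9999"], {"562": self._source("tshmm_562", [])},
            [general], ThresholdSpec(), log,
        )
        assert set(out) == {"eggnog"}
        assert any("falling back" in line for line in log)

    def test_invalid_hits_do_not_stop_the_walk(self):
        # leaf hit fails the threshold, so the parent level is searched
        leaf = self._source("tshmm_562", [make_hit(qid="q1", ev=1e-2)])
        parent = self._source("tshmm_561", [make_hit(qid="q1", ev=1e-9)])
        out = tsa_annotate(
            ["q1"], ["561", "562"], {"562": leaf, "561": parent},
            [], ThresholdSpec(),
        )
        assert set(out) == {"tshmm_561"}


@pytest.fixture
def sample_on_disk(tmp_path):
    sample = generate_sample(n_queries=8, domains_per_query=2, n_sources=2,
                             seed=11)
    fasta = tmp_path / "sample.faa"
    sample.write_fasta(fasta)
    hit_paths = sample.write_hits(tmp_path / "hits")
    meta_paths = sample.write_metadata_files(tmp_path / "meta")
    return sample, fasta, hit_paths, meta_paths, tmp_path


class TestRunSample:
    def test_empty_sample_writes_header_only_tsvs(self, tmp_path):
        fasta = tmp_path / "empty.faa"
        fasta.write_text("")
        out = tmp_path / "out"
        run_sample(fasta, {}, {}, out_dir=out)
        for name in ("output_annotation.tsv", "integrated_annotation.tsv",
                     "consensus_annotation.tsv"):
            lines = (out / name).read_text().splitlines()
            assert len(lines) == 1 and "\t" in lines[0]
        assert (out / "annotation.log").exists()

    def test_missing_input_fails_before_output(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            run_sample(tmp_path / "nope.faa", {}, {}, out_dir=tmp_path / "o")
        assert not (tmp_path / "o").exists()

    def test_single_hit_consistent_across_files(self, tmp_path):
        fasta = tmp_path / "one.faa"
        fasta.write_text(">q1\n" + "M" * 100 + "\n")
        hits = tmp_path / "pfam.tsv"
        from consannot.hits import write_hits_tsv

        with open(hits, "w") as fh:
            write_hits_tsv([make_hit(pid="PF1", ev=1e-9)], fh)
        meta = tmp_path / "pfam.meta.tsv"
        meta.write_text("PF1\tpfam:PF00010\tdescription:glucose kinase\n")
        out = tmp_path / "out"
        run_sample(fasta, {"pfam": hits}, {"pfam": meta}, out_dir=out)
        raw = (out / "output_annotation.tsv").read_text().splitlines()
        integ = (out / "integrated_annotation.tsv").read_text().splitlines()
        cons = (out / "consensus_annotation.tsv").read_text().splitlines()
        assert len(raw) == len(integ) == len(cons) == 2
        assert raw[1].split("\t")[:3] == ["q1", "pfam", "PF1"]
        assert "PF00010" in integ[1] and "PF00010" in cons[1]
        assert "glucose kinase" in cons[1]

    def test_two_sources_sharing_id_merge_in_consensus(self, sample_on_disk):
        sample, fasta, hit_paths, meta_paths, tmp = sample_on_disk
        out = tmp / "out"
        run_sample(fasta, hit_paths, meta_paths, out_dir=out)
        with open(out / "consensus_annotation.tsv") as fh:
            rows = read_consensus_tsv(fh)
        assert len(rows) == len(sample.lengths)
        # p_share = 1: planted cross-source hits agree, so every consensus
        # row merges both collections
        for row in rows:
            assert row["sources"] == ["kofam", "pfam"]
            assert row["identifiers"] == sample.reference[row["query_id"]]

    def test_chunked_inputs_equal_unchunked(self, sample_on_disk):
        sample, fasta, hit_paths, meta_paths, tmp = sample_on_disk
        run_sample(fasta, hit_paths, meta_paths, out_dir=tmp / "whole")
        chunked = sample.write_chunked_hits(tmp / "chunks", 3)
        run_sample(fasta, chunked, meta_paths, out_dir=tmp / "split")
        for name in ("output_annotation.tsv", "consensus_annotation.tsv"):
            assert (tmp / "whole" / name).read_bytes() == (
                tmp / "split" / name
            ).read_bytes()

    def test_parallel_workers_give_identical_output(self, sample_on_disk):
        sample, fasta, hit_paths, meta_paths, tmp = sample_on_disk
        run_sample(fasta, hit_paths, meta_paths, out_dir=tmp / "serial")
        config = RunConfig(workers=2)
        run_sample(fasta, hit_paths, meta_paths, config=config,
                   out_dir=tmp / "parallel")
        assert (tmp / "serial" / "consensus_annotation.tsv").read_bytes() == (
            tmp / "parallel" / "consensus_annotation.tsv"
        ).read_bytes()


class TestConfig:
    def test_from_ini_and_weights(self, tmp_path):
        path = tmp_path / "run.ini"
        path.write_text(
            "[run]\nalgorithm = heuristic\nevalue = dynamic\nworkers = 3\n"
            "[weights]\npfam = 0.95\ndefault = 0.6\n"
        )
        config = RunConfig.from_ini(path)
        assert config.algorithm == "heuristic"
        assert config.threshold.mode == "dynamic"
        assert config.workers == 3
        assert config.weights["pfam"] == 0.95
        assert config.weights["never_heard_of_it"] == 0.6

    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig(algorithm="magic")
        with pytest.raises(ValueError):
            RunConfig(max_overlap=1.2)


class TestCli:
    def test_run_produces_three_tsvs(self, sample_on_disk):
        sample, fasta, hit_paths, meta_paths, tmp = sample_on_disk
        out = tmp / "cli_out"
        args = ["-t", str(fasta), "-o", str(out), "--algorithm", "dfs"]
        for s, p in hit_paths.items():
            args += ["--hits", f"{s}={p}"]
        for s, p in meta_paths.items():
            args += ["--metadata", f"{s}={p}"]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        for name in ("output_annotation.tsv", "integrated_annotation.tsv",
                     "consensus_annotation.tsv"):
            assert (out / name).exists()

    def test_unknown_flag_fails_with_usage(self):
        result = CliRunner().invoke(cli_main, ["--frobnicate"])
        assert result.exit_code != 0
        assert "Usage" in result.output or "no such option" in result.output.lower()

    def test_taxon_option_exercises_tsa_path(self, sample_on_disk, tmp_path):
        sample, fasta, hit_paths, meta_paths, tmp = sample_on_disk
        # one taxon-specific hits file covering a planted hit
        tshmm_dir = tmp / "tshmm"
        tshmm_dir.mkdir()
        from consannot.hits import write_hits_tsv

        some_hits = sample.hits_by_source["pfam"][:2]
        with open(tshmm_dir / "562.tsv", "w") as fh:
            write_hits_tsv(some_hits, fh)
        lineage = tmp / "lineage.tsv"
        lineage.write_text("562\t2 1224 561 562\n")
        config = tmp / "run.ini"
        config.write_text(
            f"[tsa]\nlineage_table = {lineage}\ntshmm_dir = {tshmm_dir}\n"
            "general_sources = eggnog\n"
        )
        out = tmp / "tsa_out"
        args = ["-t", str(fasta), "-o", str(out), "-od", "562",
                "--config", str(config)]
        for s, p in hit_paths.items():
            args += ["--hits", f"{s}={p}"]
        for s, p in meta_paths.items():
            args += ["--metadata", f"{s}={p}"]
        result = CliRunner().invoke(cli_main, args)
        assert result.exit_code == 0, result.output
        log = (out / "annotation.log").read_text()
        assert "tsa: taxon 562" in log


class TestLineageTable:
    def test_load(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text("562\t2 1224 1236 91347 543 561 562\n561\t2 1224 561\n")
        table = load_lineage_table(path)
        assert table["562"][-1] == "562"
        assert table["562"][0] == "2"
        assert len(table) == 2


class TestSearchAdapter:
    def test_hmmsearch_round_trip(self, tmp_path):
        """Build a toy profile, search a matching target, and parse the
        resulting domtblout through the ingestion path."""
        from consannot.hits import parse_domtblout
        from consannot.search import search_sample

        import subprocess

        sto = tmp_path / "toy.sto"
        sto.write_text(
            "# STOCKHOLM 1.0\n"
            "seq1 MKVLITGAGSGIGLELAKQLA\n"
            "seq2 MKVLVTGAGSGIGLELAKRLA\n"
            "seq3 MKVLITGAGSGLGLELAKQLA\n"
            "//\n"
        )
        hmm = tmp_path / "toy.hmm"
        subprocess.run(["hmmbuild", str(hmm), str(sto)], check=True,
                       capture_output=True)
        fasta = tmp_path / "target.faa"
        fasta.write_text(">prot1\n" + "M" * 5 + "MKVLITGAGSGIGLELAKQLA" + "M" * 24 + "\n")
        plan = plan_chunks({"prot1": 50}, 1)
        out = search_sample(fasta, {"toy": hmm}, plan, tmp_path / "work")
        (dom_path, chunk_size) = out["toy"][0]
        assert chunk_size == 1
        with open(dom_path) as fh:
            hits = parse_domtblout(fh, "toy", {"prot1": 50})
        assert len(hits) == 1
        assert hits[0].profile_id == "toy"
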