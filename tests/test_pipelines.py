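"""The four module workflows against fixture ground truth."""

import dataclasses

import pandas as pd
import pytest

from seqscrub.fastq_io import parse_fastq_stream
from seqscrub.fixtures import FixtureSpec, generate, generate_reads
from seqscrub.pipelines import default_config, find_dge_tag, is_polya, run_pipeline
from seqscrub.preprocess import AdapterSpec, FilterSpec

from .conftest import make_read

ADAPTER = AdapterSpec("AGATCGGAAGAGC")


def conservation_holds(result):
    return result.raw.n_reads == result.clean.n_reads + sum(
        result.clean.filter_tally.values()
    )


class TestDgeTag:
    def test_extracts_seventeen_bases_after_anchor(self):
        tag17 = "ACGTACGTACGTACGTA"
        read = make_read("TTCATG" + tag17 + "GGG")
        out = find_dge_tag(read, "CATG", 17)
        assert out.bases == tag17 and len(out) == 17

    def test_qualities_follow_the_tag(self):
        quals = list(range(26))
        read = make_read("TTCATG" + "A" * 20, quals)
        out = find_dge_tag(read, "CATG", 17)
        assert list(out.quals) == quals[6:23]

    def test_absent_anchor_or_short_tail(self):
        assert find_dge_tag(make_read("ACGT" * 10), "CATG", 17) is None
        assert find_dge_tag(make_read("CATG" + "A" * 10), "CATG", 17) is None

    def test_first_occurrence_and_keep_anchor(self):
        read = make_read("CATG" + "C" * 17 + "CATG" + "G" * 17)
        assert find_dge_tag(read, "CATG", 17).bases == "C" * 17
        kept = find_dge_tag(read, "CATG", 17, keep_anchor=True)
        assert kept.bases == "CATG" + "C" * 17


class TestPolyA:
    @pytest.mark.parametrize(
        "bases,expected",
        [("A" * 10, True), ("AAAAAACGTC" , False), ("AAAAAAAGTC", True), ("", False)],
    )
    def test_fraction_rule_at_default_threshold(self, bases, expected):
        assert is_polya(make_read(bases), 0.7) is expected


class TestGeneralModule:
    def test_identity_pipeline_keeps_everything(self, tmp_path):
        spec = FixtureSpec(n_reads=300, read_len=60, seed=10)
        generate(spec, tmp_path / "fx")
        cfg = default_config("general")
        cfg.filters = FilterSpec(min_length=0, max_n_fraction=1.0,
                                 max_low_qual_fraction=1.0)
        res = run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        assert res.clean.n_reads == 300
        assert sum(res.clean.filter_tally.values()) == 0

    def test_adapter_trimmed_lengths_equal_planted_offsets(self, tmp_path):
        spec = FixtureSpec(
            n_reads=400, read_len=80, adapter=ADAPTER, adapter_rate=0.25,
            adapter_offset_range=(25, 70), seed=11,
        )
        generate(spec, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "ground_truth.tsv", sep="\t",
                            index_col=0)
        cfg = default_config("general", adapter=ADAPTER)
        res = run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        out_reads = {r.read_id: r for r in
                     parse_fastq_stream(tmp_path / "out" / "clean.fq")}
        planted = truth[truth.adapter_offset >= 0]
        assert len(planted) > 50
        for read_id, row in planted.set_index("read_id").iterrows():
            assert len(out_reads[read_id]) == row.adapter_offset
        assert conservation_holds(res)

    def test_duplicates_tallied_exactly(self, tmp_path):
        spec = FixtureSpec(n_reads=500, read_len=60, dup_rate=0.15, seed=12)
        generate(spec, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "ground_truth.tsv", sep="\t",
                            index_col=0)
        n_dups = int((truth.duplicate_of >= 0).sum())
        cfg = default_config("general")
        cfg.filters = dataclasses.replace(cfg.filters, dedup=True)
        res = run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        assert res.clean.filter_tally["duplicate"] == n_dups
        assert res.clean.n_reads == 500 - n_dups
        assert conservation_holds(res)

    def test_batch_exclusion(self, tmp_path):
        from seqscrub.fastq_io import BatchCoordinate

        spec = FixtureSpec(n_reads=100, read_len=60, tiles=("1101", "2104"),
                           seed=13)
        generate(spec, tmp_path / "fx")
        cfg = default_config("general")
        cfg.filters = dataclasses.replace(
            cfg.filters,
            excluded_batches=frozenset({BatchCoordinate("tile", "2104")}),
        )
        res = run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        assert res.clean.filter_tally["excluded_batch"] == 50
        for read in parse_fastq_stream(tmp_path / "out" / "clean.fq"):
            assert read.read_id.split(":")[4] == "1101"

    def test_pair_coupling(self, tmp_path):
        spec = FixtureSpec(n_reads=200, read_len=60, paired=True, n_rate=0.02,
                           seed=14)
        generate(spec, tmp_path / "fx")
        cfg = default_config("general")
        res = run_pipeline(cfg, tmp_path / "fx" / "reads_1.fq",
                           tmp_path / "fx" / "reads_2.fq", tmp_path / "out")
        out1 = list(parse_fastq_stream(tmp_path / "out" / "clean_1.fq"))
        out2 = list(parse_fastq_stream(tmp_path / "out" / "clean_2.fq"))
        assert len(out1) == len(out2)
        assert [r.stripped_id for r in out1] == [r.stripped_id for r in out2]
        assert conservation_holds(res)

    def test_determinism_and_order_preservation(self, tmp_path):
        spec = FixtureSpec(n_reads=200, read_len=60, adapter=ADAPTER,
                           adapter_rate=0.2, adapter_offset_range=(25, 55),
                           seed=15)
        generate(spec, tmp_path / "fx")
        cfg = default_config("general", adapter=ADAPTER)
        run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "o1")
        run_pipeline(cfg, tmp_path / "fx" / "reads.fq", None, tmp_path / "o2")
        assert (tmp_path / "o1" / "clean.fq").read_bytes() == (
            tmp_path / "o2" / "clean.fq"
        ).read_bytes()
        in_ids = [r.read_id for r in
                  parse_fastq_stream(tmp_path / "fx" / "reads.fq")]
        out_ids = [r.read_id for r in
                   parse_fastq_stream(tmp_path / "o1" / "clean.fq")]
        positions = {rid: i for i, rid in enumerate(in_ids)}
        assert out_ids == sorted(out_ids, key=positions.__getitem__)


class TestDgeModule:
    def test_all_outputs_are_tag_length_and_n_free(self, tmp_path):
        spec = FixtureSpec(n_reads=500, read_len=49, module_structure="dge",
                           seed=20)
        generate(spec, tmp_path / "fx")
        res = run_pipeline(default_config("dge"), tmp_path / "fx" / "reads.fq",
                           None, tmp_path / "out")
        out = list(parse_fastq_stream(tmp_path / "out" / "clean.fq"))
        assert len(out) > 400
        assert all(len(r) == 17 for r in out)
        assert all("N" not in r.bases for r in out)
        assert conservation_holds(res)

    def test_recovered_tags_match_planted(self, tmp_path):
        spec = FixtureSpec(n_reads=200, read_len=49, module_structure="dge",
                           seed=21)
        generate(spec, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "ground_truth.tsv", sep="\t",
                            index_col=0).set_index("read_id")
        run_pipeline(default_config("dge"), tmp_path / "fx" / "reads.fq",
                     None, tmp_path / "out")
        for read in parse_fastq_stream(tmp_path / "out" / "clean.fq"):
            assert read.bases == truth.loc[read.read_id, "tag"]

    def test_tag_with_n_dropped_as_ambiguous(self, tmp_path, fastq_file):
        reads = [
            make_read("TT" + "CATG" + "ACGTACGTACGTACGTA" + "GG", read_id="ok"),
            make_read("TT" + "CATG" + "ACGTACGTNCGTACGTA" + "GG", read_id="hasN"),
            make_read("TTTT" + "ACGTACGTACGTACGTA" + "GG", read_id="noanchor"),
        ]
        path = fastq_file(reads)
        res = run_pipeline(default_config("dge"), path, None, tmp_path / "out")
        assert res.clean.filter_tally["ambiguous_bases"] == 1
        assert res.clean.filter_tally["no_anchor"] == 1
        out = list(parse_fastq_stream(tmp_path / "out" / "clean.fq"))
        assert [r.read_id for r in out] == ["ok"]


class TestSrnaModule:
    def test_insert_lengths_recovered(self, tmp_path):
        spec = FixtureSpec(
            n_reads=300, read_len=49, module_structure="srna", adapter=ADAPTER,
            srna_insert_range=(22, 22), seed=30,
        )
        generate(spec, tmp_path / "fx")
        res = run_pipeline(default_config("srna", adapter=ADAPTER),
                           tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        out = list(parse_fastq_stream(tmp_path / "out" / "clean.fq"))
        assert len(out) > 250
        assert all(len(r) == 22 for r in out)
        assert conservation_holds(res)

    def test_polya_contaminants_tallied_and_absent(self, tmp_path):
        spec = FixtureSpec(
            n_reads=300, read_len=49, module_structure="srna", adapter=ADAPTER,
            srna_contaminant_rate=0.2, seed=31,
        )
        generate(spec, tmp_path / "fx")
        truth = pd.read_csv(tmp_path / "fx" / "ground_truth.tsv", sep="\t",
                            index_col=0)
        n_contaminants = int(truth.polya.sum())
        res = run_pipeline(default_config("srna", adapter=ADAPTER),
                           tmp_path / "fx" / "reads.fq", None, tmp_path / "out")
        assert res.clean.filter_tally["polya"] == n_contaminants
        contaminated = set(truth[truth.polya].read_id)
        for read in parse_fastq_stream(tmp_path / "out" / "clean.fq"):
            assert read.read_id not in contaminated

    def test_length_window_upper_bound(self, tmp_path, fastq_file):
        # a 35-base insert survives adapter trimming but exceeds max_length
        reads = [make_read("ACGTACGTGC" * 3 + "ACGTG" +
                           ADAPTER.sequence[:14], read_id="long")]
        path = fastq_file(reads)
        res = run_pipeline(default_config("srna", adapter=ADAPTER), path,
                           None, tmp_path / "out")
        assert res.clean.n_reads == 0
        assert res.clean.filter_tally["short_length"] == 1


class TestMetaModule:
    def test_quality_end_trim_postcondition(self, tmp_path, fastq_file):
        reads = [
            make_read("ACGT" * 10, [30] * 25 + [10] * 15, read_id=f"r{i}")
            for i in range(20)
        ]
        path = fastq_file(reads)
        cfg = default_config("meta")
        cfg.trim = dataclasses.replace(cfg.trim, qual_threshold=20)
        res = run_pipeline(cfg, path, None, tmp_path / "out")
        out = list(parse_fastq_stream(tmp_path / "out" / "clean.fq"))
        assert out and all(r.quals[-1] >= 20 for r in out)
        assert conservation_holds(res)

    def test_high_n_read_dropped(self, tmp_path, fastq_file):
        noisy = make_read("ACGTN" * 5 + "ACGT", read_id="n20")  # ~20% N
        clean = make_read("ACGT" * 6, read_id="ok")
        res = run_pipeline(default_config("meta"),
                           fastq_file([noisy, clean]), None, tmp_path / "out")
        assert res.clean.filter_tally["ambiguous_bases"] == 1
        assert res.clean.n_reads == 1

    def test_mean_quality_filter_disabled_by_default_but_overridable(
        self, tmp_path, fastq_file
    ):
        low_mean = make_read("ACGT" * 6, [10] * 24, read_id="lo")
        path = fastq_file([low_mean])
        res = run_pipeline(default_config("meta"), path, None, tmp_path / "o1")
        assert res.clean.n_reads == 1
        cfg = default_config("meta")
        cfg.filters = dataclasses.replace(cfg.filters, min_mean_quality=20)
        res2 = run_pipeline(cfg, path, None, tmp_path / "o2")
        assert res2.clean.filter_tally["low_mean_quality"] == 1

    def test_dedup_override_honored(self, tmp_path, fastq_file):
        reads = [make_read("ACGT" * 6, read_id=f"r{i}") for i in range(4)]
        path = fastq_file(reads)
        cfg = default_config("meta")
        cfg.filters = dataclasses.replace(cfg.filters, dedup=True)
        res = run_pipeline(cfg, path, None, tmp_path / "out")
        assert res.clean.n_reads == 1
        assert res.clean.filter_tally["duplicate"] == 3


class TestFilterOrderDeterminism:
    def test_permuting_input_permutes_output_and_keeps_tally(self, tmp_path):
        spec = FixtureSpec(n_reads=150, read_len=60, adapter=ADAPTER,
                           adapter_rate=0.3, adapter_offset_range=(10, 55),
                           n_rate=0.01, seed=40)
        pairs, _ = generate_reads(spec)
        from seqscrub.fastq_io import write_fastq

        fwd = tmp_path / "fwd.fq"
        rev = tmp_path / "rev.fq"
        write_fastq((p.mate1 for p in pairs), fwd)
        write_fastq((p.mate1 for p in reversed(pairs)), rev)
        cfg = default_config("general", adapter=ADAPTER)
        res_f = run_pipeline(cfg, fwd, None, tmp_path / "of")
        res_r = run_pipeline(cfg, rev, None, tmp_path / "orv")
        assert res_f.clean.filter_tally == res_r.clean.filter_tally
        ids_f = [r.read_id for r in parse_fastq_stream(tmp_path / "of" / "clean.fq")]
        ids_r = [r.read_id for r in parse_fastq_stream(tmp_path / "orv" / "clean.fq")]
        assert ids_f == list(reversed(ids_r))
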