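"""seqio: parsing, round trips, demultiplexing and candidate filtering."""

from __future__ import annotations

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deamscope import seqio
from deamscope.seqio import (
    ConfigError,
    DomainHit,
    FormatError,
    PairScoreRow,
    ReadRecord,
    SequenceRecord,
    demultiplex_reads,
    filter_candidates,
    parse_hmmer_tblout,
    read_fasta,
    read_fastq,
    read_pair_scores,
    write_fasta,
    write_fastq,
)

from conftest import random_dna


class TestFasta:
    def test_trailing_stop_stripped_to_flag(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">A some desc\nMKV*\n")
        (rec,) = read_fasta(p)
        assert rec.id == "A"
        assert rec.sequence == "MKV"
        assert rec.terminal_stop_flag
        assert rec.description == "some desc"

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">A\nMK\n>A\nMQ\n")
        with pytest.raises(FormatError, match="A"):
            read_fasta(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_round_trip_identity(self, tmp_path, rng):
        recs = [
            SequenceRecord(id=f"s{i}", sequence=random_dna(rng, 30),
                           terminal_stop_flag=bool(i % 2))
            for i in range(5)
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence, r.terminal_stop_flag) for r in back] == \
               [(r.id, r.sequence, r.terminal_stop_flag) for r in recs]

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">A\nMKV\n")
        assert read_fasta(p)[0].sequence == "MKV"


class TestFastq:
    def test_well_formed_record(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        (rec,) = list(read_fastq(p))
        assert rec == ReadRecord(id="r1", sequence="ACGT", quality="IIII")

    def test_truncated_record_raises(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGT\n+\n")
        with pytest.raises(FormatError):
            list(read_fastq(p))

    def test_simulated_reads_round_trip(self, tmp_path):
        """1,000 simulated reads parse back with identical sequences."""
        from deamscope.editquant import TargetDefinition
        from deamscope.synthdata import EditorSimConfig, simulate_reads

        amplicon = ("GATTACAGATTACAGATTACAGATTA" "ACCTCACGTGTATAGCAGCG"
                    "TGG" "CAGATTACAGATTACAGATTACA")
        target = TargetDefinition(target_id="t", amplicon_seq=amplicon,
                                  protospacer_start=26)
        reads, _ = simulate_reads(
            target, EditorSimConfig(base_rate=0.3, indel_rate=0.05,
                                    depth=1000, seed=7))
        p = tmp_path / "sim.fastq"
        write_fastq(reads, p)
        back = list(read_fastq(p))
        assert len(back) == 1000
        assert [r.sequence for r in back] == [r.sequence for r in reads]

    def test_length_mismatch_names_record(self):
        with pytest.raises(FormatError, match="bad"):
            ReadRecord(id="bad", sequence="ACGT", quality="III")


class TestDemultiplex:
    def _reads(self, seqs):
        return [ReadRecord(id=f"r{i}", sequence=s, quality="I" * len(s))
                for i, s in enumerate(seqs)]

    def test_exact_match_trims_barcode(self):
        assigned, unassigned = demultiplex_reads(
            self._reads(["ACGTTTTT"]), {"S1": "ACGT"}, max_mismatch=0)
        assert not unassigned
        (read,) = assigned["S1"]
        assert read.sequence == "TTTT"
        assert read.barcode == "ACGT"

    def test_equal_distance_tie_goes_unassigned(self):
        # AAGT is 1 mismatch from both AAAT and ACGT? AAGT vs AAAT -> 1; vs ACGT -> 1
        assigned, unassigned = demultiplex_reads(
            self._reads(["AAGTCCCC"]), {"S1": "AAAT", "S2": "ACGT"},
            max_mismatch=1)
        assert len(unassigned) == 1
        assert not assigned["S1"] and not assigned["S2"]

    def test_duplicate_barcodes_config_error(self):
        with pytest.raises(ConfigError):
            demultiplex_reads(self._reads(["ACGT"]), {"S1": "ACGT", "S2": "ACGT"})

    def test_planted_three_sample_assignment_is_perfect(self, rng):
        """With error-free reads and mm=1 every read returns to its sample."""
        barcodes = {"S1": "ACGTACGT", "S2": "TTGGCCAA", "S3": "GATCGATC"}
        reads, labels = [], []
        for i in range(300):
            sample = ["S1", "S2", "S3"][i % 3]
            insert = random_dna(rng, 40)
            reads.append(ReadRecord(id=f"r{i}", sequence=barcodes[sample] + insert,
                                    quality="I" * 48))
            labels.append(sample)
        assigned, unassigned = demultiplex_reads(reads, barcodes, max_mismatch=1)
        assert not unassigned
        for sample in barcodes:
            want = {f"r{i}" for i, lab in enumerate(labels) if lab == sample}
            assert {r.id for r in assigned[sample]} == want

    def test_read_conservation(self, rng):
        reads = self._reads([random_dna(rng, 20) for _ in range(50)])
        assigned, unassigned = demultiplex_reads(
            reads, {"S1": "ACGT", "S2": "TTTT"}, max_mismatch=0)
        total = sum(len(v) for v in assigned.values()) + len(unassigned)
        assert total == len(reads)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=8, max_size=30),
                      min_size=1, max_size=20),
        mm=st.integers(0, 2),
    )
    def test_conservation_and_uniqueness_hold_generally(self, seqs, mm):
        reads = self._reads(seqs)
        assigned, unassigned = demultiplex_reads(
            reads, {"S1": "ACGTACGT", "S2": "TTTTAAAA", "S3": "GGGGCCCC"},
            max_mismatch=mm)
        ids = [r.id for group in assigned.values() for r in group]
        ids += [r.id for r in unassigned]
        assert sorted(ids) == sorted(r.id for r in reads)


class TestTblout:
    def test_parses_hits_and_skips_comments(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(
            "# comment line\n"
            "seq1 - PF08210 - 1e-05 52.3 0.1 other fields\n"
            "seq2 - PF05240 - 0.5 10.0 0.2\n"
            "# trailing comment\n"
        )
        hits = parse_hmmer_tblout(p)
        assert len(hits) == 2
        assert hits[0] == DomainHit(seq_id="seq1", profile_id="PF08210",
                                    full_seq_evalue=1e-05, score=52.3)

    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text("# nothing\n# here\n")
        assert parse_hmmer_tblout(p) == []

    def test_non_numeric_evalue_reports_line(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text("seq1 - PF08210 - notanumber 52.3\n")
        with pytest.raises(FormatError, match=":1"):
            parse_hmmer_tblout(p)


class TestFilterCandidates:
    HITS = [
        DomainHit("ok", "PF08210", 1e-4),
        DomainHit("ok", "PF05240", 1e-3),
        DomainHit("nomet", "PF08210", 1e-4),
        DomainHit("border", "PF08210", 0.01),
    ]

    def _rec(self, rid, seq, flag=True):
        return SequenceRecord(id=rid, sequence=seq, terminal_stop_flag=flag)

    def test_good_record_kept_require_both(self):
        kept, rejected = filter_candidates(
            [self._rec("ok", "MKVAA")], self.HITS, domain_mode="require_both")
        assert [r.id for r in kept] == ["ok"]
        assert rejected == {}

    def test_no_start_methionine_rejected(self):
        kept, rejected = filter_candidates(
            [self._rec("nomet", "KVAAA")], self.HITS)
        assert not kept
        assert rejected == {"nomet": "no_start_met"}

    def test_evalue_exactly_at_cutoff_rejected(self):
        """The threshold is strict: e-value == 0.01 does not pass."""
        kept, rejected = filter_candidates(
            [self._rec("border", "MKVAA")], self.HITS)
        assert not kept
        assert rejected == {"border": "evalue_above_cutoff"}

    def test_record_without_hit_rejected_not_raised(self):
        kept, rejected = filter_candidates(
            [self._rec("ok", "MKVAA"), self._rec("orphan", "MAAAA")], self.HITS)
        assert [r.id for r in kept] == ["ok"]
        assert rejected == {"orphan": "no_hit"}

    def test_missing_terminal_stop_rejected_when_flags_present(self):
        kept, rejected = filter_candidates(
            [self._rec("ok", "MKVAA", flag=True),
             self._rec("nostop", "MKVAA", flag=False)],
            self.HITS + [DomainHit("nostop", "PF08210", 1e-4)])
        assert rejected == {"nostop": "no_terminal_stop"}

    def test_pass_through_when_no_record_has_flag(self):
        with pytest.warns(UserWarning):
            kept, rejected = filter_candidates(
                [self._rec("ok", "MKVAA", flag=False)], self.HITS)
        assert [r.id for r in kept] == ["ok"]

    def test_partition_invariant(self):
        recs = [self._rec("ok", "MKVAA"), self._rec("nomet", "KVA"),
                self._rec("orphan", "MQQQ")]
        kept, rejected = filter_candidates(recs, self.HITS)
        assert {r.id for r in kept} | set(rejected) == {r.id for r in recs}
        assert not ({r.id for r in kept} & set(rejected))


class TestPairScores:
    def test_row_parses(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text("id_a\tid_b\ttm_norm_a\ttm_norm_b\nA\tB\t0.82\t0.79\n")
        (row,) = read_pair_scores(p)
        assert row == PairScoreRow("A", "B", 0.82, 0.79)

    def test_self_pair_rejected(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text("id_a\tid_b\ttm_norm_a\ttm_norm_b\nA\tA\t1.0\t1.0\n")
        with pytest.raises(FormatError, match=":2"):
            read_pair_scores(p)

    def test_score_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text("id_a\tid_b\ttm_norm_a\ttm_norm_b\nA\tB\t1.2\t0.5\n")
        with pytest.raises(FormatError, match=":2"):
            read_pair_scores(p)
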