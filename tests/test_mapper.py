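"""End-to-end pipeline: mapping, SAM output, stage statistics."""

import numpy as np
import pysam
import pytest

import fasthash as fh
from fasthash.io import write_fastq

from conftest import random_dna


def mapping_keys(mappings):
    return {(m.ref_name, m.pos, m.strand, m.distance) for m in mappings}


class TestMapRead:
    def test_exact_substring_maps_at_origin(self, sim_bundle):
        _, genome, index, _, _ = sim_bundle
        p = 3210
        read = fh.ReadRecord("r", genome.fetch(p, p + 84))
        mappings = fh.map_read(read, index, genome, fh.MapperParams(e=0))
        assert ("chr1", p, "+", 0) in mapping_keys(mappings)

    def test_reverse_strand_read_found(self, sim_bundle):
        _, genome, index, _, _ = sim_bundle
        p = 4000
        read = fh.ReadRecord("r", fh.revcomp(genome.fetch(p, p + 84)))
        mappings = fh.map_read(read, index, genome, fh.MapperParams(e=0))
        assert ("chr1", p, "-", 0) in mapping_keys(mappings)

    def test_read_with_three_edits_recovered_at_e3(self, sim_bundle):
        _, genome, index, reads, truths = sim_bundle
        params = fh.MapperParams(e=3, mode="edit")
        for read, truth in zip(reads, truths):
            if truth.n_edits != 3:
                continue
            mappings = fh.map_read(read, index, genome, params)
            assert any(
                m.strand == truth.strand
                and m.ref_name == truth.ref_name
                and abs(m.pos - truth.start) <= 3
                for m in mappings
            ), f"{read.id}: origin not recovered"

    def test_short_read_unmapped(self, sim_bundle):
        _, genome, index, _, _ = sim_bundle
        assert fh.map_read(fh.ReadRecord("r", "ACGT"), index, genome, fh.MapperParams()) == []

    def test_report_best_returns_single_lowest_distance(self, sim_bundle):
        _, genome, index, reads, _ = sim_bundle
        params = fh.MapperParams(e=3, report="best")
        for read in reads[:10]:
            out = fh.map_read(read, index, genome, params)
            assert len(out) <= 1

    def test_monotone_in_edit_threshold(self, sim_bundle):
        """The mapping location set can only grow as e increases."""
        _, genome, index, reads, _ = sim_bundle
        for read in reads[:40]:
            prev = set()
            for e in range(4):
                cur = {
                    (m.ref_name, m.pos, m.strand)
                    for m in fh.map_read(read, index, genome, fh.MapperParams(e=e))
                }
                assert prev <= cur
                prev = cur

    def test_multi_sequence_coordinates(self):
        cfg = fh.SimConfig(
            genome_length=8000, n_reads=30, read_length=60, max_edits=2,
            rng_seed=77, n_sequences=3,
        )
        genome = fh.make_genome(cfg)
        index = fh.build_index(genome)
        reads, truths = fh.simulate_reads(genome, cfg)
        params = fh.MapperParams(e=2)
        for read, truth in zip(reads, truths):
            mappings = fh.map_read(read, index, genome, params)
            assert any(
                m.ref_name == truth.ref_name
                and m.strand == truth.strand
                and abs(m.pos - truth.start) <= 2
                for m in mappings
            )


class TestMapFastq:
    @pytest.fixture()
    def small_run(self, sim_bundle, tmp_path):
        _, genome, index, reads, _ = sim_bundle
        fq = tmp_path / "reads.fq"
        write_fastq(fq, reads[:30])
        sam = tmp_path / "out.sam"
        stats = fh.map_fastq(fq, index, genome, fh.MapperParams(e=3), sam)
        return genome, sam, stats, reads[:30]

    def test_stats_monotonicity(self, small_run):
        _, _, stats, reads = small_run
        assert stats.n_reads == len(reads)
        assert stats.n_verified <= stats.n_af_passed <= stats.n_candidates
        assert stats.n_mapped_reads <= stats.n_reads

    def test_sam_parses_and_nm_matches_cigar(self, small_run):
        genome, sam, _, _ = small_run
        with pysam.AlignmentFile(str(sam)) as f:
            n = 0
            for rec in f:
                if rec.is_unmapped:
                    continue
                n += 1
                assert rec.reference_name in genome.names
                nm = rec.get_tag("NM")
                assert nm <= 3
                # CIGAR read-length must equal the sequence length
                assert sum(l for op, l in rec.cigartuples if op in (0, 1)) == rec.query_length
        assert n > 0

    def test_alignment_reconstructs_read_within_distance(self, small_run):
        """Walk each SAM record's CIGAR against the reference and count edits."""
        genome, sam, _, _ = small_run
        with pysam.AlignmentFile(str(sam)) as f:
            for rec in f:
                if rec.is_unmapped:
                    continue
                ref = genome.sequence(rec.reference_name)
                edits = 0
                qpos, rpos = 0, rec.reference_start
                for op, ln in rec.cigartuples:
                    if op == 0:  # M: count mismatches
                        edits += sum(
                            1
                            for a, b in zip(
                                rec.query_sequence[qpos : qpos + ln],
                                ref[rpos : rpos + ln],
                            )
                            if a != b
                        )
                        qpos += ln
                        rpos += ln
                    elif op == 1:
                        edits += ln
                        qpos += ln
                    elif op == 2:
                        edits += ln
                        rpos += ln
                assert edits == rec.get_tag("NM")

    def test_empty_fastq_gives_header_only_sam(self, sim_bundle, tmp_path):
        _, genome, index, _, _ = sim_bundle
        fq = tmp_path / "empty.fq"
        fq.write_text("")
        sam = tmp_path / "empty.sam"
        stats = fh.map_fastq(fq, index, genome, fh.MapperParams(), sam)
        assert stats.n_reads == 0 and stats.n_map_locations == 0
        lines = sam.read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)

    def test_single_perfect_read_nm0(self, sim_bundle, tmp_path):
        _, genome, index, _, _ = sim_bundle
        fq = tmp_path / "one.fq"
        write_fastq(fq, [fh.ReadRecord("perfect", genome.fetch(100, 184))])
        sam = tmp_path / "one.sam"
        fh.map_fastq(fq, index, genome, fh.MapperParams(e=0), sam)
        body = [l for l in sam.read_text().splitlines() if not l.startswith("@")]
        assert len(body) == 1 and "NM:i:0" in body[0]

    def test_malformed_fastq_reports_line(self, sim_bundle, tmp_path):
        _, genome, index, _, _ = sim_bundle
        fq = tmp_path / "bad.fq"
        fq.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(fh.FastqFormatError, match="line"):
            fh.map_fastq(fq, index, genome, fh.MapperParams(), tmp_path / "x.sam")

    def test_stale_index_rejected(self, sim_bundle, tmp_path):
        _, genome, index, _, _ = sim_bundle
        other = fh.ReferenceGenome([("z", "ACGT" * 100)])
        fq = tmp_path / "r.fq"
        fq.write_text("")
        with pytest.raises(fh.StaleIndexError):
            fh.map_fastq(fq, index, other, fh.MapperParams(), tmp_path / "x.sam")


class TestStageBreakdown:
    def test_configs_agree_and_counts_decrease(self, sim_bundle):
        _, genome, index, reads, _ = sim_bundle
        result = fh.run_stage_breakdown(reads[:40], index, genome, fh.MapperParams(e=3))
        assert result.consistent
        base, af, cks = (
            result.stats["baseline"],
            result.stats["af"],
            result.stats["af_cks"],
        )
        assert af.n_verified <= base.n_verified
        assert cks.n_candidates <= af.n_candidates <= base.n_candidates
        for st in result.stats.values():
            assert st.n_verified <= st.n_af_passed <= st.n_candidates

    def test_repeat_genome_cks_reduces_candidates(self):
        cfg = fh.SimConfig(
            genome_length=30_000,
            repeat_spec=[(24, 80), (36, 40)],
            n_reads=40,
            read_length=96,
            max_edits=2,
            rng_seed=31,
        )
        genome = fh.make_genome(cfg)
        index = fh.build_index(genome, fh.IndexParams(k=8))
        reads, _ = fh.simulate_reads(genome, cfg)
        result = fh.run_stage_breakdown(reads, index, genome, fh.MapperParams(e=2))
        assert result.consistent
        assert (
            result.stats["af_cks"].n_candidates
            < result.stats["baseline"].n_candidates
        )
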