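"""Hamming and banded edit-distance verification kernels."""

import re

import edlib
import numpy as np
import pytest

import fasthash as fh

from conftest import random_dna


def cigar_lengths(cigar: str) -> tuple[int, int]:
    """(read bases consumed, reference bases consumed)."""
    read_len = ref_len = 0
    for n, op in re.findall(r"(\d+)([MID])", cigar):
        n = int(n)
        if op in "MI":
            read_len += n
        if op in "MD":
            ref_len += n
    return read_len, ref_len


class TestHamming:
    def test_identical_strings(self):
        assert fh.hamming_verify("A" * 84, "A" * 84, 0) == 0

    def test_counts_substitutions(self):
        assert fh.hamming_verify("ACGTACGT", "ACGAACGT", 3) == 1

    def test_rejects_past_threshold(self):
        assert fh.hamming_verify("AAAA", "TTTA", 2) is None

    def test_n_counts_as_mismatch(self):
        assert fh.hamming_verify("ANGT", "ANGT", 4) == 1

    def test_window_shorter_than_read_raises(self):
        with pytest.raises(fh.WindowError):
            fh.hamming_verify("ACGTACGT", "ACGT", 3)

    def test_extra_window_bases_ignored(self):
        assert fh.hamming_verify("ACGT", "ACGTTTTT", 0) == 0


class TestBandedEditVerify:
    def test_identical_strings(self):
        aln = fh.banded_edit_verify("ACGTACGTACGT", "ACGTACGTACGT", 2)
        assert aln.distance == 0 and aln.cigar == "12M" and aln.ref_start == 0

    def test_free_start_in_window(self):
        aln = fh.banded_edit_verify("CGTA", "ACGTACC", 1, window_start=100)
        assert aln.distance == 0 and aln.ref_start == 101 and aln.ref_span == 4

    def test_deletion_produces_d_op(self):
        # read lacks one reference base
        ref = "ACGTACGTAC"
        read = "ACGTCGTAC"  # A at index 4 deleted
        aln = fh.banded_edit_verify(read, ref, 1)
        assert aln.distance == 1
        assert "D" in aln.cigar
        rl, fl = cigar_lengths(aln.cigar)
        assert rl == len(read) and fl == aln.ref_span == len(read) + 1

    def test_insertion_produces_i_op(self):
        ref = "ACGTACGTA"
        read = "ACGTTACGTA"
        aln = fh.banded_edit_verify(read, ref, 1)
        assert aln.distance == 1 and "I" in aln.cigar

    def test_reject_beyond_threshold(self):
        assert fh.banded_edit_verify("AAAAAAAA", "TTTTTTTT", 3) is None

    def test_ties_prefer_fewest_indels(self):
        # substitution-only interpretation must win over an indel pair
        aln = fh.banded_edit_verify("ACCT", "ACGT", 2)
        assert aln.distance == 1 and aln.cigar == "4M"

    @pytest.mark.parametrize("e", [0, 1, 2, 3, 4, 5])
    def test_agrees_with_full_matrix_dp(self, e):
        """Band safety on ~500 random (read, window, e) triples: banded
        equals the unbanded semi-global distance whenever that is <= e,
        and rejects whenever it exceeds e."""
        rng = np.random.default_rng(1000 + e)
        for _ in range(84):
            l = int(rng.integers(10, 40))
            read = random_dna(rng, l)
            if rng.random() < 0.6:
                # derive the window from the read so distances land near e
                w = list(read)
                for _ in range(int(rng.integers(0, e + 3))):
                    p = int(rng.integers(0, len(w)))
                    op = rng.integers(0, 3)
                    if op == 0:
                        w[p] = "ACGT"[int(rng.integers(0, 4))]
                    elif op == 1:
                        w.insert(p, "ACGT"[int(rng.integers(0, 4))])
                    elif len(w) > 1:
                        del w[p]
                window = random_dna(rng, e) + "".join(w) + random_dna(rng, e)
            else:
                window = random_dna(rng, l + 2 * e)
            full = fh.semiglobal_edit_distance(read, window)
            banded = fh.banded_edit_verify(read, window, e)
            if full <= e:
                assert banded is not None and banded.distance == full
            else:
                assert banded is None

    def test_agrees_with_edlib_infix_mode(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            l = int(rng.integers(15, 60))
            read = random_dna(rng, l)
            window = random_dna(rng, 5) + read + random_dna(rng, 5)
            p = int(rng.integers(0, l))
            window = window[:p] + window[p + 1 :]  # one deletion somewhere
            d_edlib = edlib.align(read, window, mode="HW", task="distance")[
                "editDistance"
            ]
            banded = fh.banded_edit_verify(read, window, 3)
            if d_edlib <= 3:
                assert banded is not None and banded.distance == d_edlib
            else:
                assert banded is None

    def test_cigar_consistency_invariants(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            l = int(rng.integers(12, 50))
            e = int(rng.integers(0, 6))
            read = random_dna(rng, l)
            window = random_dna(rng, e) + read + random_dna(rng, e)
            aln = fh.banded_edit_verify(read, window, e)
            assert aln is not None
            rl, fl = cigar_lengths(aln.cigar)
            assert rl == l
            assert fl == aln.ref_span
            assert abs(aln.ref_span - l) <= e

    def test_hamming_acceptance_implies_edit_acceptance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            l = int(rng.integers(12, 40))
            e = int(rng.integers(0, 5))
            read = list(random_dna(rng, l))
            window = read.copy()
            for p in rng.choice(l, size=min(e, l), replace=False):
                window[p] = "ACGT"[int(rng.integers(0, 4))]
            read, window = "".join(read), "".join(window)
            hd = fh.hamming_verify(read, window, e)
            if hd is not None:
                aln = fh.banded_edit_verify(read, window, e)
                assert aln is not None and aln.distance <= hd


class TestAnchoredDistance:
    def test_exact_match(self):
        assert fh.anchored_edit_distance("ACGTACGT", "ACGTACGTAA", 2) == 0

    def test_charges_shift_as_edits(self):
        # the read matches two bases downstream of the anchor
        assert fh.anchored_edit_distance("GTAC", "AAGTACAA", 3) == 2

    def test_reject_beyond_threshold(self):
        assert fh.anchored_edit_distance("AAAA", "TTTTTTT", 2) is None
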