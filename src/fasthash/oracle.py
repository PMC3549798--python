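"""Brute-force full-scan mapping oracle and candidate-labelling utilities.

The oracle never seeds or filters: it evaluates the verification kernel
at every genome offset on both strands, which makes it the independent
reference for the mapper's sensitivity and comprehensiveness on
desk-scale genomes (up to ~100 kb per run).  For edit mode the scan
first computes, with a vectorized semi-global dynamic program over the
whole sequence, the minimum edit distance of every possible alignment
end column; the (rare) columns within the threshold are then resolved
through exactly the same canonical verification used by the mapper, so
both routes produce identical mapping records by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .adjacency_filter import AFParams, af_test
from .genome_index import KmerIndex, ReferenceGenome, revcomp_codes, seq_to_codes
from .seeding import (
    ReadRecord,
    ReadSeedingPlan,
    _partition_codes,
    generate_candidates,
    select_cheap_kmers,
)
from .verification import banded_edit_verify, resolve_mapping

MappingKey = tuple[str, int, str, int]  # (ref_name, start, strand, distance)


def semiglobal_edit_distance(read_seq, window_seq) -> int:
    """Full-matrix unit-cost edit distance, read consumed entirely,
    window start and end free.  O(l * W) reference for the banded kernel."""
    r = seq_to_codes(read_seq) if isinstance(read_seq, str) else np.asarray(read_seq)
    w = (
        seq_to_codes(window_seq)
        if isinstance(window_seq, str)
        else np.asarray(window_seq)
    )
    l, W = len(r), len(w)
    prev = [0] * (W + 1)
    for i in range(1, l + 1):
        cur = [i] + [0] * W
        rc = int(r[i - 1])
        for j in range(1, W + 1):
            wc = int(w[j - 1])
            sub = 0 if (wc == rc and wc < 4) else 1
            cur[j] = min(prev[j - 1] + sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def edit_scan_last_row(read_codes: np.ndarray, seq_codes: np.ndarray) -> np.ndarray:
    """Minimum semi-global edit distance for every alignment end column.

    Row ``i`` of the DP is computed over all columns at once; the
    in-row dependency D[i,j] = min(v[j], D[i,j-1] + 1) is a running
    minimum, evaluated as ``j + cummin(v[j] - j)``.  Returns the final
    row ``D[l, 0..G]``.
    """
    l = len(read_codes)
    G = len(seq_codes)
    jj = np.arange(G + 1, dtype=np.int32)
    row = np.zeros(G + 1, dtype=np.int32)  # free start
    v = np.empty(G + 1, dtype=np.int32)
    seq_bad = seq_codes >= 4
    for i in range(1, l + 1):
        rc = int(read_codes[i - 1])
        sub = (seq_codes != rc) | seq_bad if rc < 4 else np.ones(G, dtype=bool)
        v[0] = i
        np.minimum(row[:-1] + sub, row[1:] + 1, out=v[1:])
        row = jj + np.minimum.accumulate(v - jj)
    return row


def brute_force_map(
    read: ReadRecord,
    genome: ReferenceGenome,
    e: int,
    mode: str = "edit",
    strands: str = "+-",
) -> set[MappingKey]:
    """All placements of the read with distance <= e, full genome scan.

    Results are deduplicated by the same post-alignment
    ``(ref_name, start, strand)`` key as the mapper, keeping the minimal
    distance.
    """
    l = len(read.seq)
    fwd = seq_to_codes(read.seq)
    best: dict[tuple[str, int, str], int] = {}

    def _resolve(codes: np.ndarray, gstart: int, strand: str) -> None:
        res = resolve_mapping(codes, genome, gstart, e, mode)
        if res is None:
            return
        g, dist, _cigar = res
        name, pos = genome.to_local(g)
        key = (name, pos, strand)
        if key not in best or dist < best[key]:
            best[key] = dist

    for si in range(genome.n_sequences):
        lo, hi = int(genome.offsets[si]), int(genome.offsets[si + 1])
        seq_codes = genome.codes[lo:hi]
        if len(seq_codes) == 0:
            continue
        for strand in strands:
            codes = fwd if strand == "+" else revcomp_codes(fwd)
            if mode == "hamming":
                if len(seq_codes) < l:
                    continue
                wins = sliding_window_view(seq_codes, l)
                mism = ((wins != codes) | (wins >= 4) | (codes >= 4)).sum(axis=1)
                for s in np.flatnonzero(mism <= e):
                    _resolve(codes, lo + int(s), strand)
            else:
                last = edit_scan_last_row(codes, seq_codes)
                for jend in np.flatnonzero(last <= e):
                    s = min(max(int(jend) - l, 0), len(seq_codes) - 1)
                    _resolve(codes, lo + s, strand)
    return {(name, pos, strand, d) for (name, pos, strand), d in best.items()}


@dataclass
class CandidateAudit:
    """Oracle labelling of candidate locations vs. the AF verdict.

    A candidate location is *true* when verification at it succeeds --
    the banded alignment over its ``[s - e, s + l + e)`` neighborhood
    stays within the edit threshold -- and *false* when verification
    would reject it.  That is exactly the distinction the adjacency
    filter tries to anticipate without running the alignment.
    """

    n_true: int = 0
    n_false: int = 0
    n_true_rejected: int = 0
    n_false_rejected: int = 0

    @property
    def false_rejection_rate(self) -> float:
        """Fraction of oracle-labelled false candidates that AF rejects."""
        return self.n_false_rejected / self.n_false if self.n_false else float("nan")


def audit_af_on_candidates(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    genome: ReferenceGenome,
    e: int,
) -> CandidateAudit:
    """Enumerate every CKS candidate on both strands, label each with the
    anchored-edit oracle, and record AF's verdicts."""
    audit = CandidateAudit()
    for read in reads:
        l = len(read.seq)
        if l < index.k:
            continue
        fwd = seq_to_codes(read.seq)
        for strand in "+-":
            codes = fwd if strand == "+" else revcomp_codes(fwd)
            kmers = _partition_codes(codes, index.k)
            plan = ReadSeedingPlan(kmers=kmers, N=len(kmers), read_length=l)
            selected = select_cheap_kmers(plan, index, e)
            candidates = generate_candidates(plan, selected, index, genome)
            lists = [
                None if km.ambiguous else index.query_locations(km.encoded)
                for km in kmers
            ]
            afp = AFParams(e=e, N=plan.N, k=index.k)
            for cand in candidates:
                passed = af_test(cand, plan, index, afp, lists=lists).passed
                lo, hi = genome.seq_interval(cand.start)
                window = genome.fetch_codes(
                    max(lo, cand.start - e), min(hi, cand.start + l + e)
                )
                is_true = banded_edit_verify(codes, window, e) is not None
                if is_true:
                    audit.n_true += 1
                    if not passed:
                        audit.n_true_rejected += 1
                else:
                    audit.n_false += 1
                    if not passed:
                        audit.n_false_rejected += 1
    return audit
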