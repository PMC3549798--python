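"""Read partitioning, cheap k-mer selection (CKS) and candidate generation.

A read of length ``l`` is divided into ``N = floor(l / k)`` consecutive,
non-overlapping k-mers at offsets ``0, k, 2k, ...``; the trailing
``l mod k`` bases carry no seed and participate only in verification.
CKS sorts the k-mers by the cardinality of their location lists and seeds
only from the cheapest ``e + 1``: since ``e`` edits can corrupt at most
``e`` non-overlapping k-mers, at least one selected k-mer matches the
reference exactly at any placement within edit distance ``e``, which is
what makes the selection fully sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NoSeedError, ReadTooShortError
from .genome_index import KmerIndex, ReferenceGenome, seq_to_codes


@dataclass
class ReadRecord:
    """A sequencing read.  Qualities are carried through but never scored."""

    id: str
    seq: str
    quals: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SeedKmer:
    """One of the read's consecutive k-mers.

    ``encoded`` is ``None`` when the k-mer contains an ambiguous base, in
    which case it cannot be queried and its cardinality is infinite so that
    CKS never prefers it.
    """

    read_offset: int
    encoded: int | None
    cardinality: float = 0.0

    @property
    def ambiguous(self) -> bool:
        return self.encoded is None


@dataclass(frozen=True)
class CandidateLocation:
    """Putative global read-start position derived from one seed hit."""

    start: int
    source_kmer: int


@dataclass
class ReadSeedingPlan:
    """The read's k-mers plus the CKS-selected subset."""

    kmers: list[SeedKmer]
    N: int
    read_length: int
    selected: list[int] | None = field(default=None)


def _partition_codes(codes: np.ndarray, k: int) -> list[SeedKmer]:
    l = len(codes)
    if l < k:
        raise ReadTooShortError(f"read length {l} < k = {k}")
    kmers: list[SeedKmer] = []
    for j in range(l // k):
        o = j * k
        window = codes[o : o + k]
        if (window >= 4).any():
            kmers.append(SeedKmer(read_offset=o, encoded=None, cardinality=math.inf))
        else:
            val = 0
            for c in window:
                val = val * 4 + int(c)
            kmers.append(SeedKmer(read_offset=o, encoded=val))
    return kmers


def partition_read(read: ReadRecord, k: int) -> list[SeedKmer]:
    """Divide a read into ``floor(l/k)`` consecutive non-overlapping k-mers.

    Raises :class:`ReadTooShortError` when ``l < k`` (the read is then
    reported unmapped by the pipeline).
    """
    return _partition_codes(seq_to_codes(read.seq), k)


def attach_cardinalities(kmers: list[SeedKmer], index: KmerIndex) -> None:
    """Populate each queryable k-mer's location-list cardinality."""
    for km in kmers:
        if not km.ambiguous:
            km.cardinality = float(len(index.query_locations(km.encoded)))


def build_plan(read: ReadRecord, index: KmerIndex) -> ReadSeedingPlan:
    """Partition a read and populate cardinalities against ``index``."""
    kmers = partition_read(read, index.k)
    attach_cardinalities(kmers, index)
    return ReadSeedingPlan(kmers=kmers, N=len(kmers), read_length=len(read.seq))


def select_cheap_kmers(plan: ReadSeedingPlan, index: KmerIndex, e: int) -> list[int]:
    """Select the ``min(e + 1, N)`` k-mers with the smallest cardinalities.

    Ties are broken by smaller read offset, which makes the selection
    deterministic.  Ambiguous k-mers carry infinite cardinality and are
    chosen only when there are not enough queryable ones; if every k-mer
    is ambiguous a :class:`NoSeedError` is raised.
    """
    attach_cardinalities(plan.kmers, index)
    if all(km.ambiguous for km in plan.kmers):
        raise NoSeedError("all k-mers of the read contain ambiguous bases")
    order = sorted(
        range(plan.N),
        key=lambda j: (plan.kmers[j].cardinality, plan.kmers[j].read_offset),
    )
    selected = sorted(order[: min(e + 1, plan.N)])
    plan.selected = selected
    return selected


def generate_candidates(
    plan: ReadSeedingPlan,
    selected: list[int],
    index: KmerIndex,
    genome: ReferenceGenome | None = None,
) -> list[CandidateLocation]:
    """Turn seed hits into deduplicated, sorted candidate read starts.

    Each location ``loc`` in the list of selected k-mer ``j`` (read offset
    ``o_j``) implies the read starts at ``loc - o_j``.  When a genome is
    supplied, starts are clamped so the verification window stays inside
    the record containing the seed hit (edge reads remain mappable);
    without one, negative starts are clamped to zero.  Identical starts
    are deduplicated keeping the first source k-mer.
    """
    l = plan.read_length
    seen: dict[int, int] = {}
    single_record = genome is not None and genome.n_sequences == 1
    for j in selected:
        km = plan.kmers[j]
        if km.ambiguous:
            continue
        locs = index.query_locations(km.encoded)
        if len(locs) == 0:
            continue
        starts = locs - km.read_offset
        if genome is None:
            starts = np.maximum(starts, 0)
        elif single_record:
            hi = genome.total_length
            starts = np.clip(starts, 0, max(0, hi - l))
        else:
            clamped = np.empty_like(starts)
            for i, (loc, s) in enumerate(zip(locs, starts)):
                lo, hi = genome.seq_interval(int(loc))
                clamped[i] = min(max(int(s), lo), max(lo, hi - l))
            starts = clamped
        for s in starts:
            s = int(s)
            if s not in seen:
                seen[s] = j
    return [CandidateLocation(start=s, source_kmer=j) for s, j in sorted(seen.items())]
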