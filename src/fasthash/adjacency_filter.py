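"""Adjacency Filtering (AF): reject obviously false candidate locations.

For a candidate read start ``s``, every k-mer at read offset ``o_j`` is
expected near reference position ``s + o_j``.  Substitutions corrupt the
edited k-mer's sequence; insertions and deletions additionally shift all
downstream k-mers by up to the number of indels.  Both effects are
absorbed by searching each k-mer's sorted location list for a hit inside
the adjacent range ``[s + o_j - e, s + o_j + e]``.  Since at most ``e``
edits can each corrupt at most one k-mer, a placement within edit
distance ``e`` must still have at least ``N - e`` k-mers hitting their
adjacent ranges; candidates below that threshold are rejected before the
(expensive) verification step.  AF is one-sided: it never rejects a
placement whose anchored edit distance is <= e, but placements it passes
may still fail verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_index import KmerIndex
from .seeding import CandidateLocation, ReadSeedingPlan


@dataclass(frozen=True)
class AFParams:
    """Filter parameters: edit budget ``e``, k-mer count ``N``, seed size ``k``."""

    e: int
    N: int
    k: int

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError("edit distance must be non-negative")


@dataclass
class AFResult:
    passed: bool
    matched: int
    failed_kmers: list[int] = field(default_factory=list)


def adjacent_range(start: int, read_offset: int, e: int) -> tuple[int, int]:
    """Closed interval ``[start + read_offset - e, start + read_offset + e]``.

    Width ``2e + 1``; with ``e = 0`` it degenerates to the single expected
    position of the k-mer.
    """
    center = start + read_offset
    return center - e, center + e


def range_hit(locs: np.ndarray, lo: int, hi: int) -> bool:
    """True iff the sorted list contains an element in ``[lo, hi]``.

    Binary search: O(log n) comparisons.
    """
    i = int(np.searchsorted(locs, lo, side="left"))
    return i < len(locs) and int(locs[i]) <= hi


def af_test(
    candidate: CandidateLocation,
    plan: ReadSeedingPlan,
    index: KmerIndex,
    params: AFParams,
    lists: list[np.ndarray | None] | None = None,
) -> AFResult:
    """Run the adjacency test for one candidate against all N k-mers.

    AF searches every k-mer's location list, not only the CKS-selected
    ones.  ``lists`` may carry the prefetched per-k-mer location lists
    (``None`` entries for ambiguous k-mers) to avoid re-querying the hash
    table for every candidate of the same read.

    Ambiguous k-mers count as matched: they cannot be searched, and
    failing them could reject a genuinely close placement.  When
    ``e >= N`` the test is vacuous and passes outright.  The scan
    short-circuits as soon as the threshold is out of reach, so
    ``matched`` is exact only for passing candidates.
    """
    N = params.N
    e = params.e
    if e >= N:
        return AFResult(passed=True, matched=N)
    threshold = N - e  # >= 1 here
    if lists is None:
        lists = [
            None if km.ambiguous else index.query_locations(km.encoded)
            for km in plan.kmers
        ]
    matched = 0
    failed: list[int] = []
    for j, km in enumerate(plan.kmers):
        locs = lists[j]
        if locs is None:
            matched += 1  # conservative auto-match for ambiguous k-mers
            continue
        lo, hi = adjacent_range(candidate.start, km.read_offset, e)
        if range_hit(locs, lo, hi):
            matched += 1
        else:
            failed.append(j)
            if matched + (N - j - 1) < threshold:
                return AFResult(passed=False, matched=matched, failed_kmers=failed)
    return AFResult(passed=matched >= threshold, matched=matched, failed_kmers=failed)
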