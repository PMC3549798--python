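"""Verification: Hamming and banded edit-distance alignment of a read
against the reference window at a candidate location.

Costs are unit Levenshtein (substitution = insertion = deletion = 1); an
``N`` in either sequence never matches anything.  The read is consumed in
full ("global in read") while the window overhang on either side is free,
because the window is only a candidate neighborhood, not an exact span.
The dynamic program is restricted to a diagonal band wide enough to hold
every alignment that both fits in the window and has at most ``e`` edits,
so the cell count is O(e * l) rather than O(l^2).  Ties are broken by
fewest indels, then leftmost reference start, making CIGARs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import WindowError
from .genome_index import ReferenceGenome, seq_to_codes

_INF = 1 << 30


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return seq_to_codes(seq)
    return np.asarray(seq, dtype=np.uint8)


@dataclass(frozen=True)
class VerifyParams:
    """``mode='hamming'`` admits substitutions only; ``mode='edit'`` is the
    banded unit-cost alignment that also absorbs indels."""

    e: int
    mode: str = "edit"

    def __post_init__(self) -> None:
        if self.mode not in ("hamming", "edit"):
            raise ValueError(f"unknown verification mode {self.mode!r}")
        if self.e < 0:
            raise ValueError("edit distance must be non-negative")


@dataclass(frozen=True)
class Alignment:
    """A verified placement.  ``ref_start`` is global and 0-based;
    ``ref_span`` is the number of reference bases consumed."""

    distance: int
    cigar: str
    ref_start: int
    ref_span: int


def hamming_verify(read_seq, ref_window, e: int) -> int | None:
    """Substitution count over the first ``l`` window bases, or ``None``
    when it exceeds ``e``.  The window must be at least read-length long."""
    r = _as_codes(read_seq)
    w = _as_codes(ref_window)
    l = len(r)
    if len(w) < l:
        raise WindowError(f"reference window ({len(w)} bp) shorter than read ({l} bp)")
    w = w[:l]
    d = int(((w != r) | (w >= 4) | (r >= 4)).sum())
    return d if d <= e else None


def banded_edit_verify(
    read_seq, ref_window, e: int, *, window_start: int = 0
) -> Alignment | None:
    """Minimum-edit alignment of the read into the window, or ``None``.

    The window is expected to be the candidate neighborhood
    ``genome[s - e, s + l + e)`` (clamped at record bounds).  The band
    covers diagonals ``j - i`` in ``[-e, (W - l) + 2e]``, which contains
    every alignment with at most ``e`` edits that fits in a window of
    width ``W``; hence banded and full dynamic programming agree whenever
    the true distance is at most ``e``.  Rows whose minimum exceeds ``e``
    abort early.  ``window_start`` is the window's global coordinate, used
    to report ``ref_start``.
    """
    r = _as_codes(read_seq)
    w = _as_codes(ref_window)
    l = len(r)
    W = len(w)
    if l == 0:
        return Alignment(0, "", window_start, 0)
    if W < l - e:
        return None  # even e deletions cannot absorb the length deficit
    dlo = -e
    dhi = max(-e, (W - l) + 2 * e)
    nd = dhi - dlo + 1

    cost = [_INF] * nd
    indels = [0] * nd
    start = [0] * nd
    # ops[i][d]: 0 = alignment start, 1 = diagonal (M), 2 = up (I), 3 = left (D)
    ops = [[0] * nd for _ in range(l + 1)]
    for d in range(dlo, dhi + 1):
        j = d
        if 0 <= j <= W:
            idx = d - dlo
            cost[idx] = 0
            start[idx] = j

    for i in range(1, l + 1):
        rc = int(r[i - 1])
        ncost = [_INF] * nd
        nindels = [0] * nd
        nstart = [0] * nd
        oprow = ops[i]
        for idx in range(nd):
            j = i + dlo + idx
            if j < 0 or j > W:
                continue
            bc, bi, bs, bop = _INF, 0, 0, 0
            if j >= 1 and cost[idx] < _INF:  # diagonal: consume read + window
                wc = int(w[j - 1])
                c = cost[idx] + (1 if (wc != rc or wc >= 4 or rc >= 4) else 0)
                bc, bi, bs, bop = c, indels[idx], start[idx], 1
            if idx + 1 < nd and cost[idx + 1] < _INF:  # up: read base unmatched (I)
                c = cost[idx + 1] + 1
                ci, cs = indels[idx + 1] + 1, start[idx + 1]
                if (c, ci, cs) < (bc, bi, bs):
                    bc, bi, bs, bop = c, ci, cs, 2
            if idx >= 1 and ncost[idx - 1] < _INF:  # left: window base unmatched (D)
                c = ncost[idx - 1] + 1
                ci, cs = nindels[idx - 1] + 1, nstart[idx - 1]
                if (c, ci, cs) < (bc, bi, bs):
                    bc, bi, bs, bop = c, ci, cs, 3
            ncost[idx], nindels[idx], nstart[idx] = bc, bi, bs
            oprow[idx] = bop
        cost, indels, start = ncost, nindels, nstart
        if min(cost) > e:
            return None

    best = None
    for idx in range(nd):
        j = l + dlo + idx
        if j < 0 or j > W or cost[idx] > e:
            continue
        key = (cost[idx], indels[idx], start[idx], j)
        if best is None or key < best[0]:
            best = (key, idx)
    if best is None:
        return None
    (dist, _nind, j_start, j_end), idx = best

    # traceback for the CIGAR
    raw_ops: list[str] = []
    i, cur = l, idx
    while i > 0:
        op = ops[i][cur]
        if op == 1:
            raw_ops.append("M")
            i -= 1
        elif op == 2:
            raw_ops.append("I")
            i -= 1
            cur += 1
        elif op == 3:
            raw_ops.append("D")
            cur -= 1
        else:  # pragma: no cover - row 0 is never a traceback source
            break
    raw_ops.reverse()
    cigar_parts: list[str] = []
    run, prev = 0, ""
    for opc in raw_ops:
        if opc == prev:
            run += 1
        else:
            if prev:
                cigar_parts.append(f"{run}{prev}")
            run, prev = 1, opc
    if prev:
        cigar_parts.append(f"{run}{prev}")
    return Alignment(
        distance=int(dist),
        cigar="".join(cigar_parts),
        ref_start=window_start + j_start,
        ref_span=j_end - j_start,
    )


def anchored_edit_distance(read_seq, ref_window, e: int) -> int | None:
    """Edit distance of the read aligned with its start anchored at the
    window's first position (free end), or ``None`` when it exceeds ``e``.

    This is the quantity that labels a candidate location true or false:
    the window should be ``genome[s, s + l + e)``.  Leading window bases
    can still be skipped, but each skip costs one edit, so the distance is
    anchored to ``s`` rather than to the cheapest nearby start.  The band
    covers diagonals ``[-e, e]``: (2e + 1) * l cells.
    """
    r = _as_codes(read_seq)
    w = _as_codes(ref_window)
    l = len(r)
    W = len(w)
    if W < l - e:
        return None
    nd = 2 * e + 1
    cost = [_INF] * nd
    for d in range(0, e + 1):
        if d <= W:
            cost[d + e] = d  # leading deletions away from the anchor
    for i in range(1, l + 1):
        rc = int(r[i - 1])
        ncost = [_INF] * nd
        for idx in range(nd):
            j = i + idx - e
            if j < 0 or j > W:
                continue
            best = _INF
            if j >= 1 and cost[idx] < _INF:
                wc = int(w[j - 1])
                best = cost[idx] + (1 if (wc != rc or wc >= 4 or rc >= 4) else 0)
            if idx + 1 < nd and cost[idx + 1] + 1 < best:
                best = cost[idx + 1] + 1
            if idx >= 1 and ncost[idx - 1] + 1 < best:
                best = ncost[idx - 1] + 1
            ncost[idx] = best
        cost = ncost
        if min(cost) > e:
            return None
    d = min(cost)
    return int(d) if d <= e else None


def resolve_mapping(
    read_codes: np.ndarray,
    genome: ReferenceGenome,
    start: int,
    e: int,
    mode: str = "edit",
) -> tuple[int, int, str] | None:
    """Verify a candidate start and return the canonical
    ``(global_start, distance, cigar)``, or ``None`` on rejection.

    In edit mode the window is re-centered on the resolved start until it
    is a fixed point, so that nearby candidates of the same placement
    always resolve to one identical mapping record (the deduplication key
    downstream).  The iteration terminates because the (distance, indels,
    start) key never worsens when the window is re-centered.
    """
    l = len(read_codes)
    lo, hi = genome.seq_interval(start)
    if mode == "hamming":
        if start + l > hi:
            return None
        d = hamming_verify(read_codes, genome.fetch_codes(start, start + l), e)
        return None if d is None else (start, d, f"{l}M")
    cur = start
    aln: Alignment | None = None
    for _ in range(8):
        wlo = max(lo, cur - e)
        whi = min(hi, cur + l + e)
        aln = banded_edit_verify(
            read_codes, genome.fetch_codes(wlo, whi), e, window_start=wlo
        )
        if aln is None:
            return None
        if aln.ref_start == cur:
            break
        cur = aln.ref_start
    return (aln.ref_start, aln.distance, aln.cigar)
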