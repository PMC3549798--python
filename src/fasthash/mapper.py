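"""End-to-end mapping pipeline: partition -> CKS -> candidates -> AF ->
verification, on both strands, with per-stage statistics.

The reverse strand is handled by reverse-complementing the read and
mapping it against the forward index; reported coordinates are always on
the forward reference.  After indel-tolerant verification, nearby
candidates can resolve to the same alignment, so mappings are
deduplicated on the post-alignment ``(ref_name, ref_start, strand)`` key,
keeping the minimal distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .adjacency_filter import AFParams, af_test
from .errors import NoSeedError, StaleIndexError
from .genome_index import (
    KmerIndex,
    ReferenceGenome,
    load_index,
    revcomp_codes,
    seq_to_codes,
)
from .io import read_fastq, sam_header, write_sam_read
from .seeding import (
    ReadRecord,
    ReadSeedingPlan,
    _partition_codes,
    attach_cardinalities,
    generate_candidates,
    select_cheap_kmers,
)
from .verification import resolve_mapping


@dataclass(frozen=True)
class MapperParams:
    """Pipeline parameters.

    ``report='all'`` (the default) returns every verified location, which
    is the comprehensiveness contract of an all-mapper; ``'best'`` keeps
    the single lowest-distance (then leftmost) placement.  ``use_af`` and
    ``use_cks`` exist to run the ablation configurations of
    :func:`run_stage_breakdown`; both optimizations are pure filters and
    never change the reported mapping set.
    """

    e: int = 3
    mode: str = "edit"  # or "hamming"
    report: str = "all"  # or "best"
    use_af: bool = True
    use_cks: bool = True

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError("edit distance must be non-negative")
        if self.mode not in ("edit", "hamming"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.report not in ("all", "best"):
            raise ValueError(f"unknown report policy {self.report!r}")


@dataclass(frozen=True)
class Mapping:
    """A verified alignment on the forward reference (0-based ``pos``)."""

    read_id: str
    ref_name: str
    pos: int
    strand: str
    distance: int
    cigar: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.ref_name, self.pos, self.strand)


@dataclass
class StageStats:
    """Per-stage location counts for the pipeline's ablation breakdown."""

    n_reads: int = 0
    n_candidates: int = 0
    n_af_passed: int = 0
    n_verified: int = 0
    n_mapped_reads: int = 0
    n_map_locations: int = 0

    @property
    def af_pass_rate(self) -> float:
        return self.n_af_passed / self.n_candidates if self.n_candidates else 0.0

    @property
    def verify_rate(self) -> float:
        return self.n_verified / self.n_af_passed if self.n_af_passed else 0.0

    def as_row(self) -> dict[str, int]:
        return {
            "reads": self.n_reads,
            "candidates": self.n_candidates,
            "af_passed": self.n_af_passed,
            "verified": self.n_verified,
            "mapped_reads": self.n_mapped_reads,
            "map_locations": self.n_map_locations,
        }


def map_read(
    read: ReadRecord,
    index: KmerIndex,
    genome: ReferenceGenome,
    params: MapperParams,
    stats: StageStats | None = None,
) -> list[Mapping]:
    """Map one read on both strands; returns mappings sorted by
    ``(ref_name, pos, strand)``.  Reads shorter than ``k`` (or with every
    k-mer ambiguous) come back unmapped (empty list)."""
    if stats is not None:
        stats.n_reads += 1
    l = len(read.seq)
    if l < index.k:
        return []
    fwd_codes = seq_to_codes(read.seq)
    found: dict[tuple[int, str], tuple[int, str]] = {}
    for strand in "+-":
        codes = fwd_codes if strand == "+" else revcomp_codes(fwd_codes)
        kmers = _partition_codes(codes, index.k)
        plan = ReadSeedingPlan(kmers=kmers, N=len(kmers), read_length=l)
        if params.use_cks:
            try:
                selected = select_cheap_kmers(plan, index, params.e)
            except NoSeedError:
                continue  # all k-mers ambiguous on this strand
        else:
            attach_cardinalities(kmers, index)
            selected = [j for j, km in enumerate(kmers) if not km.ambiguous]
            if not selected:
                continue
            plan.selected = selected
        candidates = generate_candidates(plan, selected, index, genome)
        if stats is not None:
            stats.n_candidates += len(candidates)
        lists = [
            None if km.ambiguous else index.query_locations(km.encoded)
            for km in kmers
        ]
        afp = AFParams(e=params.e, N=plan.N, k=index.k)
        for cand in candidates:
            if params.use_af and not af_test(cand, plan, index, afp, lists=lists).passed:
                continue
            if stats is not None:
                stats.n_af_passed += 1
            res = resolve_mapping(codes, genome, cand.start, params.e, params.mode)
            if res is None:
                continue
            if stats is not None:
                stats.n_verified += 1
            gstart, dist, cigar = res
            key = (gstart, strand)
            prev = found.get(key)
            if prev is None or dist < prev[0]:
                found[key] = (dist, cigar)
    mappings = []
    for (gstart, strand), (dist, cigar) in found.items():
        name, pos = genome.to_local(gstart)
        mappings.append(
            Mapping(
                read_id=read.id,
                ref_name=name,
                pos=pos,
                strand=strand,
                distance=dist,
                cigar=cigar,
            )
        )
    mappings.sort(key=lambda m: (m.ref_name, m.pos, m.strand))
    if stats is not None:
        if mappings:
            stats.n_mapped_reads += 1
        stats.n_map_locations += len(mappings)
    if params.report == "best" and mappings:
        best = min(mappings, key=lambda m: (m.distance, m.ref_name, m.pos, m.strand))
        return [best]
    return mappings


def map_fastq(
    fastq_path: str | Path,
    index: KmerIndex | str | Path,
    genome: ReferenceGenome | str | Path,
    params: MapperParams,
    sam_out: str | Path,
    command: str | None = None,
) -> StageStats:
    """Map a FASTQ file to SAM and return the per-stage statistics.

    ``index``/``genome`` may be objects or paths; a persisted index is
    checked against the reference digest and a mismatch raises
    :class:`StaleIndexError`.
    """
    if not isinstance(genome, ReferenceGenome):
        genome = ReferenceGenome.from_fasta(genome)
    if not isinstance(index, KmerIndex):
        index = load_index(index, genome=genome)
    elif index.genome_digest != genome.digest():
        raise StaleIndexError("index was built from a different genome")
    stats = StageStats()
    with open(sam_out, "w") as out:
        out.write(sam_header(genome, command))
        for read in read_fastq(fastq_path):
            mappings = map_read(read, index, genome, params, stats=stats)
            write_sam_read(out, read, mappings)
    return stats


@dataclass
class BreakdownResult:
    """Ablation of the two optimizations on one read set.

    ``stats`` and ``mappings`` are keyed by configuration name:
    ``baseline`` (all N k-mers seed, no AF), ``af`` (adjacency filtering
    added) and ``af_cks`` (the full pipeline).  All three must report the
    identical mapping set -- the optimizations only remove verification
    work, never mappings.
    """

    stats: dict[str, StageStats] = field(default_factory=dict)
    mappings: dict[str, set] = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        sets = list(self.mappings.values())
        return all(s == sets[0] for s in sets[1:])


_CONFIGS = (
    ("baseline", False, False),
    ("af", True, False),
    ("af_cks", True, True),
)


def run_stage_breakdown(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    genome: ReferenceGenome,
    params: MapperParams,
) -> BreakdownResult:
    """Run baseline / +AF / +AF+CKS and collect stage counts per config."""
    reads = list(reads)
    result = BreakdownResult()
    for name, use_af, use_cks in _CONFIGS:
        p = replace(params, use_af=use_af, use_cks=use_cks)
        stats = StageStats()
        mapped: set[tuple[str, str, int, str, int]] = set()
        for read in reads:
            for m in map_read(read, index, genome, p, stats=stats):
                mapped.add((m.read_id, m.ref_name, m.pos, m.strand, m.distance))
        result.stats[name] = stats
        result.mappings[name] = mapped
    return result
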