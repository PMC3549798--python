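"""FASTQ input and SAM output helpers."""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterator, TextIO

from .errors import FastqFormatError
from .genome_index import ReferenceGenome, revcomp
from .seeding import ReadRecord

if TYPE_CHECKING:  # pragma: no cover
    from .mapper import Mapping


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate 4-line FASTQ records, preserving the quality string.

    Malformed records raise :class:`FastqFormatError` with the approximate
    line number of the offending record.
    """
    from Bio import SeqIO

    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            quals = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield ReadRecord(id=rec.id, seq=str(rec.seq).upper(), quals=quals)
    except ValueError as err:
        raise FastqFormatError(
            f"{path}: malformed FASTQ record near line {4 * n + 1}: {err}"
        ) from err


def write_fastq(path: str | Path, reads: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.quals or 'I' * len(r.seq)}\n")


def sam_header(genome: ReferenceGenome, command: str | None = None) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for i, name in enumerate(genome.names):
        length = int(genome.offsets[i + 1] - genome.offsets[i])
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    pg = "@PG\tID:fasthash\tPN:fasthash"
    if command:
        pg += f"\tCL:{command}"
    lines.append(pg)
    return "\n".join(lines) + "\n"


def write_sam_read(out: TextIO, read: ReadRecord, mappings: "list[Mapping]") -> None:
    """Emit one SAM line per mapping (or a FLAG-4 line when unmapped).

    POS is converted to 1-based here and only here.  Reverse-strand lines
    carry the reverse-complemented sequence, as SAM requires; the best
    mapping (lowest distance, then leftmost) is primary and the rest are
    flagged secondary.
    """
    qual = read.quals or "*"
    if not mappings:
        out.write(f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{qual}\n")
        return
    primary = min(mappings, key=lambda m: (m.distance, m.ref_name, m.pos, m.strand))
    ordered = [primary] + [m for m in mappings if m is not primary]
    for rank, m in enumerate(ordered):
        flag = 0
        if m.strand == "-":
            flag |= 16
        if rank > 0:
            flag |= 256
        seq = read.seq if m.strand == "+" else revcomp(read.seq)
        q = qual if m.strand == "+" or qual == "*" else qual[::-1]
        out.write(
            f"{read.id}\t{flag}\t{m.ref_name}\t{m.pos + 1}\t255\t{m.cigar}"
            f"\t*\t0\t0\t{seq}\t{q}\tNM:i:{m.distance}\n"
        )
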