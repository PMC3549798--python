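"""Synthetic genomes and reads with recorded ground truth.

The generator emulates the study conditions the mapper is evaluated
under: a uniform random A/C/G/T background (optionally with planted
repeat motifs to skew the k-mer frequency distribution the way real
genomes do), and reads sampled uniformly from both strands carrying 0 to
``max_edits`` random substitutions / insertions / deletions, with the
edit count uniform on ``{0..max_edits}``.  Everything is driven by one
seeded generator, so a given seed reproduces the data byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SimConfigError
from .genome_index import ReferenceGenome, codes_to_seq, revcomp
from .io import write_fastq
from .seeding import ReadRecord

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Simulation parameters.

    ``repeat_spec`` is a list of ``(motif_length, copies)`` pairs; each
    motif is drawn once at random and planted at ``copies`` random
    non-overlapping positions, overwriting the background, which produces
    the imbalanced location lists (a few expensive k-mers, many cheap
    ones) that cheap k-mer selection exploits.
    """

    genome_length: int
    repeat_spec: list[tuple[int, int]] = field(default_factory=list)
    n_reads: int = 1000
    read_length: int = 108
    max_edits: int = 3
    rng_seed: int = 0
    n_sequences: int = 1

    def __post_init__(self) -> None:
        if self.genome_length < 10 * self.read_length:
            raise SimConfigError(
                "genome_length must be at least 10x the read length"
            )
        total_repeat = sum(m * c for m, c in self.repeat_spec)
        if total_repeat > self.genome_length:
            raise SimConfigError(
                f"planted repeats ({total_repeat} bp) exceed the genome length"
            )
        if self.max_edits < 0:
            raise SimConfigError("max_edits must be non-negative")


@dataclass
class SimulatedTruth:
    """Ground truth for one read: origin and the injected edits.

    ``edits`` entries are ``(type, read_position, base)`` with type in
    ``{sub, ins, del}``; for a deletion the base is the removed reference
    base and the read position is where the removal took effect.
    """

    read_id: str
    ref_name: str
    start: int
    strand: str
    edits: list[tuple[str, int, str]]

    @property
    def n_edits(self) -> int:
        return len(self.edits)


def make_genome(config: SimConfig, fasta_path: str | Path | None = None) -> ReferenceGenome:
    """Generate the synthetic reference; optionally write it as FASTA."""
    rng = np.random.default_rng(config.rng_seed)
    codes = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    planted = np.zeros(config.genome_length, dtype=bool)
    for motif_len, copies in config.repeat_spec:
        motif = rng.integers(0, 4, size=motif_len, dtype=np.uint8)
        placed = 0
        attempts = 0
        while placed < copies and attempts < 50 * copies:
            attempts += 1
            p = int(rng.integers(0, config.genome_length - motif_len + 1))
            if planted[p : p + motif_len].any():
                continue
            codes[p : p + motif_len] = motif
            planted[p : p + motif_len] = True
            placed += 1
        if placed < copies:
            raise SimConfigError(
                f"could not place {copies} non-overlapping copies of a "
                f"{motif_len} bp motif in {config.genome_length} bp"
            )
    n_seq = max(1, config.n_sequences)
    bounds = np.linspace(0, config.genome_length, n_seq + 1).astype(int)
    records = [
        (f"chr{i + 1}", codes_to_seq(codes[bounds[i] : bounds[i + 1]]))
        for i in range(n_seq)
    ]
    genome = ReferenceGenome(records)
    if fasta_path is not None:
        genome.write_fasta(fasta_path)
    return genome


def _edit_read(
    window: np.ndarray, l: int, n_edits: int, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, str]]]:
    """Apply ``n_edits`` random edits at distinct read positions.

    ``window`` must hold at least ``l + n_edits`` reference bases so that
    deletions always have a base to consume.
    """
    positions = rng.choice(l, size=n_edits, replace=False) if n_edits else []
    kinds = rng.integers(0, 3, size=n_edits)  # 0 sub, 1 ins, 2 del
    events = {int(p): int(k) for p, k in zip(positions, kinds)}
    out: list[str] = []
    edits: list[tuple[str, int, str]] = []
    cur = 0
    for p in range(l):
        kind = events.get(p)
        if kind == 2:  # deletion: skip one reference base, then copy
            edits.append(("del", p, _BASES[int(window[cur])]))
            cur += 1
            out.append(_BASES[int(window[cur])])
            cur += 1
        elif kind == 0:  # substitution with a guaranteed different base
            ref_b = int(window[cur])
            new_b = (ref_b + 1 + int(rng.integers(0, 3))) % 4
            edits.append(("sub", p, _BASES[new_b]))
            out.append(_BASES[new_b])
            cur += 1
        elif kind == 1:  # insertion of a random base
            b = _BASES[int(rng.integers(0, 4))]
            edits.append(("ins", p, b))
            out.append(b)
        else:
            out.append(_BASES[int(window[cur])])
            cur += 1
    return "".join(out), edits


def simulate_reads(
    genome: ReferenceGenome,
    config: SimConfig,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[ReadRecord], list[SimulatedTruth]]:
    """Sample reads with ground truth; optionally write FASTQ + truth TSV.

    Origins are uniform over windows that leave ``l + max_edits``
    reference bases, strand is uniform, and the edit count is uniform on
    ``{0..max_edits}``.  A '-'-strand read is the reverse complement of
    the edited forward-strand window; its recorded origin stays in
    forward coordinates.
    """
    l = config.read_length
    need = l + config.max_edits
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 0x5EED]).generate_state(1)[0]
    )
    seq_windows = [
        max(0, int(genome.offsets[i + 1] - genome.offsets[i]) - need + 1)
        for i in range(genome.n_sequences)
    ]
    total_windows = sum(seq_windows)
    if total_windows == 0:
        raise SimConfigError("reads (plus edit slack) are longer than every sequence")
    weights = np.array(seq_windows, dtype=float) / total_windows
    width = len(str(config.n_reads))
    reads: list[ReadRecord] = []
    truths: list[SimulatedTruth] = []
    for i in range(config.n_reads):
        si = int(rng.choice(genome.n_sequences, p=weights))
        start_local = int(rng.integers(0, seq_windows[si]))
        gstart = int(genome.offsets[si]) + start_local
        n_edits = int(rng.integers(0, config.max_edits + 1))
        window = genome.fetch_codes(gstart, gstart + need)
        seq, edits = _edit_read(window, l, n_edits, rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"simread_{i:0{width}d}"
        reads.append(ReadRecord(id=rid, seq=seq, quals="I" * l))
        truths.append(
            SimulatedTruth(
                read_id=rid,
                ref_name=genome.names[si],
                start=start_local,
                strand=strand,
                edits=edits,
            )
        )
    if fastq_path is not None:
        write_fastq(fastq_path, reads)
    if truth_path is not None:
        write_truth(truth_path, truths)
    return reads, truths


def write_truth(path: str | Path, truths: list[SimulatedTruth]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "ref_name", "start", "strand", "n_edits", "edits"])
        for t in truths:
            desc = ";".join(f"{k}@{p}:{b}" for k, p, b in t.edits)
            writer.writerow([t.read_id, t.ref_name, t.start, t.strand, t.n_edits, desc])


def read_truth(path: str | Path) -> list[SimulatedTruth]:
    truths = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edits = []
            if row["edits"]:
                for item in row["edits"].split(";"):
                    kind, rest = item.split("@", 1)
                    pos, base = rest.split(":", 1)
                    edits.append((kind, int(pos), base))
            truths.append(
                SimulatedTruth(
                    read_id=row["read_id"],
                    ref_name=row["ref_name"],
                    start=int(row["start"]),
                    strand=row["strand"],
                    edits=edits,
                )
            )
    return truths
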