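"""Reference genome container and the k-mer -> location-list hash index.

The index is the classic seed-and-extend hash table: every overlapping
k-mer of the forward reference strand is a key (2-bit encoded into an
integer in ``[0, 4**k)``) and the value is the sorted array of 0-based
global genome positions where that k-mer starts.  Windows containing an
``N`` are never indexed.  Only the forward strand is indexed; reverse
strand mapping is handled by reverse-complementing the read.

Coordinates are 0-based, half-open throughout the package.  Multi-record
genomes live in one global coordinate space; a k-mer window never crosses
a record boundary because windows are formed per record.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import AmbiguousKmerError, IndexFormatError, StaleIndexError

# Base encoding: A=0, C=1, G=2, T=3 (big-endian base-4 within a k-mer).
# N and every other IUPAC ambiguity code map to 4 ("ambiguous").
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_EMPTY_LOCS = np.empty(0, dtype=np.int64)


def seq_to_codes(seq: str) -> np.ndarray:
    """Translate a DNA string into a uint8 code array (A0 C1 G2 T3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; ambiguous bases stay ambiguous."""
    comp = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
    return comp[::-1]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


def encode_kmer(seq: str) -> int:
    """Encode a k-mer string as an integer in ``[0, 4**k)``.

    Big-endian base 4: the first base carries the highest weight.
    Raises :class:`AmbiguousKmerError` for any non-ACGT character.
    """
    codes = seq_to_codes(seq)
    if (codes >= 4).any():
        raise AmbiguousKmerError(f"k-mer contains a non-ACGT base: {seq!r}")
    return int(codes.astype(np.int64) @ (4 ** np.arange(len(codes) - 1, -1, -1)))


def encode_window(codes: np.ndarray) -> int | None:
    """Encode a code-array window; ``None`` if the window is ambiguous."""
    if (codes >= 4).any():
        return None
    val = 0
    for c in codes:
        val = val * 4 + int(c)
    return val


def decode_kmer(code: int, k: int) -> str:
    if not 0 <= code < 4**k:
        raise ValueError(f"encoded k-mer {code} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class IndexParams:
    """Indexing parameters.  ``k`` is the seed length in bp (default 12)."""

    k: int = 12

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 15:
            raise ValueError(f"k must be in [1, 15], got {self.k}")


class ReferenceGenome:
    """Ordered multi-record reference held as one global code array.

    Parameters
    ----------
    records
        Iterable of ``(name, sequence)`` pairs.  Sequences are uppercased
        and any ambiguity code other than N is conservatively mapped to N.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        names: list[str] = []
        chunks: list[np.ndarray] = []
        for name, seq in records:
            names.append(name)
            chunks.append(seq_to_codes(seq))
        if not names:
            raise ValueError("reference genome has no sequences")
        self.names: list[str] = names
        self._codes = (
            np.concatenate(chunks) if len(chunks) > 1 else chunks[0].copy()
        )
        lengths = np.fromiter((len(c) for c in chunks), dtype=np.int64, count=len(chunks))
        self.offsets = np.concatenate(([0], np.cumsum(lengths)))
        self._digest: str | None = None

    # -- construction ----------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from Bio import SeqIO

        records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
        return cls(records)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.iter_records():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    # -- basic properties ------------------------------------------------
    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    def iter_records(self) -> Iterator[tuple[str, str]]:
        for i, name in enumerate(self.names):
            yield name, codes_to_seq(self._codes[self.offsets[i] : self.offsets[i + 1]])

    def sequence(self, name: str) -> str:
        i = self.names.index(name)
        return codes_to_seq(self._codes[self.offsets[i] : self.offsets[i + 1]])

    def digest(self) -> str:
        """SHA-256 over the normalized records; identifies the indexed genome."""
        if self._digest is None:
            h = hashlib.sha256()
            for i, name in enumerate(self.names):
                h.update(name.encode())
                h.update(b"\x00")
                h.update(self._codes[self.offsets[i] : self.offsets[i + 1]].tobytes())
                h.update(b"\n")
            self._digest = h.hexdigest()
        return self._digest

    # -- coordinate conversion -------------------------------------------
    def to_global(self, name: str, pos: int) -> int:
        i = self.names.index(name)
        if not 0 <= pos < self.offsets[i + 1] - self.offsets[i]:
            raise ValueError(f"position {pos} outside sequence {name!r}")
        return int(self.offsets[i] + pos)

    def to_local(self, gpos: int) -> tuple[str, int]:
        if not 0 <= gpos < self.total_length:
            raise ValueError(f"global position {gpos} outside genome")
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.offsets[i])

    def seq_interval(self, gpos: int) -> tuple[int, int]:
        """Global ``[start, end)`` bounds of the record containing ``gpos``."""
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        i = min(max(i, 0), self.n_sequences - 1)
        return int(self.offsets[i]), int(self.offsets[i + 1])

    def fetch_codes(self, start: int, end: int) -> np.ndarray:
        return self._codes[start:end]

    def fetch(self, start: int, end: int) -> str:
        return codes_to_seq(self._codes[start:end])


class KmerIndex:
    """k-mer -> sorted location-list hash table over a :class:`ReferenceGenome`."""

    def __init__(
        self,
        k: int,
        table: dict[int, np.ndarray],
        genome_digest: str,
        n_indexed_positions: int,
    ):
        self.k = k
        self.table = table
        self.genome_digest = genome_digest
        self.n_indexed_positions = n_indexed_positions

    def query_locations(self, kmer: int) -> np.ndarray:
        """Sorted location list for an encoded k-mer (empty if absent).

        The length of the returned list is the k-mer's *cardinality*, the
        quantity cheap k-mer selection sorts on.
        """
        if not 0 <= kmer < 4**self.k:
            raise ValueError(f"encoded k-mer {kmer} out of range for k={self.k}")
        return self.table.get(kmer, _EMPTY_LOCS)

    def cardinality(self, kmer: int) -> int:
        return len(self.query_locations(kmer))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerIndex):
            return NotImplemented
        return (
            self.k == other.k
            and self.genome_digest == other.genome_digest
            and self.n_indexed_positions == other.n_indexed_positions
            and self.table.keys() == other.table.keys()
            and all(np.array_equal(self.table[key], other.table[key]) for key in self.table)
        )


def build_index(genome: ReferenceGenome, params: IndexParams | None = None) -> KmerIndex:
    """Index every N-free k-mer window of the forward strand.

    Positions are global 0-based window starts; each location list ends up
    sorted ascending because windows are generated in genome order and the
    key sort is stable.
    """
    params = params or IndexParams()
    k = params.k
    all_keys: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    for i in range(genome.n_sequences):
        lo, hi = int(genome.offsets[i]), int(genome.offsets[i + 1])
        codes = genome.codes[lo:hi]
        n = len(codes) - k + 1
        if n <= 0:
            continue
        vals = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for t in range(k):
            col = codes[t : t + n]
            vals = vals * 4 + col
            ok &= col < 4
        all_keys.append(vals[ok])
        all_pos.append(np.flatnonzero(ok).astype(np.int64) + lo)
    if all_keys:
        keys = np.concatenate(all_keys)
        pos = np.concatenate(all_pos)
    else:
        keys = np.empty(0, dtype=np.int64)
        pos = np.empty(0, dtype=np.int64)
    order = np.argsort(keys, kind="stable")
    keys = keys[order]
    pos = pos[order]
    table: dict[int, np.ndarray] = {}
    if len(keys):
        bounds = np.flatnonzero(np.diff(keys)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(keys)]))
        for s, e in zip(starts, ends):
            table[int(keys[s])] = pos[s:e]
    return KmerIndex(
        k=k,
        table=table,
        genome_digest=genome.digest(),
        n_indexed_positions=len(pos),
    )


# -- persistence ----------------------------------------------------------
# Little-endian layout:
#   magic "FASTHASH" | u32 version | u32 k | u64 n_keys | u64 n_positions |
#   64-byte ASCII sha256 hex digest |
#   per key: u64 key, u64 list length, then that many u64 positions.

_MAGIC = b"FASTHASH"
_VERSION = 1
_HEADER = struct.Struct("<8sII QQ 64s")


def save_index(index: KmerIndex, path: str | Path) -> None:
    keys = sorted(index.table)
    parts = [
        _HEADER.pack(
            _MAGIC,
            _VERSION,
            index.k,
            len(keys),
            index.n_indexed_positions,
            index.genome_digest.encode("ascii"),
        )
    ]
    for key in keys:
        locs = index.table[key]
        rec = np.empty(2 + len(locs), dtype="<u8")
        rec[0] = key
        rec[1] = len(locs)
        rec[2:] = locs
        parts.append(rec.tobytes())
    Path(path).write_bytes(b"".join(parts))


def load_index(path: str | Path, genome: ReferenceGenome | None = None) -> KmerIndex:
    """Load a persisted index; verify against ``genome`` when provided."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER.size:
        raise IndexFormatError(f"{path}: truncated header")
    magic, version, k, n_keys, n_pos, digest = _HEADER.unpack_from(raw)
    if magic != _MAGIC:
        raise IndexFormatError(f"{path}: bad magic string")
    if version != _VERSION:
        raise IndexFormatError(f"{path}: unsupported format version {version}")
    if (len(raw) - _HEADER.size) % 8:
        raise IndexFormatError(f"{path}: truncated body")
    body = np.frombuffer(raw, dtype="<u8", offset=_HEADER.size)
    if len(body) != 2 * n_keys + n_pos:
        raise IndexFormatError(
            f"{path}: expected {2 * n_keys + n_pos} words, found {len(body)}"
        )
    table: dict[int, np.ndarray] = {}
    i = 0
    for _ in range(n_keys):
        key = int(body[i])
        ln = int(body[i + 1])
        if i + 2 + ln > len(body):
            raise IndexFormatError(f"{path}: truncated location list for key {key}")
        table[key] = body[i + 2 : i + 2 + ln].astype(np.int64)
        i += 2 + ln
    index = KmerIndex(
        k=k,
        table=table,
        genome_digest=digest.decode("ascii"),
        n_indexed_positions=n_pos,
    )
    if genome is not None and index.genome_digest != genome.digest():
        raise StaleIndexError(
            f"{path}: index was built for a different genome "
            f"({index.genome_digest[:12]}... != {genome.digest()[:12]}...)"
        )
    return index
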