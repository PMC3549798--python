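"""Exception hierarchy for the fasthash mapper."""


class FastHashError(Exception):
    """Base class for all fasthash-specific errors."""


class AmbiguousKmerError(FastHashError):
    """A k-mer containing a non-ACGT base cannot be integer-encoded."""


class ReadTooShortError(FastHashError):
    """Read shorter than the index k-mer length; it cannot be seeded."""


class NoSeedError(FastHashError):
    """Every k-mer of the read is ambiguous; no hash-table query is possible."""


class StaleIndexError(FastHashError):
    """Index genome digest does not match the reference supplied at mapping time."""


class IndexFormatError(FastHashError):
    """Index file is truncated, has a bad magic string, or an unknown version."""


class WindowError(FastHashError):
    """Reference window too short for the requested comparison."""


class FastqFormatError(FastHashError):
    """Malformed FASTQ record."""


class SimConfigError(FastHashError):
    """Invalid simulation configuration."""
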