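"""FASTQ ingestion and 2-bit packed in-memory read storage.

All reads of one sample group ("normal" or "mutated") are held in memory as
bit strings where each base occupies 2 bits (A=00, C=01, G=10, T=11), a
four-fold saving over one byte per base.  Reads are grouped into blocks of
64; each block stores one machine address plus a 2-byte per-read offset
header, so random access by dense read ID costs an amortized
``2 + 8/64 = 2.125`` bytes of index per read.

Base qualities are parsed for format validation only and never used:
quality-based filtering is deliberately outside this caller's model.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

NORMAL = "normal"
MUTATED = "mutated"

BLOCK_SIZE = 64
#: bytes of a machine pointer, amortized over one block
_ADDRESS_BYTES = 8
#: bytes of the per-read offset header
_HEADER_BYTES = 2

# ASCII -> 2-bit code lookup; 255 marks every non-ACGT byte.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGT", "TGCA")


class EncodingError(ValueError):
    """A sequence contains a base outside the 2-bit alphabet {A,C,G,T}."""


def _codes_from_text(seq: str) -> np.ndarray:
    """Map an ACGT string to an array of 2-bit codes (uint8 values 0..3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(
            f"non-ACGT base {seq[pos]!r} at position {pos}; "
            "the 2-bit code has no representation for it"
        )
    return codes


def _text_from_codes(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def _pack(codes: np.ndarray) -> bytes:
    """Pack 2-bit codes four to a byte, first base in the high bits."""
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4)
    packed = (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
    return packed.astype(np.uint8).tobytes()


def _unpack(data: bytes, n_bases: int) -> np.ndarray:
    if n_bases > 4 * len(data):
        raise IndexError(
            f"cannot decode {n_bases} bases from {len(data)} packed bytes"
        )
    packed = np.frombuffer(data, dtype=np.uint8)
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = packed >> 6
    out[1::4] = (packed >> 4) & 3
    out[2::4] = (packed >> 2) & 3
    out[3::4] = packed & 3
    return out[:n_bases]


def encode_sequence(seq: str) -> bytes:
    """Encode an ACGT string into packed 2 bits per base.

    The first base occupies the two most significant bits of the first
    byte, so ``"ACGT"`` encodes to the single byte ``0b00011011``.

    Raises
    ------
    EncodingError
        If the (uppercased) sequence contains a non-ACGT character; the
        message names the first offending position.
    """
    seq = seq.upper()
    if not seq:
        return b""
    return _pack(_codes_from_text(seq))


def decode_sequence(packed: bytes, length: int) -> str:
    """Inverse of :func:`encode_sequence`: recover ``length`` bases."""
    if length == 0:
        return ""
    return _text_from_codes(_unpack(packed, length))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    seq = seq.upper()
    if seq.strip("ACGT"):
        _codes_from_text(seq)  # raises EncodingError naming the position
    return seq.translate(_RC_TABLE)[::-1]


def index_overhead_bytes(block_size: int) -> float:
    """Amortized index bytes per read for block-addressed storage.

    One 2-byte in-block offset per read plus one 8-byte block address
    shared by ``block_size`` reads: ``2 + 8/block_size`` (2.125 for the
    default block of 64 reads).
    """
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    return _HEADER_BYTES + _ADDRESS_BYTES / block_size


@dataclass
class _Block:
    """Up to 64 reads packed contiguously; offsets are in bases."""

    data: bytes
    offsets: np.ndarray  # uint16, start base offset of each read
    total_bases: int


class PackedReadStore:
    """All reads of one sample group, 2-bit encoded and block-indexed.

    Read IDs are dense integers ``0..n_reads-1`` in load order.  Reads
    that cannot be represented (any non-ACGT base) or that are shorter
    than ``min_length`` are dropped at load and counted in ``n_dropped``.
    """

    def __init__(self, group_label: str, block_size: int = BLOCK_SIZE) -> None:
        if group_label not in (NORMAL, MUTATED):
            raise ValueError(f"group_label must be 'normal' or 'mutated', got {group_label!r}")
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        self.group_label = group_label
        self.block_size = block_size
        self.n_reads = 0
        self.n_dropped = 0
        self._blocks: list[_Block] = []
        # open block under construction
        self._pending_codes: list[np.ndarray] = []
        self._code_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction -------------------------------------------------

    def append(self, seq: str) -> int:
        """Store one read; returns its dense ID."""
        codes = _codes_from_text(seq.upper())
        self._pending_codes.append(codes)
        self._code_cache = None
        if len(self._pending_codes) == self.block_size:
            self._seal_block()
        self.n_reads += 1
        return self.n_reads - 1

    def _seal_block(self) -> None:
        lengths = [len(c) for c in self._pending_codes]
        offsets = np.zeros(len(lengths), dtype=np.uint16)
        if len(lengths) > 1:
            offsets[1:] = np.cumsum(lengths[:-1]).astype(np.uint16)
        total = int(sum(lengths))
        if total > 0xFFFF:
            raise OverflowError("block exceeds 65535 bases; 2-byte offsets overflow")
        concat = (
            np.concatenate(self._pending_codes)
            if self._pending_codes
            else np.empty(0, dtype=np.uint8)
        )
        self._blocks.append(_Block(_pack(concat), offsets, total))
        self._pending_codes = []

    # -- access -------------------------------------------------------

    def __len__(self) -> int:
        return self.n_reads

    def _locate(self, read_id: int) -> tuple[_Block | None, int]:
        if not 0 <= read_id < self.n_reads:
            raise IndexError(f"read id {read_id} out of range 0..{self.n_reads - 1}")
        block_idx, within = divmod(read_id, self.block_size)
        if block_idx < len(self._blocks):
            return self._blocks[block_idx], within
        return None, within  # read is in the open (unsealed) block

    def read_length(self, read_id: int) -> int:
        block, within = self._locate(read_id)
        if block is None:
            return len(self._pending_codes[within])
        start = int(block.offsets[within])
        end = (
            int(block.offsets[within + 1])
            if within + 1 < len(block.offsets)
            else block.total_bases
        )
        return end - start

    def get_read(self, read_id: int) -> str:
        """Decode and return the ``read_id``-th loaded read."""
        block, within = self._locate(read_id)
        if block is None:
            return _text_from_codes(self._pending_codes[within])
        start = int(block.offsets[within])
        length = self.read_length(read_id)
        codes = _unpack(block.data, block.total_bases)
        return _text_from_codes(codes[start : start + length])

    def __iter__(self) -> Iterator[str]:
        for i in range(self.n_reads):
            yield self.get_read(i)

    def code_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Unpack all reads into ``(codes, starts)`` for vectorized access.

        ``codes`` concatenates every read's 2-bit codes as uint8 values;
        ``starts`` has ``n_reads + 1`` entries so read *i* occupies
        ``codes[starts[i]:starts[i+1]]``.  The result is cached; the packed
        blocks remain the canonical storage.
        """
        if self._code_cache is None:
            parts = [_unpack(b.data, b.total_bases) for b in self._blocks]
            parts.extend(self._pending_codes)
            codes = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
            )
            lengths = np.fromiter(
                (self.read_length(i) for i in range(self.n_reads)),
                dtype=np.int64,
                count=self.n_reads,
            )
            starts = np.zeros(self.n_reads + 1, dtype=np.int64)
            np.cumsum(lengths, out=starts[1:])
            self._code_cache = (codes, starts)
        return self._code_cache

    def index_overhead_bytes(self) -> float:
        """Bookkeeping: amortized index bytes per read for this store."""
        return index_overhead_bytes(self.block_size)


class FastqFormatError(ValueError):
    """A FASTQ record is malformed; the message carries the record index."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        record_idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ValueError("sequence and quality lengths differ")
                yield title, seq, qual
                record_idx += 1
        except ValueError as exc:
            raise FastqFormatError(
                f"malformed FASTQ record {record_idx} in {path}: {exc}"
            ) from exc


def load_reads(
    fastq_paths: str | Path | Sequence[str | Path],
    group_label: str,
    *,
    min_length: int = 1,
    block_size: int = BLOCK_SIZE,
) -> PackedReadStore:
    """Load one sample group's FASTQ file(s) into a :class:`PackedReadStore`.

    Parameters
    ----------
    fastq_paths
        One file (single-end) or two files (paired-end mates, which must
        have equal record counts).  Plain or gzip-compressed.
    group_label
        ``"normal"`` or ``"mutated"``.
    min_length
        Reads shorter than this are dropped (a read shorter than ``d+1``
        cannot contribute a divergence column; callers pass ``d+1``).

    Whole reads containing any non-ACGT base (N, IUPAC codes) are dropped
    and counted in ``n_dropped`` rather than recoded to an arbitrary base,
    which would fabricate sequence content and could seed false
    breakpoints.  Paired mates are stored as independent reads.
    """
    if isinstance(fastq_paths, (str, Path)):
        paths = [fastq_paths]
    else:
        paths = list(fastq_paths)
    if not 1 <= len(paths) <= 2:
        raise ValueError("expected one (single-end) or two (paired-end) FASTQ files")

    store = PackedReadStore(group_label, block_size=block_size)

    def _store(seq: str) -> None:
        seq = seq.upper()
        if len(seq) < min_length or seq.strip("ACGT"):
            store.n_dropped += 1
            return
        store.append(seq)

    if len(paths) == 1:
        for _title, seq, _qual in _iter_fastq(paths[0]):
            _store(seq)
    else:
        it1, it2 = _iter_fastq(paths[0]), _iter_fastq(paths[1])
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                raise ValueError(
                    f"paired FASTQ files {paths[0]} and {paths[1]} have unequal record counts"
                )
            _store(r1[1])
            _store(r2[1])
    logger.info(
        "loaded %s group: %d reads kept, %d dropped", group_label, store.n_reads, store.n_dropped
    )
    return store
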