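"""Suffix enumeration, 4^k prefix partitioning and lexicographic sorting.

Every suffix of length >= d of every read (and, in non-strand-specific
mode, of every read's reverse complement) is a candidate witness of a
breakpoint.  To bound memory, the suffix universe is split into 4^k
batches by the length-k prefix of each suffix; batches are processed one
at a time, in lexicographic prefix order, and released after use.  The
value of k trades batch size against the number of passes and does not
change the final call set.

Two access paths are provided:

* a reference API (:func:`collect_suffixes`, :func:`sort_suffix_refs`)
  operating on explicit :class:`SuffixRef` handles — convenient and
  exactly specified, intended for small inputs and cross-checks;
* :class:`SuffixEngine`, the vectorized path the pipeline uses, which
  keeps suffixes as parallel numpy arrays and sorts on fixed-width
  ``d+1``-base keys (sufficient to delimit breakpoint clusters, whose
  identity depends only on the first ``d+1`` suffix columns).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .read_store import NORMAL, MUTATED, PackedReadStore, _text_from_codes

FORWARD = "forward"
REVERSE = "reverse"

_GROUP_ORDER = {NORMAL: 0, MUTATED: 1}
_STRAND_ORDER = {FORWARD: 0, REVERSE: 1}


@dataclass(frozen=True, order=True)
class SuffixRef:
    """Handle to one suffix occurrence: read, start offset, group, strand.

    ``strand == "reverse"`` means the suffix is taken from the reverse
    complement of the stored read.  ``suffix_length = read_length - offset``.
    """

    group: str
    strand: str
    read_id: int
    offset: int
    suffix_length: int


@dataclass(frozen=True)
class PartitionPlan:
    """The 4^k length-k prefixes, in lexicographic order."""

    k: int
    prefixes: tuple[str, ...]


def list_prefixes(k: int) -> PartitionPlan:
    """All 4^k k-mers over ACGT in lexicographic order (A < C < G < T).

    ``k = 0`` yields the single empty prefix, i.e. no partitioning.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k > 8:
        raise ValueError(f"k above 8 would create {4**k} partitions; refusing")
    prefixes = tuple("".join(p) for p in itertools.product("ACGT", repeat=k))
    return PartitionPlan(k=k, prefixes=prefixes)


class SuffixEngine:
    """Vectorized suffix access over a normal and a mutated read store.

    Internally concatenates the 2-bit code arrays of both groups — and,
    when ``strand_specific`` is false, of every read's reverse complement —
    into one pool of "oriented reads", each tagged with (group, strand,
    original read id).
    """

    def __init__(
        self,
        normal: PackedReadStore,
        mutated: PackedReadStore,
        *,
        strand_specific: bool = True,
    ) -> None:
        self.strand_specific = strand_specific
        self.stores = {NORMAL: normal, MUTATED: mutated}
        code_parts: list[np.ndarray] = []
        length_parts: list[np.ndarray] = []
        group_parts: list[np.ndarray] = []
        strand_parts: list[np.ndarray] = []
        read_id_parts: list[np.ndarray] = []
        for g_idx, store in ((0, normal), (1, mutated)):
            codes, starts = store.code_arrays()
            lengths = np.diff(starts)
            strands = [0] if strand_specific else [0, 1]
            for s_idx in strands:
                if s_idx == 0:
                    code_parts.append(codes)
                else:
                    # reverse complement: 3 - code, read-wise reversal
                    rc = np.empty_like(codes)
                    for i in range(store.n_reads):
                        seg = codes[starts[i] : starts[i + 1]]
                        rc[starts[i] : starts[i + 1]] = (3 - seg)[::-1]
                    code_parts.append(rc)
                length_parts.append(lengths)
                group_parts.append(np.full(store.n_reads, g_idx, dtype=np.uint8))
                strand_parts.append(np.full(store.n_reads, s_idx, dtype=np.uint8))
                read_id_parts.append(np.arange(store.n_reads, dtype=np.int64))
        self.codes = (
            np.concatenate(code_parts) if code_parts else np.empty(0, dtype=np.uint8)
        )
        self.lengths = (
            np.concatenate(length_parts)
            if length_parts
            else np.empty(0, dtype=np.int64)
        )
        self.starts = np.zeros(len(self.lengths) + 1, dtype=np.int64)
        np.cumsum(self.lengths, out=self.starts[1:])
        self.group = (
            np.concatenate(group_parts) if group_parts else np.empty(0, dtype=np.uint8)
        )
        self.strand = (
            np.concatenate(strand_parts)
            if strand_parts
            else np.empty(0, dtype=np.uint8)
        )
        self.read_id = (
            np.concatenate(read_id_parts)
            if read_id_parts
            else np.empty(0, dtype=np.int64)
        )
        self.n_oriented = len(self.lengths)

    # -- suffix enumeration -------------------------------------------

    def enumerate_suffixes(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """All suffixes of length >= d as ``(oriented_read_idx, offset)``."""
        if d < 1:
            raise ValueError("d must be >= 1")
        counts = np.maximum(self.lengths - d + 1, 0)
        v = np.repeat(np.arange(self.n_oriented, dtype=np.int64), counts)
        # offset within each oriented read: 0..counts[i]-1
        boundaries = np.zeros(len(v), dtype=np.int64)
        if len(v):
            firsts = np.zeros(self.n_oriented + 1, dtype=np.int64)
            np.cumsum(counts, out=firsts[1:])
            boundaries = np.arange(len(v), dtype=np.int64) - firsts[v]
        return v, boundaries

    def prefix_ids(self, v: np.ndarray, o: np.ndarray, k: int) -> np.ndarray:
        """Integer id of each suffix's first-k bases (base-4, A=0..T=3)."""
        ids = np.zeros(len(v), dtype=np.int64)
        pos = self.starts[v] + o
        for j in range(k):
            ids = ids * 4 + self.codes[pos + j]
        return ids

    def key_matrix(self, v: np.ndarray, o: np.ndarray, ncols: int) -> np.ndarray:
        """First ``ncols`` suffix bases as codes+1 (0 pads past suffix end).

        The pad value 0 sorts a proper prefix before any of its
        extensions, matching lexicographic order on the full texts for
        every comparison decided within ``ncols`` columns.
        """
        n = len(v)
        key = np.zeros((n, ncols), dtype=np.uint8)
        pos = self.starts[v] + o
        avail = self.lengths[v] - o
        for j in range(ncols):
            mask = avail > j
            key[mask, j] = self.codes[pos[mask] + j] + 1
        return key

    def sort_batch(
        self, v: np.ndarray, o: np.ndarray, ncols: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Order a suffix batch by its ``ncols``-column key, then by the
        deterministic tie-break (group, strand, read_id, offset).

        Returns ``(order, key)`` with ``key`` already reordered.
        """
        key = self.key_matrix(v, o, ncols)
        cols = [o, self.read_id[v], self.strand[v], self.group[v]]
        cols.extend(key[:, j] for j in range(ncols - 1, -1, -1))
        order = np.lexsort(cols)
        return order, key[order]

    # -- text recovery ------------------------------------------------

    def oriented_read_text(self, v: int) -> str:
        return _text_from_codes(self.codes[self.starts[v] : self.starts[v + 1]])

    def suffix_text(self, v: int, o: int) -> str:
        return _text_from_codes(self.codes[self.starts[v] + o : self.starts[v + 1]])

    def make_ref(self, v: int, o: int) -> SuffixRef:
        return SuffixRef(
            group=NORMAL if self.group[v] == 0 else MUTATED,
            strand=FORWARD if self.strand[v] == 0 else REVERSE,
            read_id=int(self.read_id[v]),
            offset=int(o),
            suffix_length=int(self.lengths[v] - o),
        )

    def resolve(self, ref: SuffixRef) -> int:
        """Oriented-read index for a :class:`SuffixRef`."""
        g = _GROUP_ORDER[ref.group]
        s = _STRAND_ORDER[ref.strand]
        base = 0
        n_norm = self.stores[NORMAL].n_reads
        n_mut = self.stores[MUTATED].n_reads
        per_store = 1 if self.strand_specific else 2
        if s == 1 and self.strand_specific:
            raise ValueError("reverse-strand suffix in a strand-specific engine")
        if g == 0:
            base = s * n_norm
        else:
            base = per_store * n_norm + s * n_mut
        return base + ref.read_id

    def ref_suffix_text(self, ref: SuffixRef) -> str:
        return self.suffix_text(self.resolve(ref), ref.offset)


def collect_suffixes(
    normal: PackedReadStore,
    mutated: PackedReadStore,
    prefix: str,
    d: int,
    *,
    strand_specific: bool = True,
    engine: SuffixEngine | None = None,
) -> list[SuffixRef]:
    """Every suffix of length >= d whose first ``len(prefix)`` bases equal
    ``prefix``, across both groups (and both strands when not
    strand-specific).

    ``d`` must be at least the prefix length so that a suffix's partition
    is decided within its guaranteed columns.
    """
    k = len(prefix)
    if d < k:
        raise ValueError(f"d ({d}) must be >= prefix length ({k})")
    if engine is None:
        engine = SuffixEngine(normal, mutated, strand_specific=strand_specific)
    v, o = engine.enumerate_suffixes(d)
    if k:
        want = 0
        for ch in prefix:
            want = want * 4 + "ACGT".index(ch)
        mask = engine.prefix_ids(v, o, k) == want
        v, o = v[mask], o[mask]
    return [engine.make_ref(int(vi), int(oi)) for vi, oi in zip(v, o)]


def sort_suffix_refs(
    refs: Sequence[SuffixRef],
    normal: PackedReadStore,
    mutated: PackedReadStore,
    *,
    engine: SuffixEngine | None = None,
) -> list[SuffixRef]:
    """Order suffix references by full lexicographic order of their texts.

    A proper prefix sorts before any extension of it.  Ties on identical
    text break deterministically by (group, strand, read_id, offset) so
    output is byte-reproducible across runs.
    """
    if engine is None:
        strand_specific = all(r.strand == FORWARD for r in refs)
        engine = SuffixEngine(normal, mutated, strand_specific=strand_specific)

    def key(ref: SuffixRef):
        return (
            engine.ref_suffix_text(ref),
            _GROUP_ORDER[ref.group],
            _STRAND_ORDER[ref.strand],
            ref.read_id,
            ref.offset,
        )

    return sorted(refs, key=key)
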