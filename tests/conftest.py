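"""Shared fixtures: tiny read sets built in memory or on disk."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from breakscan.read_store import MUTATED, NORMAL, PackedReadStore


def make_store(seqs, group=NORMAL, block_size=64) -> PackedReadStore:
    store = PackedReadStore(group, block_size=block_size)
    for s in seqs:
        store.append(s)
    return store


def make_stores(normal_seqs, mutated_seqs):
    return make_store(normal_seqs, NORMAL), make_store(mutated_seqs, MUTATED)


def tile_reads(hap: str, read_len: int, step: int) -> list[str]:
    """Error-free reads tiling a haplotype at a fixed stride."""
    return [hap[i : i + read_len] for i in range(0, len(hap) - read_len + 1, step)]


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def write_fastq(path: Path, seqs, qual_char: str = "I") -> Path:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{qual_char * len(s)}\n")
    return path


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
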