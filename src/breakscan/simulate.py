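"""Desk-scale synthetic benchmark: reference, implanted variants, reads.

Emulates the construction of a two-group (normal vs. mutated) short-read
benchmark: a random reference sequence stands in for a real chromosome,
a configurable mix of SNVs, indels and inversions is implanted with
bounded spacing between neighbouring variants (default 25-50 bp), and
paired-end reads are drawn with the classic Illumina-like geometry —
50 bp reads from fragments of length Normal(200, 10) — at a configurable
fold-coverage.  Sequencing noise is a uniform per-base substitution rate
(default 0.001); the caller never consults base qualities, so an
empirical quality profile would add nothing that this benchmark tests.

Everything is deterministic under the configured seed, and the truth
table is written alongside the reads so predictions can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .read_store import reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
INVERSION = "inversion"


@dataclass(frozen=True)
class TruthRecord:
    """One implanted variant in normal-reference coordinates.

    ``pos`` is 1-based: the substituted base (SNV), the first deleted or
    inverted base, or the first reference base *after* an insertion.
    ``spacing`` is the distance to the previous variant's position.
    """

    vtype: str
    contig: str
    pos: int
    normal_allele: str
    mutated_allele: str
    spacing: int = 0

    @property
    def length(self) -> int:
        return max(len(self.normal_allele), len(self.mutated_allele))


@dataclass
class SimParams:
    """Benchmark-generation settings (defaults are the study conditions)."""

    ref_length: int = 100_000
    gc_fraction: float = 0.5
    n_snv: int = 100
    n_ins: int = 15
    n_del: int = 15
    n_inv: int = 0
    indel_size_min: int = 1
    indel_size_max: int = 10
    inversion_size: int = 8
    spacing_min: int = 25
    spacing_max: int = 50
    read_length: int = 50
    fragment_mean: float = 200.0
    fragment_sd: float = 10.0
    coverage: float = 30.0
    error_rate: float = 0.001
    paired: bool = True
    zygosity: str = "pure"  # or "heterozygous"
    contig: str = "chr_sim"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.ref_length < 1000:
            raise ValueError("ref_length must be >= 1000")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if min(self.n_snv, self.n_ins, self.n_del, self.n_inv) < 0:
            raise ValueError("variant counts must be >= 0")
        if self.zygosity not in ("pure", "heterozygous"):
            raise ValueError("zygosity must be 'pure' or 'heterozygous'")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


# ---------------------------------------------------------------------------
# reference and variants


def make_reference(length: int, gc_fraction: float = 0.5, *, seed: int = 1) -> str:
    """Random i.i.d. ACGT sequence with the requested GC content."""
    if length < 1:
        raise ValueError("reference length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    rng = _rng(seed, 0)
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return _BASES[codes].tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n).astype(np.uint8)].tobytes().decode()


def implant_variants(reference: str, params: SimParams) -> tuple[str, list[TruthRecord]]:
    """Place the configured variant mix along the reference and apply it.

    Successive variant positions are ``spacing`` apart with ``spacing``
    drawn uniformly from the configured bounds (measured between variant
    start positions, and never smaller than the previous variant's
    footprint so events cannot overlap).  Raises if the variants do not
    fit on the reference.
    """
    rng = _rng(params.seed, 1)
    kinds = (
        [SNV] * params.n_snv
        + [INSERTION] * params.n_ins
        + [DELETION] * params.n_del
        + [INVERSION] * params.n_inv
    )
    if not kinds:
        return reference, []
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]

    records: list[TruthRecord] = []
    margin = 200  # keep variants away from the contig ends
    pos = margin + int(rng.integers(0, params.spacing_max))
    prev_pos = 0
    prev_footprint = 0
    for kind in kinds:
        spacing = int(rng.integers(params.spacing_min, params.spacing_max + 1))
        if records:
            pos = prev_pos + max(spacing, prev_footprint + 1)
        if kind == SNV:
            size = 1
        elif kind == INVERSION:
            size = params.inversion_size
        else:
            size = int(rng.integers(params.indel_size_min, params.indel_size_max + 1))
        if pos + size + margin > len(reference):
            raise ValueError(
                f"cannot fit {len(kinds)} variants with spacing "
                f"{params.spacing_min}-{params.spacing_max} on a "
                f"{len(reference)} bp reference; use fewer variants or a longer reference"
            )
        p0 = pos - 1  # 0-based
        if kind == SNV:
            ref_base = reference[p0]
            alt = "ACGT".replace(ref_base, "")[int(rng.integers(0, 3))]
            rec = TruthRecord(SNV, params.contig, pos, ref_base, alt)
        elif kind == DELETION:
            rec = TruthRecord(DELETION, params.contig, pos, reference[p0 : p0 + size], "")
        elif kind == INSERTION:
            rec = TruthRecord(INSERTION, params.contig, pos, "", _random_seq(rng, size))
        else:
            seg = reference[p0 : p0 + size]
            rc = reverse_complement(seg)
            if rc == seg:  # a palindromic segment would be a silent event
                pos += 1
                p0 += 1
                seg = reference[p0 : p0 + size]
                rc = reverse_complement(seg)
            rec = TruthRecord(INVERSION, params.contig, pos, seg, rc)
        records.append(dataclasses.replace(rec, spacing=pos - prev_pos))
        prev_pos = pos
        prev_footprint = size if kind != INSERTION else 0
    mutated = apply_truth(reference, records)
    return mutated, records


def apply_truth(reference: str, records: Sequence[TruthRecord]) -> str:
    """Reconstruct the mutated haplotype from a truth table (the
    reconstruction oracle: implantation must be reproducible from its
    own records)."""
    out: list[str] = []
    cursor = 0
    for rec in sorted(records, key=lambda r: r.pos):
        p0 = rec.pos - 1
        if p0 < cursor:
            raise ValueError(f"overlapping truth records near position {rec.pos}")
        out.append(reference[cursor:p0])
        if rec.vtype == SNV:
            out.append(rec.mutated_allele)
            cursor = p0 + 1
        elif rec.vtype == DELETION:
            cursor = p0 + len(rec.normal_allele)
        elif rec.vtype == INSERTION:
            out.append(rec.mutated_allele)
            cursor = p0
        elif rec.vtype == INVERSION:
            out.append(rec.mutated_allele)
            cursor = p0 + len(rec.normal_allele)
        else:
            raise ValueError(f"unknown truth vtype {rec.vtype!r}")
    out.append(reference[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# read simulation


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _add_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    shift = rng.integers(1, 4, size=reads.shape).astype(np.uint8)
    return np.where(mask, (reads + shift) % 4, reads)


def simulate_reads(
    haplotypes: str | tuple[str, str],
    params: SimParams,
    group_label: str,
    out_dir: str | Path,
    *,
    stream: int | None = None,
) -> list[Path]:
    """Draw reads and write FASTQ file(s); returns the written paths.

    ``haplotypes`` is a single haplotype (every fragment comes from it)
    or a pair, from which each fragment picks uniformly — the
    heterozygous case, where the mutated group ideally carries 50% of
    each variant.  Paired mode writes ``<group>_R1/_R2.fastq`` with mate
    2 being the reverse complement of the fragment's far end; fragments
    come from either strand (non-strand-specific).  The fragment count is
    ``ref_length * coverage / (2 * read_length)`` so total sequenced
    bases hit the requested coverage exactly.
    """
    if params.coverage <= 0:
        raise ValueError("coverage must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    haps = (haplotypes,) if isinstance(haplotypes, str) else tuple(haplotypes)
    hap_codes = [_seq_to_codes(h) for h in haps]
    rl = params.read_length
    if stream is None:
        stream = {"normal": 10, "mutated": 11}.get(group_label, 12)
    rng = _rng(params.seed, stream)

    base_len = len(haps[0])
    if params.paired:
        n_frag = int(round(base_len * params.coverage / (2 * rl)))
    else:
        n_frag = int(round(base_len * params.coverage / rl))

    hap_idx = (
        rng.integers(0, len(haps), size=n_frag)
        if len(haps) > 1
        else np.zeros(n_frag, dtype=np.int64)
    )
    if params.paired:
        frag_len = np.clip(
            np.rint(rng.normal(params.fragment_mean, params.fragment_sd, size=n_frag)),
            rl,
            None,
        ).astype(np.int64)
    else:
        frag_len = np.full(n_frag, rl, dtype=np.int64)
    flip = rng.random(n_frag) < 0.5  # fragment strand

    # vectorize per haplotype (fragment extraction needs a fixed source)
    inv_r1 = np.empty((n_frag, rl), dtype=np.uint8)
    inv_r2 = np.empty((n_frag, rl), dtype=np.uint8) if params.paired else None
    for h, codes in enumerate(hap_codes):
        sel = np.nonzero(hap_idx == h)[0]
        if not len(sel):
            continue
        fl = np.minimum(frag_len[sel], len(codes))
        start = (rng.random(len(sel)) * (len(codes) - fl + 1)).astype(np.int64)
        cols = np.arange(rl)
        fwd = codes[start[:, None] + cols]  # fragment head, forward strand
        tail = codes[(start + fl - rl)[:, None] + cols]
        rev = _COMP[tail[:, ::-1]]  # rc of fragment end
        fl_flip = flip[sel]
        # minus-strand fragments read the rc of the far end first
        inv_r1[sel] = np.where(fl_flip[:, None], rev, fwd)
        if params.paired:
            inv_r2[sel] = np.where(fl_flip[:, None], fwd, rev)

    inv_r1 = _add_errors(inv_r1, params.error_rate, rng)
    if params.paired:
        inv_r2 = _add_errors(inv_r2, params.error_rate, rng)

    qual = "I" * rl
    paths: list[Path] = []

    def write(path: Path, mat: np.ndarray, mate: int) -> None:
        with open(path, "w") as fh:
            txt = _BASES[mat]
            for i in range(mat.shape[0]):
                fh.write(
                    f"@{group_label}_frag{i}/{mate}\n"
                    f"{txt[i].tobytes().decode('ascii')}\n+\n{qual}\n"
                )
        paths.append(path)

    if params.paired:
        write(out_dir / f"{group_label}_R1.fastq", inv_r1, 1)
        write(out_dir / f"{group_label}_R2.fastq", inv_r2, 2)
    else:
        write(out_dir / f"{group_label}.fastq", inv_r1, 1)
    logger.info(
        "%s group: %d %s written",
        group_label,
        n_frag,
        "pairs" if params.paired else "reads",
    )
    return paths


# ---------------------------------------------------------------------------
# file plumbing and end-to-end benchmark construction


def write_fasta(path: str | Path, contig: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


_TRUTH_COLUMNS = ["vtype", "contig", "pos", "normal_allele", "mutated_allele", "spacing"]


def write_truth(path: str | Path, records: Sequence[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.vtype}\t{r.contig}\t{r.pos}\t{r.normal_allele or '.'}\t"
                f"{r.mutated_allele or '.'}\t{r.spacing}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-table header in {path}")
        for line in fh:
            vtype, contig, pos, na, ma, spacing = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    vtype=vtype,
                    contig=contig,
                    pos=int(pos),
                    normal_allele="" if na == "." else na,
                    mutated_allele="" if ma == "." else ma,
                    spacing=int(spacing),
                )
            )
    return records


@dataclass(frozen=True)
class BenchmarkFiles:
    reference: Path
    truth: Path
    normal: list[Path]
    mutated: list[Path]
    manifest: Path


def simulate_benchmark(params: SimParams, out_dir: str | Path) -> BenchmarkFiles:
    """Generate a complete benchmark: reference FASTA, truth table TSV,
    normal/mutated FASTQ group(s) and a JSON manifest of every parameter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(
        params.ref_length, params.gc_fraction, seed=params.seed
    )
    mutated_hap, truth = implant_variants(reference, params)

    ref_path = out_dir / "reference.fa"
    write_fasta(ref_path, params.contig, reference)
    truth_path = out_dir / "truth.tsv"
    write_truth(truth_path, truth)

    normal_paths = simulate_reads(reference, params, "normal", out_dir)
    mut_input: str | tuple[str, str]
    if params.zygosity == "heterozygous":
        mut_input = (reference, mutated_hap)
    else:
        mut_input = mutated_hap
    mutated_paths = simulate_reads(mut_input, params, "mutated", out_dir)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(
            {"tool": "breakscan simulate", "params": dataclasses.asdict(params)},
            fh,
            indent=2,
        )
        fh.write("\n")
    return BenchmarkFiles(
        reference=ref_path,
        truth=truth_path,
        normal=normal_paths,
        mutated=mutated_paths,
        manifest=manifest_path,
    )
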