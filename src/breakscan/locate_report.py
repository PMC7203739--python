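"""Call export (TSV/FASTA/VCF) and reference coordinates by exact match.

The caller itself is reference-free; coordinates are an optional
afterstep.  Each call's consensus *normal* sequence is searched as an
exact substring of a reference (both strands).  A unique hit fixes the
contig, the 1-based position of the event, and forward-strand alleles; a
repeated consensus is flagged ambiguous, a non-matching one unmapped.
The consensus FASTA export serves as the escape hatch for mapping with
an external aligner instead.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .consensus_typing import (
    DELETION,
    INSERTION,
    SNV,
    ConsensusPair,
    VariantCall,
    VariantComponent,
)
from .read_store import reverse_complement

logger = logging.getLogger(__name__)

LOCATED = "located"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class LocatedComponent:
    vtype: str
    pos: int  # 1-based on the reference, forward strand
    normal_allele: str
    mutated_allele: str


@dataclass
class Location:
    """Reference placement of a call (alleles re-oriented to the forward
    strand when the consensus matched the reverse strand)."""

    status: str
    contig: str | None = None
    pos: int | None = None  # 1-based position of the event (see TruthRecord)
    strand: str | None = None
    ref_normal_allele: str = ""
    ref_mutated_allele: str = ""
    anchor_base: str | None = None  # reference base just before the event
    components: list[LocatedComponent] = field(default_factory=list)


@dataclass
class CallReport:
    """Ordered variant calls plus the run metadata that produced them."""

    calls: list[VariantCall]
    params: dict = field(default_factory=dict)

    def sort(self) -> None:
        def key(c: VariantCall):
            loc = c.location
            if loc is not None and loc.status == LOCATED:
                return (0, loc.contig, loc.pos, c.cluster_id)
            return (1, "", 0, c.cluster_id)

        self.calls.sort(key=key)


# ---------------------------------------------------------------------------
# FASTA


def export_consensus_fasta(report: CallReport, path: str | Path) -> None:
    """One record per call: header ``cluster_id|vtype|breakpoint_col``,
    sequence = the consensus normal sequence (mappable externally)."""
    if not report.calls:
        logger.warning("exporting an empty report to %s", path)
    with open(path, "w") as fh:
        for call in report.calls:
            fh.write(
                f">{call.cluster_id}|{call.vtype}|{call.breakpoint_col}\n"
                f"{call.consensus.normal}\n"
            )


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference (plain or gzip) into {contig: sequence}."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# exact-match locating


def _find_all(hay: str, needle: str) -> list[int]:
    hits = []
    h = hay.find(needle)
    while h != -1:
        hits.append(h)
        h = hay.find(needle, h + 1)
    return hits


def _event_glen(call: VariantCall) -> int:
    return len(call.normal_allele)


def locate_by_exact_match(
    report: CallReport, reference: str | Path | dict[str, str]
) -> CallReport:
    """Assign (contig, 1-based position) to every call whose consensus
    normal sequence occurs exactly once in the reference (either strand)."""
    ref = reference if isinstance(reference, dict) else load_reference(reference)
    for call in report.calls:
        s = call.consensus.normal
        hits: list[tuple[str, int, str]] = []
        for contig, seq in ref.items():
            hits += [(contig, h, "+") for h in _find_all(seq, s)]
            rc = reverse_complement(s)
            if rc != s:
                hits += [(contig, h, "-") for h in _find_all(seq, rc)]
        if not hits:
            call.location = Location(status=UNMAPPED)
            continue
        if len(hits) > 1:
            call.location = Location(status=AMBIGUOUS)
            continue
        contig, h, strand = hits[0]
        n, b = len(s), call.breakpoint_col
        glen = _event_glen(call)
        if strand == "+":
            pos = h + b + 1
            na, ma = call.normal_allele, call.mutated_allele
        else:
            pos = h + n - b - glen + 1
            na = reverse_complement(call.normal_allele)
            ma = reverse_complement(call.mutated_allele)
        comps: list[LocatedComponent] = []
        for comp in call.components:
            cg = len(comp.normal_allele)
            if strand == "+":
                cpos = h + comp.col + 1
                cna, cma = comp.normal_allele, comp.mutated_allele
            else:
                cpos = h + n - comp.col - cg + 1
                cna = reverse_complement(comp.normal_allele)
                cma = reverse_complement(comp.mutated_allele)
            comps.append(LocatedComponent(comp.vtype, cpos, cna, cma))
        comps.sort(key=lambda c: c.pos)
        anchor = ref[contig][pos - 2] if pos >= 2 else None
        call.location = Location(
            status=LOCATED,
            contig=contig,
            pos=pos,
            strand=strand,
            ref_normal_allele=na,
            ref_mutated_allele=ma,
            anchor_base=anchor,
            components=comps,
        )
    report.sort()
    return report


# ---------------------------------------------------------------------------
# TSV


_TSV_COLUMNS = [
    "cluster_id",
    "vtype",
    "normal_allele",
    "mutated_allele",
    "length",
    "n_norm",
    "n_mut",
    "q",
    "breakpoint_col",
    "contig",
    "pos",
    "status",
    "normal_consensus",
    "mutated_consensus",
    "components",
]


def _fmt_components(loc: Location | None, call: VariantCall) -> str:
    if loc is not None and loc.status == LOCATED and loc.components:
        return ";".join(
            f"{c.vtype}:{c.pos}:{c.normal_allele or '.'}:{c.mutated_allele or '.'}"
            for c in loc.components
        )
    if call.components:
        return ";".join(
            f"{c.vtype}@{c.col}:{c.normal_allele or '.'}:{c.mutated_allele or '.'}"
            for c in call.components
        )
    return "."


def write_calls_tsv(report: CallReport, path: str | Path) -> None:
    report.sort()
    rows = []
    for call in report.calls:
        loc = call.location
        located = loc is not None and loc.status == LOCATED
        rows.append(
            {
                "cluster_id": call.cluster_id,
                "vtype": call.vtype,
                "normal_allele": (loc.ref_normal_allele if located else call.normal_allele) or ".",
                "mutated_allele": (loc.ref_mutated_allele if located else call.mutated_allele) or ".",
                "length": call.length,
                "n_norm": call.n_normal,
                "n_mut": call.n_mutated,
                "q": f"{call.q:.6g}",
                "breakpoint_col": call.breakpoint_col,
                "contig": loc.contig if located else ".",
                "pos": loc.pos if located else 0,
                "status": loc.status if loc is not None else "unlocated",
                "normal_consensus": call.consensus.normal,
                "mutated_consensus": call.consensus.mutated,
                "components": _fmt_components(loc, call),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def report_from_tsv(path: str | Path) -> CallReport:
    """Rebuild a (re-locatable) report from a calls TSV.

    Consensus sequences, breakpoint columns and consensus-coordinate
    components survive the TSV round trip, so a report written before
    locating can be located afterwards.  Reference-oriented fields of
    already-located rows are recomputed on the next locate run.
    """
    df = read_calls_tsv(path)
    calls: list[VariantCall] = []
    for row in df.itertuples(index=False):
        comps: list[VariantComponent] = []
        if row.components not in (".", "") and "@" in row.components:
            for token in row.components.split(";"):
                head, na, ma = token.rsplit(":", 2)
                vtype, col = head.split("@")
                comps.append(
                    VariantComponent(
                        vtype,
                        int(col),
                        "" if na == "." else na,
                        "" if ma == "." else ma,
                    )
                )
        calls.append(
            VariantCall(
                vtype=row.vtype,
                normal_allele="" if row.normal_allele == "." else row.normal_allele,
                mutated_allele="" if row.mutated_allele == "." else row.mutated_allele,
                length=int(row.length),
                consensus=ConsensusPair(
                    normal=row.normal_consensus,
                    mutated=row.mutated_consensus,
                    breakpoint_col=int(row.breakpoint_col),
                ),
                components=comps,
                cluster_id=int(row.cluster_id),
                n_normal=int(row.n_norm),
                n_mutated=int(row.n_mut),
                q=float(row.q),
            )
        )
    return CallReport(calls=calls)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"contig": str, "normal_allele": str, "mutated_allele": str, "components": str},
        keep_default_na=False,
    )
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call TSV {path} lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# VCF


def write_calls_vcf(report: CallReport, path: str | Path) -> None:
    """VCF 4.2 with left-anchored indels (REF carries the base before the
    event).  Only located calls can be represented; raises otherwise."""
    report.sort()
    located = [
        c
        for c in report.calls
        if c.location is not None and c.location.status == LOCATED
    ]
    if report.calls and not located:
        raise ValueError("VCF output requires located calls; run locate first")
    contigs = sorted({c.location.contig for c in located})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breakscan\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">\n'
            '##INFO=<ID=SUPPORT,Number=2,Type=Integer,Description="Supporting reads (normal,mutated)">\n'
            '##INFO=<ID=VF,Number=1,Type=Float,Description="Variant fraction in the mutated group">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in located:
            loc = call.location
            if call.vtype == SNV:
                pos, ref, alt = loc.pos, loc.ref_normal_allele, loc.ref_mutated_allele
            elif call.vtype in (INSERTION, DELETION):
                if loc.anchor_base is None:
                    logger.warning(
                        "cluster %d: indel at contig start cannot be left-anchored; skipped",
                        call.cluster_id,
                    )
                    continue
                pos = loc.pos - 1
                ref = loc.anchor_base + loc.ref_normal_allele
                alt = loc.anchor_base + loc.ref_mutated_allele
            else:  # inversion, complex, unassigned: full-window replacement
                pos, ref, alt = loc.pos, loc.ref_normal_allele, loc.ref_mutated_allele
                if not ref or not alt:
                    continue
            info = (
                f"SVTYPE={call.vtype.upper()};"
                f"SUPPORT={call.n_normal},{call.n_mutated};VF={call.q:.4g}"
            )
            fh.write(
                f"{loc.contig}\t{pos}\tcluster{call.cluster_id}\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )


def write_calls(
    report: CallReport, path: str | Path, format: str = "tsv"
) -> None:
    if format == "tsv":
        write_calls_tsv(report, path)
    elif format == "vcf":
        write_calls_vcf(report, path)
    else:
        raise ValueError(f"unknown call format {format!r} (expected 'tsv' or 'vcf')")
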