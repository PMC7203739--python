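"""Consensus building and variant typing from breakpoint clusters.

Each accepted cluster yields a pair of consensus sequences — one per
sample group — anchored on the shared d-mer and extended column by
column by strict majority vote.  The pair diverges at a single known
column (the breakpoint), and the variant type is read off by comparing
the two sequences in a fixed order: indel, then SNV, then inversion,
then complex; anything else stays unassigned.

For non-strand-specific libraries every breakpoint is discovered twice,
once per strand; strand-mirrored calls are recognized through shared
breakpoint-spanning substrings (default 15 bp) and merged, and a merged
pair of unassigned calls gets one more chance at typing after its two
consensus pairs are stitched into longer sequences.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import edlib

from .cluster_filter import (
    BreakpointCluster,
    RecoveredRead,
    majority_base,
)
from .read_store import MUTATED, NORMAL, reverse_complement

logger = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
INVERSION = "inversion"
COMPLEX = "complex"
UNASSIGNED = "unassigned"


class ConsensusError(ValueError):
    """The cluster cannot produce a usable consensus pair."""


@dataclass(frozen=True)
class ConsensusPair:
    """Normal/mutated consensus sequences sharing their first
    ``breakpoint_col`` bases and differing there if both extend past it."""

    normal: str
    mutated: str
    breakpoint_col: int

    def __post_init__(self) -> None:
        b = self.breakpoint_col
        if self.normal[:b] != self.mutated[:b]:
            raise ValueError("consensus pair flanks differ left of the breakpoint")

    @property
    def right_extent_normal(self) -> int:
        return len(self.normal) - self.breakpoint_col

    @property
    def right_extent_mutated(self) -> int:
        return len(self.mutated) - self.breakpoint_col


@dataclass(frozen=True)
class VariantComponent:
    """One element of a decomposed complex call.

    ``col`` is the 0-based column in the *normal* consensus where the
    component applies (for an insertion, the first normal base after it).
    """

    vtype: str
    col: int
    normal_allele: str
    mutated_allele: str


@dataclass
class VariantCall:
    """A typed breakpoint with its consensus pair and support."""

    vtype: str
    normal_allele: str
    mutated_allele: str
    length: int
    consensus: ConsensusPair
    components: list[VariantComponent] = field(default_factory=list)
    cluster_id: int = -1
    anchor: str = ""
    n_normal: int = 0
    n_mutated: int = 0
    q: float = float("nan")
    merged_from: tuple[int, ...] = ()
    #: consensus pair of the strand-mirrored partner cluster, already
    #: reoriented into this call's orientation (set by the merge step for
    #: unassigned/unassigned pairs; consumed by reinfer_unassigned)
    partner_pair: ConsensusPair | None = None
    location: object | None = None

    @property
    def breakpoint_col(self) -> int:
        return self.consensus.breakpoint_col


# ---------------------------------------------------------------------------
# Step 1: merging clusters that indicate the identical breakpoint


def merge_identical_breakpoints(
    clusters: list[BreakpointCluster],
) -> list[BreakpointCluster]:
    """Union clusters whose left-of-breakpoint anchors are identical over
    their common length; member reads are deduplicated downstream when
    the merged cluster is re-recovered.  Idempotent."""
    by_key: dict[str, list[BreakpointCluster]] = defaultdict(list)
    for c in clusters:
        by_key[c.anchor].append(c)
    # anchors of unequal length: treat an anchor as matching another if one
    # is a suffix of the other (the shared bases immediately left of the
    # breakpoint); with a single d this never triggers.
    merged: list[BreakpointCluster] = []
    for anchor in sorted(by_key):
        group = by_key[anchor]
        if len(group) == 1:
            merged.append(group[0])
            continue
        members = [m for c in group for m in c.members]
        merged.append(
            BreakpointCluster(
                anchor=anchor,
                d=group[0].d,
                partition_prefix=group[0].partition_prefix,
                members=members,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Step 2: consensus by majority voting


def _vote_direction(
    reads: list[RecoveredRead], direction: int, min_cov: int
) -> str:
    """Extend from the divergence column (direction=+1 includes it) or
    leftward from the anchor (direction=-1), one column at a time; halt
    at the first column lacking >=min_cov coverage or a strict majority.

    Returns the consensus text in left-to-right order (for direction=-1
    the returned text is the flank ending just left of column 0).
    """
    out: list[str] = []
    j = 0 if direction > 0 else -1
    while True:
        votes: Counter = Counter()
        for r in reads:
            pos = r.breakpoint_col + j
            if 0 <= pos < len(r.text):
                votes[r.text[pos]] += 1
        total = sum(votes.values())
        if total < min_cov:
            break
        base, top = votes.most_common(1)[0]
        if top * 2 <= total:  # tie or no strict majority: undecidable
            break
        # deterministic tie handling is moot (strict majority is unique)
        out.append(base)
        j += direction
    if direction < 0:
        out.reverse()
    return "".join(out)


def build_consensus(cluster: BreakpointCluster, *, min_cov: int = 2) -> ConsensusPair:
    """Majority-vote consensus pair for a recovered, filtered cluster.

    The normal group's whole read set votes.  For the mutated group only
    the variant subpopulation votes — reads whose divergence-column base
    differs from the normal majority — because in a heterozygous sample
    roughly half the mutated group carries the reference allele and
    would otherwise vote the consensus back to reference.

    Raises
    ------
    ConsensusError
        If either voting population has fewer than ``min_cov`` reads
        covering the divergence column, or that column itself has no
        strict majority.
    """
    if not cluster.recovered:
        raise ConsensusError("cluster must be recovered first")
    ref_base = majority_base(cluster.divergence_bases[NORMAL])
    normal_voters = cluster.normal_reads
    mutated_voters = [
        r
        for r in cluster.mutated_reads
        if r.divergence_base is not None and r.divergence_base != ref_base
    ]
    for label, voters in ((NORMAL, normal_voters), (MUTATED, mutated_voters)):
        covering = sum(1 for r in voters if r.divergence_base is not None)
        if covering < min_cov:
            raise ConsensusError(
                f"only {covering} {label} reads cover the divergence column"
            )

    right_n = _vote_direction(normal_voters, +1, min_cov)
    right_m = _vote_direction(mutated_voters, +1, min_cov)
    if not right_n or not right_m:
        raise ConsensusError("divergence column undecidable by strict majority")
    left_n = _vote_direction(normal_voters, -1, min_cov)
    left_m = _vote_direction(mutated_voters, -1, min_cov)

    return _make_pair(left_n, right_n, left_m, right_m)


def _make_pair(left_n: str, right_n: str, left_m: str, right_m: str) -> ConsensusPair:
    """Trim the two left flanks to their longest common suffix so both
    sequences share exactly ``breakpoint_col`` leading bases."""
    common = min(len(left_n), len(left_m))
    agree = 0
    while agree < common and left_n[len(left_n) - 1 - agree] == left_m[len(left_m) - 1 - agree]:
        agree += 1
    flank = left_n[len(left_n) - agree :] if agree else ""
    return ConsensusPair(
        normal=flank + right_n, mutated=flank + right_m, breakpoint_col=agree
    )


# ---------------------------------------------------------------------------
# Step 3: typing


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            ops.append((int(n), ch))
            n = ""
    return ops


def _decompose_complex(
    a: str, b: str, offset: int, max_edit_runs: int, m: int
) -> tuple[list[VariantComponent], int] | None:
    """Global unit-cost alignment of normal window ``a`` vs mutated window
    ``b``; returns (components, edit span in normal coords) when the edit
    script has 1..max_edit_runs runs of non-match operations and is
    confirmed by a trailing run of >= m matching bases, else None.

    The trailing-match requirement mirrors the m-base confirmation of the
    simple types: without it, a window too short for a legitimate indel or
    inversion test realigns as a shifted edit script that ends in an
    artefactual edit at the window edge and would decompose into spurious
    components.

    ``offset`` shifts component columns into full-consensus coordinates.
    """
    res = edlib.align(b, a, mode="NW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return None
    ops = _parse_cigar(cigar)
    runs = 0
    prev_match = True
    for _n, op in ops:
        is_match = op == "="
        if not is_match and prev_match:
            runs += 1
        prev_match = is_match
    if runs == 0 or runs > max_edit_runs:
        return None
    if ops[-1][1] != "=" or ops[-1][0] < m:
        return None
    components: list[VariantComponent] = []
    i = j = 0  # i walks a (normal), j walks b (mutated)
    last_edit_end = 0
    for n, op in ops:
        if op == "=":
            i += n
            j += n
        elif op == "X":
            for t in range(n):
                components.append(
                    VariantComponent(SNV, offset + i + t, a[i + t], b[j + t])
                )
            i += n
            j += n
            last_edit_end = i
        elif op == "D":
            # query=b is missing n bases present in target=a: deletion
            components.append(
                VariantComponent(DELETION, offset + i, a[i : i + n], "")
            )
            i += n
            last_edit_end = i
        elif op == "I":
            components.append(
                VariantComponent(INSERTION, offset + i, "", b[j : j + n])
            )
            j += n
            last_edit_end = i
        else:  # pragma: no cover - edlib emits only =, X, I, D
            return None
    return components, last_edit_end


def classify_variant(
    pair: ConsensusPair,
    m: int = 10,
    gmax: int | None = None,
    *,
    max_edit_runs: int = 5,
) -> VariantCall:
    """Infer the variant type of a consensus pair.

    Candidate types are tested in the fixed order indel -> SNV ->
    inversion -> complex; the first test that succeeds wins, and a pair
    that fits nothing is left unassigned.  ``m`` is the number of bases
    past the event that must match exactly to confirm indel/inversion
    calls (the SNV confirmation window is ``m`` truncated to the
    available extent, at least one base).  Indels and inversions report
    the smallest size that fits; an exact tie between an insertion and a
    deletion of the same size is reported as the deletion.
    """
    b = pair.breakpoint_col
    nc, mc = pair.normal, pair.mutated
    rn, rm = len(nc) - b, len(mc) - b

    def call(vtype, na, ma, length, comps=()):
        return VariantCall(
            vtype=vtype,
            normal_allele=na,
            mutated_allele=ma,
            length=length,
            consensus=pair,
            components=list(comps),
        )

    if rn <= 0 and rm <= 0:
        return call(UNASSIGNED, "", "", 0)

    # 1. indel: excising g bases from one side realigns the next m bases
    g_del_max = len(nc) - b - m
    g_ins_max = len(mc) - b - m
    hi = min(gmax, max(g_del_max, g_ins_max)) if gmax else max(g_del_max, g_ins_max)
    for g in range(1, max(hi, 0) + 1):
        if g <= g_del_max and b + m <= len(mc) and nc[b + g : b + g + m] == mc[b : b + m]:
            return call(DELETION, nc[b : b + g], "", g)
        if g <= g_ins_max and b + m <= len(nc) and mc[b + g : b + g + m] == nc[b : b + m]:
            return call(INSERTION, "", mc[b : b + g], g)

    # 2. SNV: one substituted base, downstream context intact
    if rn >= 1 and rm >= 1:
        w = min(m, rn - 1, rm - 1)
        if w >= 1 and nc[b] != mc[b] and nc[b + 1 : b + 1 + w] == mc[b + 1 : b + 1 + w]:
            return call(SNV, nc[b], mc[b], 1)

    # 3. inversion: a segment replaced by its reverse complement
    l_max = min(len(nc) - b - m, len(mc) - b - m)
    for l in range(2, max(l_max, 0) + 1):
        if mc[b : b + l] == reverse_complement(nc[b : b + l]) and nc[
            b + l : b + l + m
        ] == mc[b + l : b + l + m]:
            return call(INVERSION, nc[b : b + l], mc[b : b + l], l)

    # 4. complex: short edit script over the shared window
    w = min(rn, rm)
    if w >= 2:
        decomposed = _decompose_complex(nc[b : b + w], mc[b : b + w], b, max_edit_runs, m)
        if decomposed is not None:
            comps, span = decomposed
            return call(
                COMPLEX, nc[b : b + span], mc[b : b + span], span, comps
            )

    return call(UNASSIGNED, "", "", 0)


# ---------------------------------------------------------------------------
# Steps 4-5: strand-mirrored cluster integration and re-inference


def _breakpoint_windows(seq: str, b: int, L: int) -> set[str]:
    """All length-L substrings of ``seq`` that include column ``b``."""
    out: set[str] = set()
    for p in range(max(0, b - L + 1), min(len(seq) - L, b) + 1):
        out.add(seq[p : p + L])
    return out


def merge_reverse_complement_clusters(
    calls: list[VariantCall], L: int = 15, *, strand_specific: bool = False
) -> list[VariantCall]:
    """Merge pairs of calls that describe the same breakpoint seen from
    opposite strands.

    Two calls merge when each one's set of breakpoint-spanning length-L
    normal-consensus substrings contains the reverse complement of a
    member of the other's, and likewise for the mutated consensus.  The
    merged call keeps the orientation of the cluster with the
    lexicographically smaller anchor (or of the typed side, if exactly
    one side was typed), and sums support counts.  In strand-specific
    mode this operation is the identity.
    """
    if strand_specific or len(calls) < 2:
        return list(calls)

    win_n = [_breakpoint_windows(c.consensus.normal, c.breakpoint_col, L) for c in calls]
    win_m = [_breakpoint_windows(c.consensus.mutated, c.breakpoint_col, L) for c in calls]
    rc_n = [{reverse_complement(w) for w in s} for s in win_n]
    rc_m = [{reverse_complement(w) for w in s} for s in win_m]

    parent = list(range(len(calls)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if win_n[i] & rc_n[j] and win_m[i] & rc_m[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(calls)):
        groups[find(i)].append(i)

    out: list[VariantCall] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        idxs = groups[root]
        if len(idxs) == 1:
            out.append(calls[idxs[0]])
            continue
        typed = [i for i in idxs if calls[i].vtype != UNASSIGNED]
        if len(typed) >= 1:
            # prefer a typed orientation; among several, smaller anchor
            canon_i = min(typed, key=lambda i: calls[i].anchor)
        else:
            canon_i = min(idxs, key=lambda i: calls[i].anchor)
        canon = calls[canon_i]
        others = [calls[i] for i in idxs if i != canon_i]
        n_norm = canon.n_normal + sum(c.n_normal for c in others)
        n_mut = canon.n_mutated + sum(c.n_mutated for c in others)
        tot_m = canon.n_mutated + sum(c.n_mutated for c in others)
        q = (
            (canon.q * canon.n_mutated + sum(c.q * c.n_mutated for c in others)) / tot_m
            if tot_m
            else canon.q
        )
        merged = replace(
            canon,
            n_normal=n_norm,
            n_mutated=n_mut,
            q=q,
            merged_from=tuple(sorted(calls[i].cluster_id for i in idxs)),
        )
        if not typed and len(others) == 1:
            # both sides unassigned: keep the partner's pair, reoriented
            # into the canonical orientation, for re-inference
            p = others[0].consensus
            merged.partner_pair = ConsensusPair(
                normal=reverse_complement(p.normal),
                mutated=reverse_complement(p.mutated),
                breakpoint_col=0,
            )
        out.append(merged)
    return out


def _stitch(a: str, b: str, min_overlap: int) -> tuple[str, int] | None:
    """Overlay ``b`` onto ``a`` at the unique maximal exact overlap of at
    least ``min_overlap`` bases; returns (merged text, offset of a's
    origin within it), or None when no or ambiguous placement exists."""
    best_t: int | None = None
    best_len = 0
    ambiguous = False
    for t in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo, hi = max(0, t), min(len(a), t + len(b))
        if hi - lo < min_overlap:
            continue
        if a[lo:hi] == b[lo - t : hi - t]:
            if hi - lo > best_len:
                best_t, best_len, ambiguous = t, hi - lo, False
            elif hi - lo == best_len:
                ambiguous = True
    if best_t is None or ambiguous:
        return None
    t = best_t
    prefix = b[: -t] if t < 0 else ""
    suffix = b[len(a) - t :] if t + len(b) > len(a) else ""
    return prefix + a + suffix, len(prefix)


def reinfer_unassigned(
    call: VariantCall,
    m: int = 10,
    *,
    min_overlap: int = 15,
    max_edit_runs: int = 5,
) -> VariantCall:
    """Retype a merged unassigned call after stitching its two consensus
    pairs into longer sequences.

    The two clusters anchor on opposite sides of the breakpoint, so their
    consensus pairs cover complementary flanks; stitching them on an
    exact overlap extends both extents enough to type events larger than
    a single cluster's reach.  If either the normal or the mutated
    sequences fail to stitch (no consistent overlap, or an ambiguous
    one), the call is returned unchanged.
    """
    if call.vtype != UNASSIGNED or call.partner_pair is None:
        return call
    a, p = call.consensus, call.partner_pair
    sn = _stitch(a.normal, p.normal, min_overlap)
    sm = _stitch(a.mutated, p.mutated, min_overlap)
    if sn is None or sm is None:
        logger.debug("stitching failed for merged cluster %s", call.merged_from)
        return call
    merged_n, off_n = sn
    merged_m, off_m = sm
    b_n = off_n + a.breakpoint_col
    b_m = off_m + a.breakpoint_col
    pair = _make_pair(
        merged_n[:b_n], merged_n[b_n:], merged_m[:b_m], merged_m[b_m:]
    )
    retyped = classify_variant(pair, m=m, max_edit_runs=max_edit_runs)
    if retyped.vtype == UNASSIGNED:
        return call
    return replace(
        call,
        vtype=retyped.vtype,
        normal_allele=retyped.normal_allele,
        mutated_allele=retyped.mutated_allele,
        length=retyped.length,
        consensus=pair,
        components=retyped.components,
        partner_pair=None,
    )
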