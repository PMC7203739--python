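"""Breakpoint-cluster detection in sorted suffix batches, and quality filters.

A breakpoint cluster is a maximal run of lexicographically consecutive
suffixes that share their first ``d`` bases (the *anchor*) while showing
at least two distinct bases at column ``d+1``, with both sample groups
represented.  Divergence is required at exactly column ``d+1``: a
divergence deeper into the suffixes re-appears as the ``d+1`` column of
the cluster anchored correspondingly downstream, so the exact-position
rule avoids duplicate registration of the same breakpoint.

Clusters then pass through the support filters: read-count cutoffs
``cmin``/``cmax`` per group, the variant-fraction window
``[qmin, qmax]`` over the mutated group, and a cap on apparent
contamination of the normal group (mutated-like reads are expected to
make up at most ~5% of a real normal sample).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .read_store import MUTATED, NORMAL, PackedReadStore, reverse_complement
from .suffix_partition import FORWARD, REVERSE, SuffixEngine, SuffixRef

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class RecoveredRead:
    """One full read recovered from a member suffix, oriented to the
    cluster's strand, with the divergence column's position inside it."""

    read_id: int
    group: str
    strand: str
    text: str
    breakpoint_col: int  # 0-based; may equal len(text) for a length-d suffix

    @property
    def divergence_base(self) -> str | None:
        if self.breakpoint_col < len(self.text):
            return self.text[self.breakpoint_col]
        return None


@dataclass
class BreakpointCluster:
    """Suffixes sharing a d-base anchor and diverging at column d+1."""

    anchor: str
    d: int
    partition_prefix: str
    members: list[SuffixRef]
    normal_reads: list[RecoveredRead] = field(default_factory=list)
    mutated_reads: list[RecoveredRead] = field(default_factory=list)
    divergence_bases: dict[str, Counter] = field(default_factory=dict)
    normal_majority_base: str | None = None
    q: float | None = None
    recovered: bool = False

    @property
    def n_normal(self) -> int:
        return len(self.normal_reads)

    @property
    def n_mutated(self) -> int:
        return len(self.mutated_reads)

    def reads(self, group: str) -> list[RecoveredRead]:
        return self.normal_reads if group == NORMAL else self.mutated_reads


@dataclass
class FilterParams:
    """Cluster-level quality cutoffs.

    ``cmin``/``cmax`` bound the per-group read support (``cmax=None``
    disables the upper cutoff); ``qmin``/``qmax`` bound the variant
    fraction of the mutated group (0.9-1.0 for a pure mutated sample,
    0.35-0.6 for a heterozygous one); ``pnorm_max`` caps the fraction of
    normal-group reads carrying a non-majority base at the divergence
    column.
    """

    cmin: int = 6
    cmax: int | None = 28
    qmin: float = 0.9
    qmax: float = 1.0
    pnorm_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.qmin <= self.qmax <= 1:
            raise ValueError(f"need 0 <= qmin <= qmax <= 1, got {self.qmin}, {self.qmax}")
        if self.cmin < 1 or (self.cmax is not None and self.cmax < self.cmin):
            raise ValueError(f"need 1 <= cmin <= cmax, got {self.cmin}, {self.cmax}")
        if not 0 <= self.pnorm_max <= 1:
            raise ValueError("pnorm_max must be a fraction in [0, 1]")

    @classmethod
    def pure(cls, **kw) -> "FilterParams":
        """Preset for a pure (non-heterozygous) mutated sample: q in [0.9, 1.0]."""
        kw.setdefault("qmin", 0.9)
        kw.setdefault("qmax", 1.0)
        return cls(**kw)

    @classmethod
    def heterozygous(cls, **kw) -> "FilterParams":
        """Preset for a heterozygous mutated sample: q in [0.35, 0.6]."""
        kw.setdefault("qmin", 0.35)
        kw.setdefault("qmax", 0.6)
        return cls(**kw)


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# scanning


def scan_clusters(
    sorted_refs: list[SuffixRef],
    d: int,
    normal: PackedReadStore,
    mutated: PackedReadStore,
    *,
    engine: SuffixEngine | None = None,
    partition_prefix: str = "",
) -> list[BreakpointCluster]:
    """One linear pass over a sorted suffix batch, emitting each maximal
    run that shares its first ``d`` bases and satisfies the breakpoint
    conditions: >= 2 distinct bases at column ``d+1`` among members long
    enough to have one, and both groups represented."""
    if engine is None:
        strand_specific = all(r.strand == FORWARD for r in sorted_refs)
        engine = SuffixEngine(normal, mutated, strand_specific=strand_specific)
    clusters: list[BreakpointCluster] = []
    run: list[SuffixRef] = []
    run_anchor: str | None = None

    def flush() -> None:
        if not run:
            return
        div = {engine.ref_suffix_text(r)[d] for r in run if r.suffix_length >= d + 1}
        groups = {r.group for r in run}
        if len(div) >= 2 and groups == {NORMAL, MUTATED}:
            clusters.append(
                BreakpointCluster(
                    anchor=run_anchor,
                    d=d,
                    partition_prefix=partition_prefix,
                    members=list(run),
                )
            )

    for ref in sorted_refs:
        anchor = engine.ref_suffix_text(ref)[:d]
        if anchor != run_anchor:
            flush()
            run = []
            run_anchor = anchor
        run.append(ref)
    flush()
    return clusters


def scan_batch(
    engine: SuffixEngine,
    v: np.ndarray,
    o: np.ndarray,
    d: int,
    partition_prefix: str,
) -> list[BreakpointCluster]:
    """Vectorized equivalent of sort + :func:`scan_clusters` for one
    partition's suffix batch given as parallel arrays."""
    n = len(v)
    if n == 0:
        return []
    order, key = engine.sort_batch(v, o, d + 1)
    v, o = v[order], o[order]
    groups = engine.group[v]
    div = key[:, d]  # 0 means the suffix has length exactly d

    new_run = np.empty(n, dtype=bool)
    new_run[0] = True
    if n > 1:
        new_run[1:] = np.any(key[1:, :d] != key[:-1, :d], axis=1)
    starts = np.nonzero(new_run)[0]

    max_div = np.maximum.reduceat(div, starts)
    min_div = np.minimum.reduceat(np.where(div == 0, np.uint8(99), div), starts)
    g_min = np.minimum.reduceat(groups, starts)
    g_max = np.maximum.reduceat(groups, starts)
    candidate = (max_div > 0) & (min_div != 99) & (max_div != min_div) & (g_min == 0) & (g_max == 1)

    ends = np.append(starts[1:], n)
    clusters: list[BreakpointCluster] = []
    for run_idx in np.nonzero(candidate)[0]:
        s, e = int(starts[run_idx]), int(ends[run_idx])
        anchor = "".join(_BASES[c - 1] for c in key[s, :d])
        members = [engine.make_ref(int(v[i]), int(o[i])) for i in range(s, e)]
        clusters.append(
            BreakpointCluster(
                anchor=anchor, d=d, partition_prefix=partition_prefix, members=members
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# recovery and filters


def recover_reads(
    cluster: BreakpointCluster,
    normal: PackedReadStore,
    mutated: PackedReadStore,
) -> BreakpointCluster:
    """Attach each member's full read, oriented to the member's strand,
    with the in-read divergence column ``offset + d``.

    A read contributing several member suffixes (or several offsets of
    the same repeat) is collapsed to one vote per (read, strand); the
    smallest offset is kept.
    """
    stores = {NORMAL: normal, MUTATED: mutated}
    best: dict[tuple[str, str, int], SuffixRef] = {}
    for ref in cluster.members:
        key = (ref.group, ref.strand, ref.read_id)
        if key not in best or ref.offset < best[key].offset:
            best[key] = ref
    cluster.normal_reads = []
    cluster.mutated_reads = []
    for (group, strand, read_id), ref in sorted(best.items()):
        store = stores[group]
        if not 0 <= read_id < store.n_reads:
            raise RuntimeError(f"dangling read id {read_id} in {group} group")
        text = store.get_read(read_id)
        if strand == REVERSE:
            text = reverse_complement(text)
        rec = RecoveredRead(
            read_id=read_id,
            group=group,
            strand=strand,
            text=text,
            breakpoint_col=ref.offset + cluster.d,
        )
        cluster.reads(group).append(rec)
    cluster.divergence_bases = {
        g: Counter(
            r.divergence_base for r in cluster.reads(g) if r.divergence_base is not None
        )
        for g in (NORMAL, MUTATED)
    }
    cluster.recovered = True
    return cluster


def majority_base(counts: Counter) -> str | None:
    """Most frequent base; ties broken alphabetically for determinism."""
    if not counts:
        return None
    top = max(counts.values())
    return min(b for b, c in counts.items() if c == top)


def variant_fraction(cluster: BreakpointCluster) -> float:
    """Fraction of mutated-group reads carrying a non-reference base at
    the divergence column, among mutated reads that cover that column.

    A member whose suffix has length exactly d ends at the anchor and is
    blind to the divergence column; counting such reads in the
    denominator would dilute q below the acceptance window at genuine
    breakpoints, so the fraction is taken over informative reads only.
    The reference base is the normal group's majority base there.
    """
    if not cluster.recovered:
        raise ValueError("cluster must be recovered before computing q")
    if not cluster.normal_reads:
        raise ValueError("variant fraction needs a non-empty normal group")
    if not cluster.mutated_reads:
        raise ValueError("variant fraction undefined for an empty mutated group")
    ref_base = majority_base(cluster.divergence_bases[NORMAL])
    cluster.normal_majority_base = ref_base
    covering = [r for r in cluster.mutated_reads if r.divergence_base is not None]
    if not covering:
        cluster.q = 0.0
        return cluster.q
    n_variant = sum(1 for r in covering if r.divergence_base != ref_base)
    cluster.q = n_variant / len(covering)
    return cluster.q


def apply_filters(cluster: BreakpointCluster, params: FilterParams) -> FilterDecision:
    """Accept or reject a recovered cluster; the first failing criterion
    (in the fixed order below) is reported as the reason."""
    n_norm, n_mut = cluster.n_normal, cluster.n_mutated
    if min(n_norm, n_mut) < params.cmin:
        return FilterDecision(False, "too_few_reads")
    if params.cmax is not None and max(n_norm, n_mut) > params.cmax:
        return FilterDecision(False, "too_many_reads")
    q = cluster.q if cluster.q is not None else variant_fraction(cluster)
    if not params.qmin <= q <= params.qmax:
        return FilterDecision(False, "q_out_of_range")
    ref_base = cluster.normal_majority_base
    covering = [r for r in cluster.normal_reads if r.divergence_base is not None]
    n_contam = sum(1 for r in covering if r.divergence_base != ref_base)
    if covering and n_contam / len(covering) > params.pnorm_max:
        return FilterDecision(False, "normal_contaminated")
    return FilterDecision(True, None)
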