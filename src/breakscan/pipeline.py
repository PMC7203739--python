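"""End-to-end variant calling: load -> partition -> scan -> filter ->
consensus -> type -> strand merge -> re-infer.

The suffix universe is processed in 4^k prefix partitions, strictly one
at a time: each partition's key material is built, sorted, scanned for
breakpoint clusters and released before the next partition starts, so
peak memory is the packed reads plus a single partition's batch.  The
choice of k does not change the final call set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cluster_filter import (
    BreakpointCluster,
    FilterParams,
    apply_filters,
    recover_reads,
    scan_batch,
    variant_fraction,
)
from .consensus_typing import (
    ConsensusError,
    build_consensus,
    classify_variant,
    merge_identical_breakpoints,
    merge_reverse_complement_clusters,
    reinfer_unassigned,
)
from .locate_report import CallReport
from .read_store import MUTATED, NORMAL, PackedReadStore, load_reads
from .suffix_partition import SuffixEngine, list_prefixes

logger = logging.getLogger(__name__)


@dataclass
class RejectedCluster:
    """Audit entry for a cluster that failed the quality filters."""

    anchor: str
    reason: str
    n_normal: int
    n_mutated: int
    q: float | None


@dataclass
class CallOptions:
    """Tunables of the calling pipeline (defaults: d=30, k=3, pure-mode
    filters, non-strand-specific input)."""

    d: int = 30
    k: int = 3
    filters: FilterParams = field(default_factory=FilterParams.pure)
    strand_specific: bool = False
    m: int = 10  # confirmation bases past an event during typing
    gmax: int | None = None
    rc_window: int = 15  # substring length for strand-mirror merging
    min_cov: int = 2
    max_edit_runs: int = 5

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not 0 <= self.k <= self.d:
            raise ValueError(f"need 0 <= k <= d, got k={self.k}, d={self.d}")


def accepted_clusters(
    normal: PackedReadStore,
    mutated: PackedReadStore,
    options: CallOptions | None = None,
    *,
    audit: list[RejectedCluster] | None = None,
) -> list[BreakpointCluster]:
    """Partition, sort and scan all suffixes; return the recovered
    clusters that survive the quality filters."""
    opt = options or CallOptions()
    engine = SuffixEngine(normal, mutated, strand_specific=opt.strand_specific)
    plan = list_prefixes(opt.k)

    v, o = engine.enumerate_suffixes(opt.d)
    if opt.k > 0:
        pids = engine.prefix_ids(v, o, opt.k)
        order = np.argsort(pids, kind="stable")
        v, o, pids = v[order], o[order], pids[order]
        bounds = np.searchsorted(pids, np.arange(4**opt.k + 1))
        del order
    else:
        bounds = np.array([0, len(v)])

    accepted: list[BreakpointCluster] = []
    for p_idx, prefix in enumerate(plan.prefixes):
        lo, hi = int(bounds[p_idx]), int(bounds[p_idx + 1])
        if lo == hi:
            continue
        clusters = scan_batch(engine, v[lo:hi], o[lo:hi], opt.d, prefix)
        n_ok = 0
        for cluster in clusters:
            recover_reads(cluster, normal, mutated)
            variant_fraction(cluster)
            decision = apply_filters(cluster, opt.filters)
            if decision.accepted:
                accepted.append(cluster)
                n_ok += 1
            elif audit is not None:
                audit.append(
                    RejectedCluster(
                        cluster.anchor,
                        decision.reason,
                        cluster.n_normal,
                        cluster.n_mutated,
                        cluster.q,
                    )
                )
        logger.debug(
            "partition %s: %d suffixes, %d clusters registered, %d accepted",
            prefix or "(all)",
            hi - lo,
            len(clusters),
            n_ok,
        )
        # the partition's suffix batch (keys, order) is released here;
        # only accepted clusters survive
    return accepted


def call_from_stores(
    normal: PackedReadStore,
    mutated: PackedReadStore,
    options: CallOptions | None = None,
    *,
    audit: list[RejectedCluster] | None = None,
) -> CallReport:
    """Run the calling pipeline on two already-loaded read stores."""
    opt = options or CallOptions()
    accepted = accepted_clusters(normal, mutated, opt, audit=audit)
    merged_clusters = merge_identical_breakpoints(accepted)
    for cluster in merged_clusters:
        if not cluster.recovered:
            recover_reads(cluster, normal, mutated)
            variant_fraction(cluster)
    merged_clusters.sort(key=lambda c: c.anchor)

    calls = []
    for cid, cluster in enumerate(merged_clusters):
        try:
            pair = build_consensus(cluster, min_cov=opt.min_cov)
        except ConsensusError as exc:
            logger.info("cluster %s dropped: %s", cluster.anchor, exc)
            continue
        call = classify_variant(
            pair, m=opt.m, gmax=opt.gmax, max_edit_runs=opt.max_edit_runs
        )
        call.cluster_id = cid
        call.anchor = cluster.anchor
        call.n_normal = cluster.n_normal
        call.n_mutated = cluster.n_mutated
        call.q = cluster.q
        calls.append(call)

    if not opt.strand_specific:
        calls = merge_reverse_complement_clusters(calls, opt.rc_window)
        calls = [
            reinfer_unassigned(c, m=opt.m, max_edit_runs=opt.max_edit_runs)
            for c in calls
        ]

    params = {
        "d": opt.d,
        "k": opt.k,
        "cmin": opt.filters.cmin,
        "cmax": opt.filters.cmax,
        "qmin": opt.filters.qmin,
        "qmax": opt.filters.qmax,
        "pnorm_max": opt.filters.pnorm_max,
        "strand_specific": opt.strand_specific,
        "m": opt.m,
        "rc_window": opt.rc_window,
        "n_reads_normal": normal.n_reads,
        "n_reads_mutated": mutated.n_reads,
        "n_dropped_normal": normal.n_dropped,
        "n_dropped_mutated": mutated.n_dropped,
    }
    report = CallReport(calls=calls, params=params)
    report.sort()
    return report


def call_variants(
    normal_paths: Sequence[str | Path] | str | Path,
    mutated_paths: Sequence[str | Path] | str | Path,
    options: CallOptions | None = None,
    *,
    audit: list[RejectedCluster] | None = None,
) -> CallReport:
    """Load normal and mutated FASTQ group(s) and call variants.

    Reads shorter than ``d + 1`` are dropped at load: they cannot reach
    a divergence column.
    """
    opt = options or CallOptions()
    normal = load_reads(normal_paths, NORMAL, min_length=opt.d + 1)
    mutated = load_reads(mutated_paths, MUTATED, min_length=opt.d + 1)
    if normal.n_reads == 0:
        raise ValueError("normal group contains no usable reads")
    if mutated.n_reads == 0:
        raise ValueError("mutated group contains no usable reads")
    return call_from_stores(normal, mutated, opt, audit=audit)
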