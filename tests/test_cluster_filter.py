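"""Breakpoint-cluster scanning, read recovery and quality filters."""

import pytest

from breakscan.cluster_filter import (
    BreakpointCluster,
    FilterParams,
    RecoveredRead,
    apply_filters,
    recover_reads,
    scan_clusters,
    variant_fraction,
)
from breakscan.pipeline import CallOptions, accepted_clusters
from breakscan.suffix_partition import SuffixRef, collect_suffixes, sort_suffix_refs

from conftest import make_stores, random_dna
from oracles import brute_force_clusters


def _scan(normal_seqs, mutated_seqs, d, strand_specific=True):
    normal, mutated = make_stores(normal_seqs, mutated_seqs)
    refs = sort_suffix_refs(
        collect_suffixes(normal, mutated, "", d, strand_specific=strand_specific),
        normal,
        mutated,
    )
    return scan_clusters(refs, d, normal, mutated), normal, mutated


class TestScanClusters:
    # shared 9-mer anchor, groups diverging at column 10 (C vs T)
    NORM = "AAACCCTTTCGATTAGAC"
    MUT = "AAACCCTTTTGATTAGAC"

    def test_single_divergent_cluster(self):
        clusters, normal, mutated = _scan([self.NORM] * 6, [self.MUT] * 6, d=9)
        target = [c for c in clusters if c.anchor == "AAACCCTTT"]
        assert len(target) == 1
        cluster = recover_reads(target[0], normal, mutated)
        assert cluster.divergence_bases["normal"] == {"C": 6}
        assert cluster.divergence_bases["mutated"] == {"T": 6}

    def test_identical_groups_no_cluster(self):
        clusters, *_ = _scan([self.NORM] * 6, [self.NORM] * 6, d=9)
        assert clusters == []

    def test_divergence_within_one_group_only(self):
        # mutated reads share no suffix with the divergent normal run
        other = "GGGGGGGGGGGGGGGGGG"
        norm_b = self.NORM[:9] + "G" + self.NORM[10:]
        clusters, *_ = _scan([self.NORM] * 3 + [norm_b] * 3, [other] * 6, d=9)
        assert clusters == []

    def test_both_groups_required_at_scan_time(self):
        clusters, *_ = _scan([self.NORM] * 6, [], d=9)
        assert clusters == []


class TestRecoverReads:
    def test_forward_breakpoint_column(self):
        normal, mutated = make_stores(["TTAAACCC"], ["TTAAACCC"])
        cluster = BreakpointCluster(
            anchor="AAC",
            d=3,
            partition_prefix="",
            members=[SuffixRef("normal", "forward", 0, 2, 6)],
        )
        recover_reads(cluster, normal, mutated)
        rec = cluster.normal_reads[0]
        assert (rec.text, rec.breakpoint_col) == ("TTAAACCC", 5)

    def test_reverse_strand_orientation(self):
        normal, mutated = make_stores(["GGGTTTAA"], ["GGGTTTAA"])
        cluster = BreakpointCluster(
            anchor="TTA",
            d=3,
            partition_prefix="",
            members=[SuffixRef("normal", "reverse", 0, 0, 8)],
        )
        recover_reads(cluster, normal, mutated)
        rec = cluster.normal_reads[0]
        assert (rec.text, rec.breakpoint_col) == ("TTAAACCC", 3)

    def test_duplicate_read_counted_once(self):
        normal, mutated = make_stores(["AACAACG"], ["AACAACG"])
        cluster = BreakpointCluster(
            anchor="AAC",
            d=3,
            partition_prefix="",
            members=[
                SuffixRef("normal", "forward", 0, 0, 7),
                SuffixRef("normal", "forward", 0, 3, 4),
            ],
        )
        recover_reads(cluster, normal, mutated)
        assert cluster.n_normal == 1
        assert cluster.normal_reads[0].breakpoint_col == 3  # smallest offset


def _recovered_cluster(n_ref, n_alt, normal_n=10, ref_base="C", alt_base="T"):
    """Cluster with synthetic recovered reads: normal carries ref_base at
    the divergence column; n_alt of the mutated reads carry alt_base."""
    text_ref = "AAAA" + ref_base + "GGGG"
    text_alt = "AAAA" + alt_base + "GGGG"
    cluster = BreakpointCluster(anchor="AAAA", d=4, partition_prefix="", members=[])
    cluster.normal_reads = [
        RecoveredRead(i, "normal", "forward", text_ref, 4) for i in range(normal_n)
    ]
    cluster.mutated_reads = [
        RecoveredRead(i, "mutated", "forward", text_alt if i < n_alt else text_ref, 4)
        for i in range(n_ref + n_alt)
    ]
    from collections import Counter

    cluster.divergence_bases = {
        g: Counter(r.divergence_base for r in cluster.reads(g))
        for g in ("normal", "mutated")
    }
    cluster.recovered = True
    return cluster


class TestVariantFraction:
    @pytest.mark.parametrize(
        "n_ref,n_alt,expected", [(0, 10, 1.0), (5, 5, 0.5), (19, 1, 0.05)]
    )
    def test_fraction(self, n_ref, n_alt, expected):
        cluster = _recovered_cluster(n_ref, n_alt)
        assert variant_fraction(cluster) == pytest.approx(expected)

    def test_empty_mutated_group_undefined(self):
        cluster = _recovered_cluster(0, 0)
        cluster.mutated_reads = []
        with pytest.raises(ValueError, match="empty mutated"):
            variant_fraction(cluster)


class TestApplyFilters:
    def test_too_few_reads(self):
        cluster = _recovered_cluster(0, 20, normal_n=5)
        variant_fraction(cluster)
        decision = apply_filters(cluster, FilterParams(cmin=6))
        assert (decision.accepted, decision.reason) == (False, "too_few_reads")

    def test_too_many_reads(self):
        cluster = _recovered_cluster(0, 30, normal_n=30)
        variant_fraction(cluster)
        decision = apply_filters(cluster, FilterParams(cmin=6, cmax=28, qmin=0.9))
        assert (decision.accepted, decision.reason) == (False, "too_many_reads")

    def test_q_window(self):
        cluster = _recovered_cluster(5, 5)  # q = 0.5
        variant_fraction(cluster)
        decision = apply_filters(cluster, FilterParams(qmin=0.9, qmax=1.0))
        assert (decision.accepted, decision.reason) == (False, "q_out_of_range")

    def test_pure_accept(self):
        cluster = _recovered_cluster(0, 10)
        variant_fraction(cluster)
        decision = apply_filters(cluster, FilterParams(cmin=6, qmin=0.9, qmax=1.0))
        assert decision.accepted and decision.reason is None

    def test_contaminated_normal_group(self):
        cluster = _recovered_cluster(0, 10, normal_n=10)
        cluster.normal_reads[0] = RecoveredRead(99, "normal", "forward", "AAAATGGGG", 4)
        from collections import Counter

        cluster.divergence_bases["normal"] = Counter(
            r.divergence_base for r in cluster.normal_reads
        )
        variant_fraction(cluster)
        decision = apply_filters(cluster, FilterParams(cmin=6, pnorm_max=0.05))
        assert (decision.accepted, decision.reason) == (False, "normal_contaminated")

    def test_param_validation(self):
        with pytest.raises(ValueError):
            FilterParams(qmin=0.9, qmax=0.5)
        with pytest.raises(ValueError):
            FilterParams(cmin=10, cmax=5)


def _micro_fixture(rng, n_reads=16, read_len=36, d=12):
    """Tiled error-free reads over a reference with one SNV."""
    ref = random_dna(rng, 120)
    pos = rng.randrange(40, 80)
    alt = rng.choice([b for b in "ACGT" if b != ref[pos]])
    mut = ref[:pos] + alt + ref[pos + 1 :]
    step = max(1, (len(ref) - read_len) // (n_reads // 2))
    normal_seqs = [ref[i : i + read_len] for i in range(0, len(ref) - read_len + 1, step)]
    mutated_seqs = [mut[i : i + read_len] for i in range(0, len(mut) - read_len + 1, step)]
    return normal_seqs[: n_reads // 2], mutated_seqs[: n_reads // 2], d


class TestPipelineAgainstBruteForce:
    def test_oracle_equivalence_micro(self, rng):
        for trial in range(4):
            normal_seqs, mutated_seqs, d = _micro_fixture(rng)
            normal, mutated = make_stores(normal_seqs, mutated_seqs)
            params = FilterParams(cmin=2, cmax=None, qmin=0.8, qmax=1.0)
            for k in (0, 2):
                got = accepted_clusters(
                    normal,
                    mutated,
                    CallOptions(d=d, k=k, filters=params, strand_specific=False),
                )
                got_sigs = {
                    (
                        c.anchor,
                        frozenset(
                            (m.group, m.strand, m.read_id, m.offset) for m in c.members
                        ),
                    )
                    for c in got
                }
                want = brute_force_clusters(
                    normal_seqs,
                    mutated_seqs,
                    d,
                    strand_specific=False,
                    cmin=2,
                    qmin=0.8,
                    qmax=1.0,
                    pnorm_max=0.05,
                )
                assert got_sigs == want

    def test_monotonicity_in_cmin_and_q_window(self, rng):
        normal_seqs, mutated_seqs, d = _micro_fixture(rng, n_reads=20)
        normal, mutated = make_stores(normal_seqs, mutated_seqs)

        def run(cmin, qmin, qmax):
            clusters = accepted_clusters(
                normal,
                mutated,
                CallOptions(
                    d=d,
                    k=1,
                    filters=FilterParams(cmin=cmin, cmax=None, qmin=qmin, qmax=qmax),
                    strand_specific=False,
                ),
            )
            return {c.anchor for c in clusters}

        base = run(2, 0.5, 1.0)
        assert run(4, 0.5, 1.0) <= base  # raising cmin
        assert run(2, 0.8, 1.0) <= base  # narrowing the q window
        assert run(2, 0.5, 0.9) <= base

    def test_determinism(self, rng):
        normal_seqs, mutated_seqs, d = _micro_fixture(rng)
        normal, mutated = make_stores(normal_seqs, mutated_seqs)
        opts = CallOptions(
            d=d, k=2, filters=FilterParams(cmin=2, cmax=None), strand_specific=False
        )
        first = [(c.anchor, tuple(c.members)) for c in accepted_clusters(normal, mutated, opts)]
        second = [(c.anchor, tuple(c.members)) for c in accepted_clusters(normal, mutated, opts)]
        assert first == second
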