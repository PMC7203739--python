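"""Consensus voting, variant typing and strand-mirrored cluster merging."""

import pytest

from breakscan.cluster_filter import BreakpointCluster, RecoveredRead
from breakscan.consensus_typing import (
    COMPLEX,
    DELETION,
    INSERTION,
    INVERSION,
    SNV,
    UNASSIGNED,
    ConsensusError,
    ConsensusPair,
    VariantCall,
    _stitch,
    build_consensus,
    classify_variant,
    merge_identical_breakpoints,
    merge_reverse_complement_clusters,
    reinfer_unassigned,
)
from breakscan.read_store import reverse_complement

from conftest import random_dna
from oracles import column_majority


def _cluster_from_reads(normal_texts, mutated_texts, bp_col, d=4):
    from collections import Counter

    cluster = BreakpointCluster(
        anchor=normal_texts[0][bp_col - d : bp_col], d=d, partition_prefix="", members=[]
    )
    cluster.normal_reads = [
        RecoveredRead(i, "normal", "forward", t, bp_col)
        for i, t in enumerate(normal_texts)
    ]
    cluster.mutated_reads = [
        RecoveredRead(i, "mutated", "forward", t, bp_col)
        for i, t in enumerate(mutated_texts)
    ]
    cluster.divergence_bases = {
        g: Counter(
            r.divergence_base for r in cluster.reads(g) if r.divergence_base is not None
        )
        for g in ("normal", "mutated")
    }
    cluster.recovered = True
    return cluster


class TestMergeIdenticalBreakpoints:
    def _cluster(self, anchor, members=()):
        return BreakpointCluster(
            anchor=anchor, d=len(anchor), partition_prefix="", members=list(members)
        )

    def test_identical_anchors_merge(self):
        from breakscan.suffix_partition import SuffixRef

        m1 = SuffixRef("normal", "forward", 0, 0, 8)
        m2 = SuffixRef("mutated", "forward", 1, 0, 8)
        merged = merge_identical_breakpoints(
            [self._cluster("ACGTACGT", [m1]), self._cluster("ACGTACGT", [m2])]
        )
        assert len(merged) == 1
        assert set(merged[0].members) == {m1, m2}

    def test_different_anchors_kept_apart(self):
        merged = merge_identical_breakpoints(
            [self._cluster("ACGTACGT"), self._cluster("ACGTACGA")]
        )
        assert len(merged) == 2

    def test_idempotent(self):
        clusters = [self._cluster("AAAA"), self._cluster("AAAA"), self._cluster("CCCC")]
        once = merge_identical_breakpoints(clusters)
        twice = merge_identical_breakpoints(once)
        assert [(c.anchor, set(c.members)) for c in twice] == [
            (c.anchor, set(c.members)) for c in once
        ]


class TestBuildConsensus:
    def test_identical_reads_full_length(self):
        text_n = "GGCCAACTGTAG"
        text_m = "GGCCAAGTGTAG"  # diverges at column 6
        cluster = _cluster_from_reads([text_n] * 6, [text_m] * 6, bp_col=6)
        pair = build_consensus(cluster)
        assert (pair.normal, pair.mutated) == (text_n, text_m)
        assert pair.breakpoint_col == 6

    def test_tie_column_halts_extension(self):
        # votes split 3:3 two columns right of the breakpoint
        base_n = "GGCCAACT"
        cluster = _cluster_from_reads(
            [base_n + "A"] * 3 + [base_n + "C"] * 3,
            ["GGCCAAGTA"] * 6,
            bp_col=6,
        )
        pair = build_consensus(cluster)
        assert pair.normal == "GGCCAACT"  # halted before the tied column
        assert pair.mutated == "GGCCAAGTA"

    def test_low_coverage_fails(self):
        cluster = _cluster_from_reads(["GGCCAACT"], ["GGCCAAGT"] * 4, bp_col=6)
        with pytest.raises(ConsensusError):
            build_consensus(cluster)

    def test_variant_subpopulation_defines_mutated_consensus(self):
        # heterozygous-like mutated group: reference reads must not vote
        text_n = "GGCCAACTGT"
        text_m = "GGCCAAGTGT"
        cluster = _cluster_from_reads(
            [text_n] * 6, [text_m] * 5 + [text_n] * 5, bp_col=6
        )
        pair = build_consensus(cluster)
        assert pair.mutated == text_m

    def test_matches_column_majority_oracle_with_seeded_errors(self, rng):
        ref = random_dna(rng, 60)
        alt = "A" if ref[30] != "A" else "C"
        mut = ref[:30] + alt + ref[31:]
        normal_reads, mutated_reads = [], []
        for i in range(20):
            start = rng.randrange(0, 14)
            n = ref[start : start + 40]
            m = mut[start : start + 40]
            if i == 3:  # one seeded error in a normal read, away from col 30
                pos = 5
                n = n[:pos] + ("G" if n[pos] != "G" else "T") + n[pos + 1 :]
            normal_reads.append((n, 30 - start))
            mutated_reads.append((m, 30 - start))
        cluster = _cluster_from_reads([t for t, _ in normal_reads], [], bp_col=0, d=1)
        cluster.normal_reads = [
            RecoveredRead(i, "normal", "forward", t, c)
            for i, (t, c) in enumerate(normal_reads)
        ]
        cluster.mutated_reads = [
            RecoveredRead(i, "mutated", "forward", t, c)
            for i, (t, c) in enumerate(mutated_reads)
        ]
        from collections import Counter

        cluster.divergence_bases = {
            g: Counter(r.divergence_base for r in cluster.reads(g))
            for g in ("normal", "mutated")
        }
        pair = build_consensus(cluster)
        assert pair.normal[pair.breakpoint_col] == ref[30]
        assert pair.mutated[pair.breakpoint_col] == alt
        # every consensus column equals the independent column-vote oracle
        for j in range(-pair.breakpoint_col, len(pair.normal) - pair.breakpoint_col):
            want = column_majority(normal_reads, j)
            assert pair.normal[pair.breakpoint_col + j] == want


def _pair(flank, n_tail, m_tail):
    return ConsensusPair(
        normal=flank + n_tail, mutated=flank + m_tail, breakpoint_col=len(flank)
    )


FLANK = "GATTACAGATTACAGATTACA"
TAIL = "CCGTAGGCTAACGTAGCATTGG"


class TestClassifyVariant:
    def test_snv(self):
        call = classify_variant(_pair(FLANK, "C" + TAIL, "T" + TAIL))
        assert (call.vtype, call.normal_allele, call.mutated_allele) == (SNV, "C", "T")

    def test_deletion(self):
        call = classify_variant(_pair(FLANK, "ACG" + TAIL, TAIL))
        assert (call.vtype, call.normal_allele, call.mutated_allele, call.length) == (
            DELETION,
            "ACG",
            "",
            3,
        )

    def test_insertion(self):
        call = classify_variant(_pair(FLANK, TAIL, "GGCA" + TAIL))
        assert (call.vtype, call.mutated_allele, call.length) == (INSERTION, "GGCA", 4)

    def test_inversion_8bp(self):
        seg = "AACCGGTT"[:8]
        seg = "ATCCGGAA"  # non-palindromic 8-mer
        assert reverse_complement(seg) != seg
        call = classify_variant(_pair(FLANK, seg + TAIL, reverse_complement(seg) + TAIL))
        assert (call.vtype, call.length) == (INVERSION, 8)
        assert call.mutated_allele == reverse_complement(call.normal_allele)

    def test_contiguous_snvs_decompose_as_complex(self):
        # "CA" -> "GT" is not the reverse complement of "CA", so the
        # inversion test cannot claim it first
        call = classify_variant(_pair(FLANK, "CA" + TAIL, "GT" + TAIL))
        assert call.vtype == COMPLEX
        assert [c.vtype for c in call.components] == [SNV, SNV]
        assert [(c.normal_allele, c.mutated_allele) for c in call.components] == [
            ("C", "G"),
            ("A", "T"),
        ]

    def test_complex_decomposition_round_trip(self):
        # two substitutions one base apart: decomposable, not an inversion
        pair = _pair(FLANK, "CAG" + TAIL, "TAC" + TAIL)
        call = classify_variant(pair)
        assert call.vtype == COMPLEX
        b = pair.breakpoint_col
        recon = list(pair.normal)
        for comp in sorted(call.components, key=lambda c: c.col, reverse=True):
            if comp.vtype == SNV:
                recon[comp.col] = comp.mutated_allele
            elif comp.vtype == DELETION:
                del recon[comp.col : comp.col + len(comp.normal_allele)]
            elif comp.vtype == INSERTION:
                recon[comp.col:comp.col] = list(comp.mutated_allele)
        recon = "".join(recon)
        overlap = min(len(recon), len(pair.mutated))
        assert recon[:overlap] == pair.mutated[:overlap]

    def test_typing_order_deletion_never_complex(self):
        # a deletable pair must win at step 1 even though an edit script exists
        for g in (1, 2, 5):
            call = classify_variant(
                ConsensusPair(FLANK + TAIL, FLANK + TAIL[g:], len(FLANK))
            )
            assert call.vtype == DELETION, f"size {g} reported {call.vtype}"

    def test_short_extent_is_unassigned_not_complex(self):
        pair = ConsensusPair(FLANK + "ACGTA", FLANK + "GTACC", len(FLANK))
        call = classify_variant(pair, m=10)
        assert call.vtype == UNASSIGNED

    def test_insertion_deletion_tie_reports_deletion(self):
        # palindromic-context tie: both interpretations fit at g=1
        flank = "GATTACAGATTACAGATTACA"
        tail = "AAAAAAAAAAAAAAAA"
        call = classify_variant(ConsensusPair(flank + "A" + tail, flank + tail, len(flank)))
        assert call.vtype == DELETION


class TestStitchAndReinfer:
    def test_stitch_simple_overlap(self):
        a = "AAACGTACGTTTGCATCGGA"
        b = a[8:] + "CCTTAGC"
        merged, off = _stitch(a, b, 10)
        assert off == 0
        assert merged == a + "CCTTAGC"

    def test_stitch_left_extension(self):
        a = "CGTACGTTTGCATCGGA"
        b = "TTTAA" + a[:12]
        merged, off = _stitch(a, b, 10)
        assert off == 5
        assert merged == "TTTAA" + a

    def test_stitch_no_overlap_fails(self):
        assert _stitch("A" * 20, "C" * 20, 10) is None

    def test_reinfer_types_large_deletion(self, rng):
        # 12 bp deletion: each side alone lacks the g+m confirmation extent
        left = random_dna(rng, 40)
        deleted = random_dna(rng, 12)
        right = random_dna(rng, 40)
        normal_seq = left + deleted + right
        # forward cluster: long left flank, 8 bases of right extent
        fwd = ConsensusPair(
            normal=left + (deleted + right)[:8],
            mutated=left + right[:8],
            breakpoint_col=len(left),
        )
        # partner cluster (already reoriented): short left, long right
        partner = ConsensusPair(
            normal=left[-8:] + deleted + right,
            mutated=left[-8:] + right,
            breakpoint_col=8,
        )
        call = classify_variant(fwd)
        assert call.vtype == UNASSIGNED
        call.partner_pair = partner
        retyped = reinfer_unassigned(call)
        assert (retyped.vtype, retyped.length) == (DELETION, 12)
        assert retyped.normal_allele == deleted

    def test_reinfer_leaves_unstitchable_call(self, rng):
        pair = ConsensusPair(FLANK + "ACGTA", FLANK + "GTACC", len(FLANK))
        call = classify_variant(pair)
        call.partner_pair = ConsensusPair("G" * 20 + "A" * 20, "G" * 20 + "C" * 20, 20)
        assert reinfer_unassigned(call).vtype == UNASSIGNED

    def test_reinfer_ignores_typed_calls(self):
        call = classify_variant(_pair(FLANK, "C" + TAIL, "T" + TAIL))
        assert reinfer_unassigned(call) is call


def _call(cid, anchor, pair, vtype=UNASSIGNED, n_norm=8, n_mut=8):
    call = VariantCall(
        vtype=vtype,
        normal_allele="",
        mutated_allele="",
        length=0,
        consensus=pair,
        cluster_id=cid,
        anchor=anchor,
        n_normal=n_norm,
        n_mutated=n_mut,
        q=1.0,
    )
    return call


class TestMergeReverseComplementClusters:
    def _mirrored_pair(self, rng):
        flank_l = random_dna(rng, 25)
        flank_r = random_dna(rng, 25)
        normal = flank_l + "C" + flank_r
        mutated = flank_l + "T" + flank_r
        fwd = ConsensusPair(normal, mutated, 25)
        rev = ConsensusPair(
            reverse_complement(normal), reverse_complement(mutated), 25
        )
        a = _call(0, "A" + flank_l[1:], fwd, vtype=SNV)
        b = _call(1, "C" + flank_r[1:], rev, vtype=SNV)
        return a, b

    def test_mirrored_calls_merge_with_summed_support(self, rng):
        a, b = self._mirrored_pair(rng)
        merged = merge_reverse_complement_clusters([a, b], 15)
        assert len(merged) == 1
        assert merged[0].n_normal == 16
        assert merged[0].n_mutated == 16

    def test_unrelated_calls_not_merged(self, rng):
        a, _ = self._mirrored_pair(rng)
        c = _call(
            2,
            "GGGG",
            ConsensusPair(random_dna(rng, 40), random_dna(rng, 40)[:39] + "A", 0),
            vtype=SNV,
        )
        assert len(merge_reverse_complement_clusters([a, c], 15)) == 2

    def test_strand_specific_mode_is_identity(self, rng):
        a, b = self._mirrored_pair(rng)
        assert merge_reverse_complement_clusters([a, b], 15, strand_specific=True) == [a, b]
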