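"""Independent oracles: small, slow re-implementations used only to check
the package's fast paths.  They deliberately share no code with the
package beyond the variant-free alphabet."""

from __future__ import annotations

from collections import Counter

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def all_suffixes(normal_seqs, mutated_seqs, d, strand_specific):
    """Every suffix of length >= d as (text, group, strand, read_id, offset)."""
    out = []
    for group, seqs in (("normal", normal_seqs), ("mutated", mutated_seqs)):
        for rid, s in enumerate(seqs):
            orientations = [("forward", s)]
            if not strand_specific:
                orientations.append(("reverse", rc(s)))
            for strand, t in orientations:
                for o in range(len(t) - d + 1):
                    out.append((t[o:], group, strand, rid, o))
    return out


def brute_force_clusters(
    normal_seqs,
    mutated_seqs,
    d,
    *,
    strand_specific=True,
    cmin=1,
    cmax=None,
    qmin=0.0,
    qmax=1.0,
    pnorm_max=1.0,
):
    """Accepted breakpoint clusters by all-pairs suffix comparison.

    Groups suffixes by comparing every pair directly (union-find on
    first-d equality, no partitioning or sorting), applies the breakpoint
    conditions and the read-count / variant-fraction / contamination
    filters, and returns a set of cluster signatures
    ``(anchor, frozenset of member (group, strand, read_id, offset))``.
    """
    sufs = all_suffixes(normal_seqs, mutated_seqs, d, strand_specific)
    n = len(sufs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sufs[i][0][:d] == sufs[j][0][:d]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    accepted = set()
    for idxs in groups.values():
        members = [sufs[i] for i in idxs]
        div = {m[0][d] for m in members if len(m[0]) > d}
        grps = {m[1] for m in members}
        if len(div) < 2 or grps != {"normal", "mutated"}:
            continue
        # one vote per (group, strand, read); smallest offset kept
        best = {}
        for text, group, strand, rid, o in members:
            key = (group, strand, rid)
            if key not in best or o < best[key][4]:
                best[key] = (text, group, strand, rid, o)
        per_group = {"normal": [], "mutated": []}
        for text, group, strand, rid, o in best.values():
            per_group[group].append((text, o))
        n_norm, n_mut = len(per_group["normal"]), len(per_group["mutated"])
        if min(n_norm, n_mut) < cmin:
            continue
        if cmax is not None and max(n_norm, n_mut) > cmax:
            continue
        norm_div = Counter(t[d] for t, _o in per_group["normal"] if len(t) > d)
        if norm_div:
            top = max(norm_div.values())
            ref_base = min(b for b, c in norm_div.items() if c == top)
        else:
            ref_base = None
        mut_cov = [t[d] for t, _o in per_group["mutated"] if len(t) > d]
        q = (
            sum(1 for b in mut_cov if b != ref_base) / len(mut_cov)
            if mut_cov
            else 0.0
        )
        if not qmin <= q <= qmax:
            continue
        norm_cov = [t[d] for t, _o in per_group["normal"] if len(t) > d]
        if norm_cov:
            contam = sum(1 for b in norm_cov if b != ref_base) / len(norm_cov)
            if contam > pnorm_max:
                continue
        anchor = members[0][0][:d]
        sig = frozenset((g, s, r, o) for _t, g, s, r, o in members)
        accepted.add((anchor, sig))
    return accepted


def naive_sorted_texts(texts):
    """Plain lexicographic sort of full suffix texts (Python's string
    order: a proper prefix sorts before its extensions)."""
    return sorted(texts)


def column_majority(reads_with_cols, col, min_cov=2):
    """Strict-majority base at a column of breakpoint-aligned reads, or
    None when coverage < min_cov or no base exceeds half the votes.

    ``reads_with_cols`` is a list of (text, breakpoint_col).
    """
    votes = Counter()
    for text, bcol in reads_with_cols:
        p = bcol + col
        if 0 <= p < len(text):
            votes[text[p]] += 1
    total = sum(votes.values())
    if total < min_cov:
        return None
    base, top = votes.most_common(1)[0]
    if top * 2 <= total:
        return None
    return base
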