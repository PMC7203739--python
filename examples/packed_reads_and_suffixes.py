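"""The memory layer: 2-bit packed reads and prefix-partitioned suffixes.

Reads are stored as bit strings (A=00, C=01, G=10, T=11) in blocks of
64 with 2-byte in-block offsets, so random access by read ID costs
2 + 8/64 = 2.125 index bytes per read.  Breakpoint scanning never sorts
all suffixes at once: they are split into 4^k batches by their length-k
prefix and each batch is sorted and released in turn.
"""

from breakscan import (
    PackedReadStore,
    collect_suffixes,
    encode_sequence,
    index_overhead_bytes,
    list_prefixes,
    sort_suffix_refs,
)
from breakscan.suffix_partition import SuffixEngine

print("encode('ACGT') ->", format(encode_sequence("ACGT")[0], "08b"),
      "(2 bits per base)")
print("index overhead per read:", index_overhead_bytes(64), "bytes")

plan = list_prefixes(3)
print(f"k=3 splits suffixes into {len(plan.prefixes)} batches, "
      f"'{plan.prefixes[0]}' ... '{plan.prefixes[-1]}'")

normal = PackedReadStore("normal")
mutated = PackedReadStore("mutated")
for seq in ("AAACCCTTTG", "CCCTTTGGGA"):
    normal.append(seq)
mutated.append("AAACCCTTAG")

engine = SuffixEngine(normal, mutated, strand_specific=True)
refs = collect_suffixes(normal, mutated, "CCC", d=4, engine=engine)
ordered = sort_suffix_refs(refs, normal, mutated, engine=engine)
print("suffixes with prefix CCC, lexicographically sorted:")
for ref in ordered:
    print(f"  {engine.ref_suffix_text(ref):10s} "
          f"({ref.group}, read {ref.read_id}, offset {ref.offset})")
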