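"""How a breakpoint's variant type is read off its consensus pair.

A breakpoint cluster yields two consensus sequences — normal and
mutated — that agree up to the breakpoint column and diverge there.
Typing compares them in a fixed order (indel, SNV, inversion, complex):
the first interpretation whose downstream context matches for m = 10
confirmation bases wins.
"""

from breakscan import ConsensusPair, classify_variant, reverse_complement

FLANK = "GATTACAGATTACAGATTACA"   # shared sequence left of the breakpoint
TAIL = "CCGTAGGCTAACGTAGCATTGG"   # shared context after the event

cases = {
    "substitution":      (FLANK + "C" + TAIL, FLANK + "T" + TAIL),
    "3 bp deletion":     (FLANK + "ACG" + TAIL, FLANK + TAIL),
    "4 bp insertion":    (FLANK + TAIL, FLANK + "GGCA" + TAIL),
    "8 bp inversion":    (FLANK + "ATCCGGAA" + TAIL,
                          FLANK + reverse_complement("ATCCGGAA") + TAIL),
    "2 adjacent SNVs":   (FLANK + "CA" + TAIL, FLANK + "GT" + TAIL),
}

for name, (normal, mutated) in cases.items():
    pair = ConsensusPair(normal, mutated, breakpoint_col=len(FLANK))
    call = classify_variant(pair)
    detail = f"{call.normal_allele or '-'} -> {call.mutated_allele or '-'}"
    if call.components:  # a decomposed complex lists its elements
        detail += " = " + " + ".join(
            f"{c.vtype}({c.normal_allele or '-'}>{c.mutated_allele or '-'})"
            for c in call.components
        )
    print(f"{name:16s} => {call.vtype:9s} length={call.length:2d}  {detail}")
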