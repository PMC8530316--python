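"""Enumerate the ligation-junction motifs of one- and two-enzyme digests.

The junction of a proximity-ligation event is the end-filled terminus of
one restriction fragment joined to the end-filled terminus of another, so
its sequence (and length l_LA) is predictable from the enzymes alone.
"""

from pliqc import junction_set, parse_enzyme

for spec in ("DpnII", "HindIII"):
    enz = parse_enzyme(spec)
    js = junction_set(enz)
    m = js.motifs[0]
    print(f"{spec:8s} site={enz.site} overhang={enz.overhang} "
          f"junction={m.sequence} l_LA={m.l_la}")

print("\nDual digest DpnII + HinfI (G^ANTC):")
js = junction_set(parse_enzyme("DpnII"), parse_enzyme("HinfI"))
for m in js.motifs:
    print(f"  {m.sequence:10s} l_LA={m.l_la}  from {m.source[0]}+{m.source[1]}")
print(f"  {len(js.concrete)} concrete search sequences "
      "(ambiguity-expanded, reverse-complement closed)")
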