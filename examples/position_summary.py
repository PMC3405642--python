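"""Summarise the varying mtDNA positions of a small subset.

Builds a 15-member subset in which nine individuals carry the C mutation at
locus 16362 and six carry the normal base, plus a second locus with mixed
alleles, and prints each varying position in the standard
``locus N>M (Y/X)`` notation: Y members carry the mutant nucleotide M,
X members carry the normal nucleotide N.
"""

from mitomatch import VariantSet, summarize_positions, synthetic_rcrs

reference = synthetic_rcrs()

members = []
for i in range(15):
    calls = {}
    if i < 9:
        calls[16362] = "C"          # mutation carried by nine members
    if i % 3 == 0:
        base = reference[708]       # locus 709, 1-based
        calls[709] = "A" if base != "A" else "G"
    members.append(VariantSet(f"member{i:02d}", calls))

for summary in summarize_positions(members, reference):
    print(summary.rendered())
print()
print("reading: 'locus normal>mutant (carriers of mutant / carriers of normal)'")
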