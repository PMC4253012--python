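"""Find microsatellite (STR) regions in a DNA sequence.

The detector reports maximal runs of at least ``min_repeats`` contiguous
copies of a primitive 2-6 nt motif, resolves overlapping candidates
deterministically, and can re-phase boundaries so that orthologous arrays
written with rotated motifs (GATA vs ATAG) compare cleanly.
"""
import orthosat as o

seq = ("TTGACCTGATCGTAGCCTGACGAT"
       + "GATA" * 9            # a clean tetranucleotide array
       + "CGTTAG"
       + "CA" * 7              # a dinucleotide array after a 6-nt spacer
       + "CATGGACTTGACGG")

structure = o.find_str_regions(seq, min_repeats=4)
structure = o.harmonize_boundaries(structure, seq)

for r in structure.regions:
    print(f"{r.motif} x {r.repeat_count}  at [{r.start}, {r.end})")
print("spacers between regions:", structure.spacers)
print("total repeats:", o.total_repeats(structure))
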