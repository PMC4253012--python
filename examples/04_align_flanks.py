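"""Align orthologous amplicons and count species-specific non-STR bases.

STR arrays are paired as anchors and surplus repeats are gapped as whole
units, so length differences caused by repeat-count variation vanish from
the accounting.  What remains — the non-STR imbalance — is exactly the
flank insertion/deletion signal that corrupts fragment-length genotyping.
"""
import orthosat as o
from orthosat.flankalign import align_orthologs, nonstr_imbalance

left = "TTGACCTGATCGTAGCCTGACGATTGCCAT"
right = "CGTTAGCATGGACTTGACGGTACCGGATTA"
insertion = "GCCTAGTTAC"  # 10 nt present only in the human flank

chimp = left + "GATA" * 9 + right
human = left[:12] + insertion + left[12:] + "GATA" * 13 + right

c_struct = o.harmonize_boundaries(o.find_str_regions(chimp, 4), chimp)
h_struct = o.harmonize_boundaries(o.find_str_regions(human, 4), human)

aln = align_orthologs(chimp, human, c_struct, h_struct, "demo")
print("anchored on a shared STR array:", aln.anchored)
print("chimp:", aln.chimp_aln)
print("human:", aln.human_aln)
chimp_only, human_only = nonstr_imbalance(aln)
print(f"species-specific non-STR bases: chimp {chimp_only}, human {human_only}")
print("(the 16 bp of surplus GATA repeats are invisible, the 10 bp insertion is not)")
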