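"""Decide whether a chimpanzee marker behaves like the human ortholog.

Each species contributes an observed allele-length range and the reference
individual's own fragment length.  A marker is retained when (i) both
reference lengths fall in the intersection of the ranges, or (ii) in their
union, or (iii) the ranges overlap strongly (range-overlap score >= the
threshold) and the offending length is within 6 bp of the union.
"""
import orthosat as o

chimp_range = o.LengthRange(196, 216, species="chimpanzee")
human_range = o.LengthRange(200, 224, species="human")

print("range class:", o.classify_ranges(chimp_range, human_range))
print("range overlap score:", round(o.range_overlap_score(chimp_range, human_range), 3))

for x_chimp in (205, 198, 195, 180):
    a = o.assess_lengths("demo", x_chimp, 210, chimp_range, human_range)
    print(f"chimp ref {x_chimp} bp -> criterion {a.criterion!r:6} "
          f"retained={a.retained}  ({a.reason})")
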