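"""Convert PCR fragment lengths to repeat numbers and back.

A calibration model ties one sequenced reference fragment (known length,
known repeat count, known unit size) to the rest of a species' genotypes.
Conversions are exact rational arithmetic; a normalization pass flags each
marker as integer, common-fraction (rounded), or mixed-fraction (left
unadjusted, typically an unmerged inter-laboratory offset).
"""
import numpy as np

import orthosat as o
from orthosat.calibrate import CalibrationModel

model = CalibrationModel(marker="demo", species="human",
                         ref_adjusted_length=208, ref_total_repeats=12,
                         unit_size=4)

for L in (208, 216, 196):
    print(f"{L} bp -> {o.length_to_repeats(L, model)} repeats")
print("14 repeats ->", o.repeats_to_length(14, model), "bp")

lengths = np.array([[[208.0, 216.0]], [[196.0, 208.0]], [[212.0, 212.0]]])
ds = o.GenotypeDataset(["a", "b", "c"], ["P"] * 3, ["human"] * 3,
                       ["demo"], lengths, "length")
repeats, report = o.normalize_dataset(ds, {("demo", "human"): model})
print("normalization flags:", report)
print("repeat genotypes:\n", repeats.alleles[:, 0, :])
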