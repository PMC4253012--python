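"""Conversion between PCR fragment lengths and repeat numbers.

A genotype panel sizes PCR products, but the biologically comparable quantity
across species is the total repeat number of the embedded STR arrays.  Under
the assumption that all within-species length variation is repeat-number
variation, a locus is calibrated against its species' reference amplicon:

    repeats(L) = ref_total_repeats + (L - ref_adjusted_length) / unit_size

which is affine and strictly increasing in L.  Calibration is only defined
when every STR region of the locus shares one repeat-unit size; mixed-unit
loci are rejected because a length change cannot be attributed to a repeat
count.  Models are species-specific by construction — calibrating one
species' genotypes against the other species' reference would bake the very
flank-length imbalances the pipeline measures into the repeat numbers.

Converted values are exact rationals.  When every converted allele at a locus
shares a single non-zero decimal fraction (small reference or sizing
inaccuracies shift all genotypes by a constant sub-unit amount), all values
are rounded to the nearest integer (half away from zero).  Loci showing
multiple distinct fractions are left unadjusted and flagged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .strdetect import total_repeats
from .types import EPCRFragment, GenotypeDataset, STRStructure

FLAG_INTEGER = "integer"
FLAG_COMMON_ROUNDED = "common-fraction rounded"
FLAG_MIXED_UNADJUSTED = "mixed-fraction unadjusted"


class MixedUnitError(ValueError):
    """STR regions of the locus use more than one repeat-unit size."""


@dataclass(frozen=True)
class CalibrationModel:
    marker: str
    species: str
    ref_adjusted_length: int
    ref_total_repeats: int
    unit_size: int

    def __post_init__(self):
        if not (2 <= self.unit_size <= 6):
            raise ValueError("unit_size must be within 2..6")
        if self.ref_total_repeats < 1:
            raise ValueError("reference must contain at least one repeat")


def build_model(fragment: EPCRFragment, structure: STRStructure) -> CalibrationModel:
    """Calibration model from a reference amplicon and its STR structure."""
    if not structure.regions:
        raise ValueError(f"{fragment.marker_name}: no STR regions; cannot calibrate")
    units = {r.unit_size for r in structure.regions}
    if len(units) > 1:
        raise MixedUnitError(
            f"{fragment.marker_name}: mixed-unit excluded (unit sizes {sorted(units)})")
    return CalibrationModel(
        marker=fragment.marker_name, species=fragment.species,
        ref_adjusted_length=fragment.adjusted_length,
        ref_total_repeats=total_repeats(structure),
        unit_size=units.pop())


def length_to_repeats(length_bp, model: CalibrationModel) -> Fraction:
    """Exact repeat number implied by a fragment length (may be non-integer)."""
    if length_bp <= 0:
        raise ValueError("fragment length must be positive")
    return (Fraction(model.ref_total_repeats)
            + Fraction(int(round(length_bp)) - model.ref_adjusted_length, model.unit_size))


def repeats_to_length(repeats, model: CalibrationModel) -> int:
    """Fragment length implied by a repeat number (exact inverse of the above)."""
    if repeats < 1:
        raise ValueError("repeat number must be >= 1")
    value = model.ref_adjusted_length + (Fraction(repeats) - model.ref_total_repeats) * model.unit_size
    if value.denominator != 1:
        raise ValueError("repeat number implies a non-integer length")
    return int(value)


def _round_half_away(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2)) if x >= 0 else -math.floor(-x + Fraction(1, 2))


def normalize_dataset(dataset: GenotypeDataset,
                      models: dict[tuple[str, str], CalibrationModel]):
    """Convert a length dataset to repeat numbers, locus by locus.

    ``models`` maps (marker, species) -> CalibrationModel; a model is required
    for every species with data at each marker.  Returns (repeat dataset,
    report) where the report maps marker -> flag: "integer" (all converted
    values integral), "common-fraction rounded" (all shared one non-zero
    fraction; rounded to nearest), or "mixed-fraction unadjusted".
    The operation is idempotent: feeding the repeat-number output back in
    re-applies only the rounding policy, which is then a no-op.
    """
    already_repeats = dataset.representation == "repeats"
    out = np.full_like(dataset.alleles, np.nan)
    report: dict[str, str] = {}
    species_arr = np.array(dataset.species)
    for j, marker in enumerate(dataset.loci):
        converted: dict[tuple[int, int], Fraction] = {}
        for sp in sorted(set(dataset.species)):
            mask = species_arr == sp
            idx = np.flatnonzero(mask)
            vals = dataset.alleles[mask, j, :]
            if np.all(np.isnan(vals)):
                continue
            model = None
            if not already_repeats:
                model = models.get((marker, sp))
                if model is None:
                    raise KeyError(f"missing calibration model for ({marker}, {sp})")
            for i in idx:
                for k in range(2):
                    v = dataset.alleles[i, j, k]
                    if not np.isnan(v):
                        if already_repeats:
                            # values are exact rationals with denominator <= 6
                            converted[(i, k)] = Fraction(v).limit_denominator(64)
                        else:
                            converted[(i, k)] = length_to_repeats(v, model)
        fractions = {f - math.floor(f) for f in converted.values()}
        nonzero = {f for f in fractions if f != 0}
        if not nonzero:
            flag = FLAG_INTEGER
            final = converted
        elif len(fractions) == 1:
            flag = FLAG_COMMON_ROUNDED
            final = {key: Fraction(_round_half_away(f)) for key, f in converted.items()}
        else:
            flag = FLAG_MIXED_UNADJUSTED
            final = converted
        report[marker] = flag
        for (i, k), f in final.items():
            out[i, j, k] = float(f)
    return dataset.copy_with(alleles=out, representation="repeats"), report
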