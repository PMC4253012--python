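"""Domain types shared across the pipeline.

Coordinates are 0-based half-open internally; report writers emit 1-based
inclusive coordinates and say so in their headers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_BASES = frozenset("ACGT")
MISSING = -9

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGT characters in {what}: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class PrimerPair:
    """A locus-specific forward/reverse primer pair.

    ``forward_extra_bp``/``reverse_extra_bp`` record non-genomic 5' additions
    used to stabilise PCR product sizing: 7 for a pig-tail, 1 for a single
    extra adenine, 0 for an unmodified primer.  ``merge_offset`` is a signed
    bp correction that was applied to one species' genotypes when datasets
    were merged; it is reversed before any length comparison.
    """

    marker_name: str
    forward: str
    reverse: str
    forward_extra_bp: int = 0
    reverse_extra_bp: int = 0
    merge_offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "forward", _check_dna(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _check_dna(self.reverse, "reverse primer"))
        if not self.forward or not self.reverse:
            raise ValueError(f"{self.marker_name}: empty primer sequence")
        for v in (self.forward_extra_bp, self.reverse_extra_bp):
            if v not in (0, 1, 7):
                raise ValueError(f"{self.marker_name}: extra-bp must be 0, 1 or 7, got {v}")
        if self.forward_extra_bp and self.reverse_extra_bp:
            raise ValueError(f"{self.marker_name}: at most one primer may carry a modification")


@dataclass(frozen=True)
class PrimerHit:
    """One accepted local alignment of a primer against a reference.

    ``five_prime_pos`` is the 1-based reference position of the primer's
    5'-terminal base as placed by the alignment (on the minus strand this is
    the rightmost base of the match).  ``primer_length`` counts genomic
    primer bases only (non-genomic tails excluded).
    """

    chromosome: str
    strand: str  # '+' or '-'
    five_prime_pos: int
    alignment_length: int
    identity: float
    primer_length: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity outside [0,1]: {self.identity}")
        if self.alignment_length > self.primer_length + 10:
            raise ValueError("alignment length exceeds primer length + 10")


@dataclass(frozen=True)
class STRRegion:
    """A run of ``repeat_count`` contiguous copies of ``motif`` within a fragment."""

    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    motif: str
    unit_size: int
    repeat_count: int

    def __post_init__(self):
        if self.end - self.start != self.unit_size * self.repeat_count:
            raise ValueError("region extent inconsistent with unit_size x repeat_count")
        if len(self.motif) != self.unit_size:
            raise ValueError("motif length inconsistent with unit_size")
        if is_motif_reducible(self.motif):
            raise ValueError(f"motif {self.motif} is a repetition of a shorter motif")


def is_motif_reducible(motif: str) -> bool:
    """True when the motif is a whole-number repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return True
    return False


def motif_rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def rotation_equivalent(a: str, b: str) -> bool:
    return len(a) == len(b) and b in motif_rotations(a)


@dataclass
class STRStructure:
    """Ordered, non-overlapping STR regions plus inter-region spacer lengths."""

    regions: list[STRRegion] = field(default_factory=list)
    spacers: list[int] = field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start < a.end:
                raise ValueError("regions overlap or are unsorted")
        if self.regions and len(self.spacers) != len(self.regions) - 1:
            raise ValueError("spacer count must be region count - 1")
        # 0 is legal: two regions with distinct motifs may abut directly
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be >= 0")

    @classmethod
    def from_regions(cls, regions: list[STRRegion]) -> "STRStructure":
        regions = sorted(regions, key=lambda r: r.start)
        spacers = [b.start - a.end for a, b in zip(regions, regions[1:])]
        return cls(regions=regions, spacers=spacers)

    def __len__(self):
        return len(self.regions)


@dataclass(frozen=True)
class EPCRFragment:
    """A candidate amplicon demarcated by a primer-hit pair in a reference."""

    marker_name: str
    chromosome: str
    sequence: str
    raw_length: int
    adjusted_length: int
    species: str
    start: int = 0  # 0-based offset of fragment within the reference record

    def __post_init__(self):
        if self.sequence and self.raw_length != len(self.sequence):
            raise ValueError("raw_length inconsistent with sequence")


@dataclass(frozen=True)
class LengthRange:
    """Closed interval of observed PCR fragment lengths (bp) for one species."""

    lo: int
    hi: int
    species: str = ""

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"lo > hi in LengthRange: [{self.lo}, {self.hi}]")

    @property
    def width(self) -> int:
        """Number of integer bp values the closed interval contains."""
        return self.hi - self.lo + 1

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass(frozen=True)
class PopulationDistance:
    population: str
    distance_km: float

    def __post_init__(self):
        if self.distance_km < 0:
            raise ValueError("distance must be non-negative")


class GenotypeDataset:
    """Diploid genotypes at multiple loci with population/species labels.

    Alleles are stored as a float array of shape (n_individuals, n_loci, 2)
    with NaN for missing values; each pair is kept sorted ascending so that
    file output is deterministic.  ``representation`` is either ``"length"``
    (PCR fragment lengths, bp) or ``"repeats"`` (repeat numbers).
    """

    def __init__(self, individuals, populations, species, loci, alleles,
                 representation: str):
        if representation not in ("length", "repeats"):
            raise ValueError(f"unknown representation {representation!r}")
        self.individuals = list(individuals)
        self.populations = list(populations)
        self.species = list(species)
        self.loci = list(loci)
        alleles = np.asarray(alleles, dtype=float)
        if alleles.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("allele array shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(alleles <= 0):
                raise ValueError("allele values must be strictly positive when present")
        # one genotype may be half-missing in the raw file; treat as fully missing
        half = np.isnan(alleles).sum(axis=2) == 1
        alleles[half] = np.nan
        self.alleles = np.sort(alleles, axis=2)
        self.representation = representation
        pop2sp = {}
        for p, s in zip(self.populations, self.species):
            if pop2sp.setdefault(p, s) != s:
                raise ValueError(f"population {p} maps to more than one species")
        self.pop_to_species = pop2sp

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, marker: str) -> int:
        return self.loci.index(marker)

    def species_mask(self, species: str) -> np.ndarray:
        return np.array([s == species for s in self.species])

    def population_mask(self, population: str) -> np.ndarray:
        return np.array([p == population for p in self.populations])

    def species_range(self, marker: str, species: str) -> Optional[LengthRange]:
        """Observed allele range [min, max] for one marker in one species."""
        vals = self.alleles[self.species_mask(species), self.locus_index(marker), :]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return None
        return LengthRange(int(vals.min()), int(vals.max()), species=species)

    def subset_loci(self, markers) -> "GenotypeDataset":
        idx = [self.locus_index(m) for m in markers]
        return GenotypeDataset(self.individuals, self.populations, self.species,
                               [self.loci[i] for i in idx],
                               self.alleles[:, idx, :].copy(), self.representation)

    def copy_with(self, alleles=None, representation=None) -> "GenotypeDataset":
        return GenotypeDataset(
            self.individuals, self.populations, self.species, self.loci,
            self.alleles.copy() if alleles is None else alleles,
            self.representation if representation is None else representation)

    def __eq__(self, other):
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (self.individuals == other.individuals
                and self.populations == other.populations
                and self.species == other.species
                and self.loci == other.loci
                and self.representation == other.representation
                and np.array_equal(self.alleles, other.alleles, equal_nan=True))
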