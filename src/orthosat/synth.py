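"""Synthetic ortholog pairs, primer tables, and genotype datasets with known truth.

The generator emulates the data-generating structure the analysis assumes:
a flanking sequence shared between the two species, embedded STR arrays whose
repeat counts differ by species, primer sites at the amplicon ends, optional
species-specific flank insertions (the source of length incommensurability),
and multi-population diploid genotypes whose repeat-number frequencies have
drifted around a species base distribution.

Sequence construction is exact and verified: flanks and spacers are
rejection-sampled to be repeat-free, junction bases are chosen so that no STR
array can extend across its boundaries, and the assembled amplicon is
re-scanned to confirm that detection recovers precisely the planted regions.
Every marker therefore comes with a machine-checkable truth record.

Genotypes are simulated at drift equilibrium: population repeat-frequency
vectors are drawn from a Dirichlet distribution around the species base
frequencies with concentration (1-F)/F (Balding-Nichols style), and diploid
alleles are sampled i.i.d.  Base distributions are discretized
double-geometric around a species mean, giving the long-tailed,
mostly-single-step allele spacing characteristic of stepwise mutation.
A minimal forward-time single-step mutator is included for realism demos.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as osio
from .calibrate import CalibrationModel
from .epcr import scan_primer
from .strdetect import find_str_regions
from .types import (GenotypeDataset, LengthRange, PopulationDistance,
                    PrimerPair, STRRegion, STRStructure, revcomp)

PRIMER_LEN = 20
PAD_LEN = 15
PIGTAIL = "GTTTCTT"  # the classic 7-bp non-genomic 5' tail

SCENARIO_OK = "ok"
SCENARIO_NO_HIT = "no_hit"
SCENARIO_LENGTH_FAR = "length_far"
SCENARIO_SHARED_REVERSE = "shared_reverse"
SCENARIO_MULTI_HIT = "multi_hit"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MarkerConfig:
    """Ground-truth blueprint for one synthetic marker.

    ``repeats_chimp``/``repeats_human`` give per-region repeat counts in the
    two reference amplicons (0 removes the region from that species).
    ``indels`` plant species-specific flank insertions of the given sizes
    (<= 32 bp each).  ``support_*`` are inclusive total-repeat ranges the
    genotype simulator draws from (default: reference total +/- 2).
    ``scenario`` perturbs the chimpanzee reference record to exercise a
    specific branch of the amplicon-identification decision tree.
    """

    name: str
    motifs: Sequence[str] = ("GATA",)
    repeats_chimp: Sequence[int] = (10,)
    repeats_human: Sequence[int] = (12,)
    spacers: Sequence[int] = ()
    flank_len: int = 60
    indels: Sequence[tuple[str, int]] = ()
    disruption: Optional[tuple[str, int]] = None  # (species, region index)
    mod_flag: str = "none"        # 'none', 'P' (pig-tail) or 'M' (extra adenine)
    mod_primer: str = "none"
    merge_offset: int = 0
    scenario: str = SCENARIO_OK
    support_chimp: Optional[tuple[int, int]] = None
    support_human: Optional[tuple[int, int]] = None

    def __post_init__(self):
        n = len(self.motifs)
        if len(self.repeats_chimp) != n or len(self.repeats_human) != n:
            raise ValueError(f"{self.name}: per-region repeat counts must match motifs")
        if n > 1 and len(self.spacers) != n - 1:
            raise ValueError(f"{self.name}: need {n - 1} spacer lengths")
        if self.flank_len < PRIMER_LEN + 10:
            raise ValueError(f"{self.name}: flank too short for a primer site")
        if any(size > 32 for _, size in self.indels):
            raise ValueError(f"{self.name}: indel sizes above 32 bp are not plausible here")


@dataclass
class MarkerTruth:
    """Everything the generator knows about one marker."""

    config: MarkerConfig
    primer_pair: PrimerPair
    amplicons: dict            # species -> amplicon sequence
    references: dict           # species -> full reference record (with pads/scenario)
    structures: dict           # species -> STRStructure (min_repeats=4 detection truth)
    adjusted_lengths: dict     # species -> int (raw + tail bp - merge offset)
    indel_totals: dict         # species -> planted species-specific flank nt
    varying_unit: int          # repeat-unit size the genotype simulator steps by
    ref_totals: dict           # species -> total planted repeats (all regions)
    supports: dict             # species -> (lo, hi) total-repeat support

    def model(self, species: str) -> CalibrationModel:
        return CalibrationModel(
            marker=self.config.name, species=species,
            ref_adjusted_length=self.adjusted_lengths[species],
            ref_total_repeats=max(1, self.ref_totals[species]),
            unit_size=self.varying_unit)

    def length_of(self, species: str, total_repeats: int) -> int:
        return (self.adjusted_lengths[species]
                + (total_repeats - self.ref_totals[species]) * self.varying_unit)


@dataclass
class StudyBundle:
    markers: list[MarkerTruth]
    genotypes: GenotypeDataset                 # length representation
    true_repeats: GenotypeDataset              # repeat representation (ground truth)
    primer_pairs: list[PrimerPair]
    distances: dict[str, PopulationDistance]
    seed: int

    def reference_records(self, species: str) -> dict[str, str]:
        return {t.config.name: t.references[species] for t in self.markers}

    def models(self) -> dict[tuple[str, str], CalibrationModel]:
        out = {}
        for t in self.markers:
            for sp in ("chimpanzee", "human"):
                if t.ref_totals[sp] >= 1:
                    out[(t.config.name, sp)] = t.model(sp)
        return out

    def write_to(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sp in ("chimpanzee", "human"):
            osio.write_fasta({f"{name}|{sp}": seq
                              for name, seq in self.reference_records(sp).items()},
                             directory / f"reference_{sp}.fa")
        osio.write_primer_table(self.primer_pairs, directory / "primers.tsv")
        osio.write_genotypes(self.genotypes, directory / "genotypes_length.tsv")
        osio.write_samples(self.genotypes, directory / "samples.tsv", self.distances)


def _random_chunk(rng: np.random.Generator, length: int, max_tries: int = 200) -> str:
    """A repeat-free random sequence (no >=3 contiguous copies of any 2-6 nt motif)."""
    if length == 0:
        return ""
    for _ in range(max_tries):
        seq = "".join(rng.choice(_BASES, size=length))
        if length < 6 or not find_str_regions(seq, min_repeats=3).regions:
            # also bar homopolymer triples, which seed runs across junctions
            if not any(seq[i] == seq[i + 1] == seq[i + 2] for i in range(len(seq) - 2)):
                return seq
    raise RuntimeError("could not sample a repeat-free chunk")


def _fix_edge(chunk: str, forbidden_last: str | None, forbidden_first: str | None,
              rng: np.random.Generator) -> str:
    """Replace edge bases that would let an adjacent STR array extend across."""
    chunk = list(chunk)
    if chunk and forbidden_last and chunk[-1] == forbidden_last:
        options = [b for b in "ACGT" if b != forbidden_last
                   and not (len(chunk) > 1 and b == chunk[-2])]
        chunk[-1] = str(rng.choice(options))
    if chunk and forbidden_first and chunk[0] == forbidden_first:
        options = [b for b in "ACGT" if b != forbidden_first
                   and not (len(chunk) > 1 and b == chunk[1])]
        chunk[0] = str(rng.choice(options))
    return "".join(chunk)


def _interruption_base(motif: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != motif[0] and b != motif[-1]]
    return str(rng.choice(options))


def _build_species_amplicon(cfg: MarkerConfig, species: str, left: str, right: str,
                            spacer_seqs: list[str], rng: np.random.Generator,
                            indel_seqs: list[tuple[str, str]]):
    """Assemble one species' amplicon; returns (sequence, expected regions)."""
    counts = cfg.repeats_chimp if species == "chimpanzee" else cfg.repeats_human
    parts = [left]
    expected: list[STRRegion] = []
    pos = len(left)
    for i, (motif, count) in enumerate(zip(cfg.motifs, counts)):
        if count > 0:
            if cfg.disruption and cfg.disruption == (species, i) and count >= 5:
                c1 = count // 2
                c2 = count - c1
                x = _interruption_base(motif, rng)
                block = motif * c1 + x + motif * c2
                expected.append(STRRegion(pos, pos + c1 * len(motif), motif,
                                          len(motif), c1))
                p2 = pos + c1 * len(motif) + 1
                expected.append(STRRegion(p2, p2 + c2 * len(motif), motif,
                                          len(motif), c2))
            else:
                block = motif * count
                expected.append(STRRegion(pos, pos + count * len(motif), motif,
                                          len(motif), count))
            parts.append(block)
            pos += len(block)
        if i < len(cfg.motifs) - 1:
            parts.append(spacer_seqs[i])
            pos += len(spacer_seqs[i])
    parts.append(right)
    seq = "".join(parts)
    # species-specific flank insertions, placed mid-flank away from primer sites
    for target_species, ins in indel_seqs:
        if target_species != species:
            continue
        insert_at = cfg.flank_len // 2  # inside the left flank, clear of the primer
        seq = seq[:insert_at] + ins + seq[insert_at:]
        shift = len(ins)
        expected = [STRRegion(r.start + shift, r.end + shift, r.motif,
                              r.unit_size, r.repeat_count) for r in expected]
    return seq, [r for r in expected if r.repeat_count >= 4]


def make_ortholog_pair(cfg: MarkerConfig, seed: int | np.random.Generator) -> MarkerTruth:
    """Construct one marker's ortholog pair, primer pair, and truth record.

    The assembled amplicons are re-scanned with the production detector and
    generation is retried until detection recovers exactly the planted
    regions (at the 4-repeat threshold) in both species.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(60):
        left = _random_chunk(rng, cfg.flank_len)
        right = _random_chunk(rng, cfg.flank_len)
        counts_pairs = list(zip(cfg.repeats_chimp, cfg.repeats_human))
        first_motif = next((m for m, (c, h) in zip(cfg.motifs, counts_pairs)
                            if c > 0 or h > 0), None)
        last_motif = next((m for m, (c, h) in reversed(list(zip(cfg.motifs, counts_pairs)))
                           if c > 0 or h > 0), None)
        left = _fix_edge(left, first_motif[-1] if first_motif else None, None, rng)
        right = _fix_edge(right, None, last_motif[0] if last_motif else None, rng)
        spacer_seqs = []
        for i, gap in enumerate(cfg.spacers):
            sp_chunk = _random_chunk(rng, gap)
            sp_chunk = _fix_edge(sp_chunk, cfg.motifs[i + 1][-1],
                                 cfg.motifs[i][0], rng)
            spacer_seqs.append(sp_chunk)
        indel_seqs = [(species, _random_chunk(rng, size))
                      for species, size in cfg.indels]

        amplicons, structures, ok = {}, {}, True
        for sp in ("chimpanzee", "human"):
            seq, expected = _build_species_amplicon(cfg, sp, left, right,
                                                    spacer_seqs, rng, indel_seqs)
            detected = find_str_regions(seq, min_repeats=4)
            if list(detected.regions) != expected:
                ok = False
                break
            amplicons[sp] = seq
            structures[sp] = detected
        if not ok:
            continue

        forward = amplicons["human"][:PRIMER_LEN]
        reverse = revcomp(amplicons["human"][-PRIMER_LEN:])
        # primer sites are in shared flank: confirm they sit in both amplicons
        if not (amplicons["chimpanzee"].startswith(forward)
                and amplicons["chimpanzee"].endswith(revcomp(reverse))):
            continue
        if any(amplicons[sp].count(forward) != 1
               or amplicons[sp].count(revcomp(reverse)) != 1
               for sp in amplicons):
            continue

        extra = {"none": 0, "P": 7, "M": 1}[cfg.mod_flag]
        tail = {0: "", 7: PIGTAIL, 1: "A"}[extra]
        pp = PrimerPair(
            marker_name=cfg.name,
            forward=(tail + forward) if cfg.mod_primer == "forward" else forward,
            reverse=(tail + reverse) if cfg.mod_primer == "reverse" else reverse,
            forward_extra_bp=extra if cfg.mod_primer == "forward" else 0,
            reverse_extra_bp=extra if cfg.mod_primer == "reverse" else 0,
            merge_offset=cfg.merge_offset)

        references = {}
        for sp in ("chimpanzee", "human"):
            pad_l = _random_chunk(rng, PAD_LEN)
            pad_r = _random_chunk(rng, PAD_LEN)
            amp = amplicons[sp]
            if sp == "chimpanzee" and cfg.scenario != SCENARIO_OK:
                amp = _apply_scenario(cfg, amp, forward, rng)
            references[sp] = pad_l + amp + pad_r

        # The primer-scan thresholds tolerate short degenerate matches, so a
        # random flank can by chance host a spurious hit; re-draw until each
        # reference carries exactly the hit pattern its scenario calls for.
        # This makes every marker's decision-tree branch seed-independent.
        if not _verify_primer_sites(pp, references, cfg.scenario):
            continue

        extras = extra  # at most one primer is modified
        adjusted = {sp: len(amplicons[sp]) + extras - cfg.merge_offset
                    for sp in amplicons}
        indel_totals = {"chimpanzee": sum(s for spp, s in cfg.indels if spp == "chimpanzee"),
                        "human": sum(s for spp, s in cfg.indels if spp == "human")}
        units = {len(m) for m, (c, h) in zip(cfg.motifs, counts_pairs) if c > 0 or h > 0}
        varying_unit = len(cfg.motifs[0])
        ref_totals = {"chimpanzee": sum(cfg.repeats_chimp),
                      "human": sum(cfg.repeats_human)}
        supports = {
            "chimpanzee": cfg.support_chimp or (max(1, ref_totals["chimpanzee"] - 2),
                                                ref_totals["chimpanzee"] + 2),
            "human": cfg.support_human or (max(1, ref_totals["human"] - 2),
                                           ref_totals["human"] + 2),
        }
        return MarkerTruth(cfg, pp, amplicons, references, structures, adjusted,
                           indel_totals, varying_unit, ref_totals, supports)
    raise RuntimeError(f"{cfg.name}: could not assemble a self-consistent ortholog pair")


_SCENARIO_CHIMP_HITS = {
    SCENARIO_OK: (1, 1),              # (forward + strand, reverse - strand)
    SCENARIO_NO_HIT: (0, 1),
    SCENARIO_LENGTH_FAR: (1, 1),
    SCENARIO_SHARED_REVERSE: (2, 1),
    SCENARIO_MULTI_HIT: (2, 2),
}


def _verify_primer_sites(pp: PrimerPair, references: dict, scenario: str) -> bool:
    """True when each reference holds exactly the expected primer-hit counts."""
    for sp, ref in references.items():
        want = _SCENARIO_CHIMP_HITS[scenario] if sp == "chimpanzee" else (1, 1)
        fwd = [h for h in scan_primer(pp.forward, ref, tail_bp=pp.forward_extra_bp)
               if h.strand == "+"]
        rev = [h for h in scan_primer(pp.reverse, ref, tail_bp=pp.reverse_extra_bp)
               if h.strand == "-"]
        if (len(fwd), len(rev)) != want:
            return False
    return True


def _apply_scenario(cfg: MarkerConfig, amplicon: str, forward: str,
                    rng: np.random.Generator) -> str:
    if cfg.scenario == SCENARIO_NO_HIT:
        # obliterate the forward primer site
        return _random_chunk(rng, PRIMER_LEN) + amplicon[PRIMER_LEN:]
    if cfg.scenario == SCENARIO_LENGTH_FAR:
        # reference carries a 40-bp insertion the genotyped samples lack
        at = cfg.flank_len - 10
        return amplicon[:at] + _random_chunk(rng, 40) + amplicon[at:]
    if cfg.scenario == SCENARIO_SHARED_REVERSE:
        # second forward-primer site upstream: two overlapping candidates
        # sharing the reverse primer position
        return forward + _random_chunk(rng, 12) + amplicon
    if cfg.scenario == SCENARIO_MULTI_HIT:
        # whole duplicated amplicon downstream: two independent candidates
        return amplicon + _random_chunk(rng, 30) + amplicon
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def _double_geometric(lo: int, hi: int, center: float, q: float = 0.5) -> np.ndarray:
    ks = np.arange(lo, hi + 1)
    w = q ** np.abs(ks - np.clip(center, lo, hi))
    return w / w.sum()


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    species: str
    n_individuals: int


def simulate_genotypes(markers: list[MarkerTruth], pops: list[PopulationSpec],
                       f_drift: float, seed: int,
                       base_freqs: dict[tuple[str, str], np.ndarray] | None = None,
                       missing_rate: float = 0.0,
                       pin_ranges: bool = True) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Simulate diploid genotypes; returns (length dataset, repeat dataset).

    Population repeat frequencies are Dirichlet draws with concentration
    p_base * (1-F)/F around the species base distribution (double-geometric
    over the configured support unless ``base_freqs`` overrides it, keyed by
    (marker, species)).  Repeat numbers are converted to fragment lengths via
    each species' reference calibration, so planted flank offsets propagate
    into lengths.  With ``pin_ranges`` the first individual of each species
    carries the support endpoints, making the observed range equal the
    configured support (the study conditions fix the ranges the decision
    trees see).
    """
    if not (0.0 < f_drift < 1.0):
        raise ValueError("F_drift must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    individuals, populations, species = [], [], []
    for p in pops:
        for i in range(p.n_individuals):
            individuals.append(f"{p.name}_{i:03d}")
            populations.append(p.name)
            species.append(p.species)
    n_ind = len(individuals)
    loci = [t.config.name for t in markers]
    lengths = np.full((n_ind, len(loci), 2), np.nan)
    repeats = np.full((n_ind, len(loci), 2), np.nan)

    conc = (1.0 - f_drift) / f_drift
    row = 0
    pop_rows = {}
    for p in pops:
        pop_rows[p.name] = (row, row + p.n_individuals)
        row += p.n_individuals

    for j, truth in enumerate(markers):
        for sp in ("chimpanzee", "human"):
            lo, hi = truth.supports[sp]
            ks = np.arange(lo, hi + 1)
            if base_freqs and (truth.config.name, sp) in base_freqs:
                base = np.asarray(base_freqs[(truth.config.name, sp)], dtype=float)
                if base.size != ks.size:
                    raise ValueError("base frequency vector does not match support")
            else:
                base = _double_geometric(lo, hi, truth.ref_totals[sp])
            first_of_species = True
            for p in pops:
                if p.species != sp:
                    continue
                freq = rng.dirichlet(np.maximum(base * conc, 1e-9)) if ks.size > 1 \
                    else np.array([1.0])
                r0, r1 = pop_rows[p.name]
                draw = rng.choice(ks, size=(r1 - r0, 2), p=freq)
                if pin_ranges and first_of_species and ks.size > 1:
                    draw[0] = (lo, hi)
                    first_of_species = False
                repeats[r0:r1, j, :] = draw
                lengths[r0:r1, j, :] = truth.adjusted_lengths[sp] \
                    + (draw - truth.ref_totals[sp]) * truth.varying_unit
        if missing_rate > 0:
            miss = rng.random(n_ind) < missing_rate
            lengths[miss, j, :] = np.nan
            repeats[miss, j, :] = np.nan

    length_ds = GenotypeDataset(individuals, populations, species, loci,
                                lengths, "length")
    repeat_ds = GenotypeDataset(individuals, populations, species, loci,
                                repeats, "repeats")
    return length_ds, repeat_ds


def stepwise_mutate(repeat_alleles: np.ndarray, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One round of symmetric single-step mutation on a repeat-number array."""
    out = repeat_alleles.copy()
    mask = (~np.isnan(out)) & (rng.random(out.shape) < rate)
    steps = rng.choice([-1, 1], size=out.shape)
    out[mask] += steps[mask]
    return np.maximum(out, 1)


def default_study_configs() -> list[MarkerConfig]:
    """One marker per decision-tree branch and per structure-concordance class."""
    return [
        MarkerConfig("M_RET", motifs=("GATA",), repeats_chimp=(10,), repeats_human=(12,)),
        MarkerConfig("M_PIG", motifs=("TCTA",), repeats_chimp=(9,), repeats_human=(11,),
                     mod_flag="P", mod_primer="reverse"),
        MarkerConfig("M_ADE", motifs=("CA",), repeats_chimp=(12,), repeats_human=(14,),
                     mod_flag="M", mod_primer="forward", merge_offset=2),
        MarkerConfig("M_NOHIT", scenario=SCENARIO_NO_HIT),
        MarkerConfig("M_FAR", scenario=SCENARIO_LENGTH_FAR),
        MarkerConfig("M_OVL", scenario=SCENARIO_SHARED_REVERSE),
        MarkerConfig("M_MULTI", scenario=SCENARIO_MULTI_HIT),
        MarkerConfig("M_IDENT", repeats_chimp=(12,), repeats_human=(12,),
                     support_chimp=(10, 14), support_human=(10, 14)),
        MarkerConfig("M_CSUB", repeats_chimp=(12,), repeats_human=(12,),
                     support_chimp=(11, 13), support_human=(9, 15)),
        MarkerConfig("M_HSUB", repeats_chimp=(12,), repeats_human=(12,),
                     support_chimp=(9, 15), support_human=(11, 13)),
        MarkerConfig("M_PLOW", repeats_chimp=(11,), repeats_human=(13,),
                     support_chimp=(9, 13), support_human=(11, 15)),
        MarkerConfig("M_PHIGH", repeats_chimp=(13,), repeats_human=(12,),
                     support_chimp=(11, 15), support_human=(9, 13)),
        MarkerConfig("M_DISJ", repeats_chimp=(8,), repeats_human=(16,),
                     support_chimp=(6, 9), support_human=(14, 18)),
        # criterion ii: chimp reference outside its own range but inside the union
        MarkerConfig("M_CRIT2", repeats_chimp=(16,), repeats_human=(16,),
                     support_chimp=(12, 15), support_human=(12, 18)),
        # criterion iii pass: chimp reference 1 repeat unit below the union, high ROS
        MarkerConfig("M_CRIT3", repeats_chimp=(9,), repeats_human=(12,),
                     support_chimp=(10, 15), support_human=(10, 16)),
        # criterion iii fail: low ROS, chimp reference below the union
        MarkerConfig("M_FAIL3", repeats_chimp=(9,), repeats_human=(12,),
                     support_chimp=(10, 11), support_human=(11, 18)),
        # structure-concordance classes; wide observed ranges keep these loci
        # past the length criteria so the structure comparison is what excludes
        # or classifies them
        MarkerConfig("M_3REP", repeats_chimp=(3,), repeats_human=(11,),
                     support_chimp=(3, 12), support_human=(9, 13)),
        MarkerConfig("M_2REP", repeats_chimp=(2,), repeats_human=(10,),
                     support_chimp=(2, 11), support_human=(8, 12)),
        MarkerConfig("M_DISR", repeats_chimp=(11,), repeats_human=(11,),
                     disruption=("chimpanzee", 0)),
        MarkerConfig("M_NOSTR", repeats_chimp=(0,), repeats_human=(10,),
                     support_chimp=(1, 12), support_human=(7, 13)),
        MarkerConfig("M_MIXED", motifs=("GATA", "CA"), repeats_chimp=(8, 6),
                     repeats_human=(8, 6), spacers=(9,)),
        # planted flank insertion: the inflation mechanism
        MarkerConfig("M_INDEL", repeats_chimp=(10,), repeats_human=(12,),
                     indels=(("human", 8),)),
    ]


def concordant_panel_configs(n_loci: int = 40, max_indel: int = 32,
                        mean_offset: int = 2, indel_fraction: float = 0.5,
                        seed: int = 0) -> list[MarkerConfig]:
    """A concordant-locus panel mirroring the study conditions.

    Single tetranucleotide STR per locus, the chimpanzee array shorter by
    ``mean_offset`` repeats on average, and a species-specific flank insertion
    of 0-``max_indel`` bp planted at ``indel_fraction`` of the loci.
    """
    rng = np.random.default_rng(seed)
    motifs = ["GATA", "TCTA", "AGAT", "CTAT", "TAGA"]
    configs = []
    for i in range(n_loci):
        human_reps = int(rng.integers(10, 17))
        chimp_reps = max(4, human_reps - mean_offset + int(rng.integers(-1, 2)))
        indels = ()
        if rng.random() < indel_fraction:
            size = int(rng.integers(4, max_indel + 1))
            species = "human" if rng.random() < 0.5 else "chimpanzee"
            indels = ((species, size),)
        configs.append(MarkerConfig(
            name=f"L{i:03d}", motifs=(motifs[i % len(motifs)],),
            repeats_chimp=(chimp_reps,), repeats_human=(human_reps,),
            indels=indels,
            support_chimp=(max(2, chimp_reps - 3), chimp_reps + 3),
            support_human=(max(2, human_reps - 3), human_reps + 3)))
    return configs


def make_study(configs: list[MarkerConfig] | None = None, seed: int = 17,
               pops: list[PopulationSpec] | None = None, f_drift: float = 0.05,
               distances: dict[str, float] | None = None,
               missing_rate: float = 0.0) -> StudyBundle:
    """Build a complete self-contained study fixture with known ground truth."""
    configs = configs if configs is not None else default_study_configs()
    rng = np.random.default_rng(seed)
    markers = [make_ortholog_pair(cfg, rng) for cfg in configs]
    if pops is None:
        pops = [PopulationSpec("ChimpWest", "chimpanzee", 20),
                PopulationSpec("ChimpEast", "chimpanzee", 20),
                PopulationSpec("HumAfrica", "human", 20),
                PopulationSpec("HumEurope", "human", 20),
                PopulationSpec("HumEAsia", "human", 20),
                PopulationSpec("HumAmerica", "human", 20)]
    geno_seed = int(rng.integers(0, 2 ** 31 - 1))
    lengths, repeats = simulate_genotypes(markers, pops, f_drift, geno_seed,
                                          missing_rate=missing_rate)
    if distances is None:
        distances = {}
        km = 0.0
        for p in pops:
            if p.species == "human":
                distances[p.name] = km
                km += 4000.0
    dist = {name: PopulationDistance(name, d) for name, d in distances.items()}
    return StudyBundle(markers, lengths, repeats,
                       [t.primer_pair for t in markers], dist, seed)
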