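"""Detection and cross-species comparison of STR regions inside amplicons.

An STR region is a run of at least ``min_repeats`` contiguous copies of a
2-6 nt motif.  Any interruption, even a single base, terminates a region;
runs on either side of an interruption are reported separately provided each
meets the repeat minimum.  Motifs are always reported at their minimal unit
size (a candidate whose motif is itself a whole-number repetition of a
shorter motif is covered by the shorter unit).  Homopolymer runs are never
reported (unit size 1 is excluded by construction).

Overlapping candidate calls with distinct motifs are resolved
deterministically: longer span wins, then smaller unit size, then leftmost
start.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import (STRRegion, STRStructure, _check_dna, is_motif_reducible,
                    motif_rotations, rotation_equivalent)

DEFAULT_UNIT_SIZES = (2, 3, 4, 5, 6)

# concordance classes
IDENTICAL = "identical"
THREE_REPEAT = "three_repeat_variant"
TWO_REPEAT = "two_repeat_variant"
DISRUPTED = "disrupted_variant"
DISCORDANT = "discordant"
NO_STR = "no_str"

# maximum interruption (nt) between two sub-regions for a one-vs-two split to
# be called a disruption (point mutation or small indel) rather than discordant
DISRUPTION_GAP_NT = 6


@dataclass(frozen=True)
class StructureConcordance:
    """Outcome of comparing the STR structures of two putative orthologs."""

    concordance: str       # one of the class constants above
    affected_species: str  # 'human', 'chimpanzee', 'both', or 'none'
    detail: str = ""

    def __post_init__(self):
        none_ok = self.concordance in (IDENTICAL, NO_STR)
        if (self.affected_species == "none") != none_ok:
            raise ValueError("affected_species must be 'none' exactly for "
                             "identical/no_str outcomes")


def _candidate_runs(seq: str, min_repeats: int, unit_sizes) -> list[STRRegion]:
    """All maximal leftmost-phase runs of >= min_repeats copies of a primitive motif."""
    n = len(seq)
    out = []
    for u in sorted(unit_sizes):
        if u < 2 or u > 6:
            raise ValueError("unit sizes must be within 2..6")
        if n < u * min_repeats:
            continue
        # match[i] true when position i continues the periodicity at lag u
        i = 0
        limit = n - u
        while i < limit:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            s = i
            while i < limit and seq[i] == seq[i + u]:
                i += 1
            seg_end = i + u  # maximal periodic segment seq[s:seg_end)
            # every phase of the segment is a maximal run of a rotated motif;
            # all are emitted as candidates because overlap resolution may clip
            # the leftmost phase against a longer neighbouring region while a
            # shifted phase still fits
            for d in range(u):
                count = (seg_end - s - d) // u
                if count < min_repeats:
                    continue
                motif = seq[s + d:s + d + u]
                if not is_motif_reducible(motif):
                    out.append(STRRegion(start=s + d, end=s + d + count * u,
                                         motif=motif, unit_size=u,
                                         repeat_count=count))
    return out


def _resolve_overlaps(candidates: list[STRRegion]) -> list[STRRegion]:
    ordered = sorted(candidates,
                     key=lambda r: (-(r.end - r.start), r.unit_size, r.start))
    kept: list[STRRegion] = []
    for cand in ordered:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda r: r.start)


def find_str_regions(sequence: str, min_repeats: int = 4,
                     unit_sizes=DEFAULT_UNIT_SIZES) -> STRStructure:
    """Locate every STR region in ``sequence``.

    Returns an :class:`STRStructure` with regions sorted by start position
    and spacer lengths between consecutive regions.
    """
    seq = _check_dna(sequence)
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    candidates = _candidate_runs(seq, min_repeats, unit_sizes)
    return STRStructure.from_regions(_resolve_overlaps(candidates))


def harmonize_boundaries(structure: STRStructure, sequence: str) -> STRStructure:
    """Re-phase regions with rotationally equivalent motifs onto a common motif.

    Multiple STR regions may descend from one interrupted ancestral array, in
    which case their motifs are rotations of each other (e.g. ATCT / TCTA).
    Where a phase shift within the sequence preserves a region's repeat count,
    later regions are shifted to use the first such region's motif.  No-op
    where impossible.
    """
    seq = sequence.upper()
    regions = list(structure.regions)
    canonical: dict[frozenset, str] = {}
    for idx, reg in enumerate(regions):
        rot_class = frozenset(motif_rotations(reg.motif))
        target = canonical.setdefault(rot_class, reg.motif)
        if reg.motif == target:
            continue
        u, c = reg.unit_size, reg.repeat_count
        best = None
        for d in sorted(range(-(u - 1), u), key=abs):
            ns, ne = reg.start + d, reg.end + d
            if ns < 0 or ne > len(seq):
                continue
            if seq[ns:ne] != target * c:
                continue
            prev_end = regions[idx - 1].end if idx > 0 else 0
            next_start = regions[idx + 1].start if idx + 1 < len(regions) else len(seq)
            if ns >= prev_end and ne <= next_start:
                best = d
                break
        if best is not None:
            regions[idx] = STRRegion(start=reg.start + best, end=reg.end + best,
                                     motif=target, unit_size=u, repeat_count=c)
    return STRStructure.from_regions(regions)


def total_repeats(structure: STRStructure) -> int:
    """Sum of repeat counts over all regions (0 for an empty structure)."""
    return sum(r.repeat_count for r in structure.regions)


def _probe_short_run(seq: str, span: tuple[int, int], motif: str,
                     slop: int = 3) -> int:
    """Largest count (>=2) of a rotation of ``motif`` inside seq[span] +/- slop.

    Used to look for 2-3-repeat remnants of a region the other species carries
    at full length.  Returns 0 when nothing is found.
    """
    lo = max(0, span[0] - slop)
    hi = min(len(seq), span[1] + slop)
    sub = seq[lo:hi]
    structure = find_str_regions(sub, min_repeats=2, unit_sizes=(len(motif),)) \
        if len(sub) >= 2 * len(motif) else STRStructure()
    best = 0
    for reg in structure.regions:
        if rotation_equivalent(reg.motif, motif):
            best = max(best, reg.repeat_count)
    return best


def compare_structures(chimp: STRStructure, human: STRStructure,
                       chimp_seq: str, human_seq: str,
                       alignment) -> StructureConcordance:
    """Classify the concordance of two species' STR structures.

    ``alignment`` is an :class:`orthosat.flankalign.OrthologAlignment` over
    the same sequences; it supplies the coordinate correspondence used to
    pair regions and to probe for 2-3-repeat remnants opposite a region that
    only reaches the 4-repeat detection threshold in one species.
    """
    if not chimp.regions and not human.regions:
        return StructureConcordance(NO_STR, "none", "no STR region in either species")

    chimp_regs = list(chimp.regions)
    human_regs = list(human.regions)

    # pair regions whose aligned spans overlap
    links: list[tuple[int, int]] = []
    for ci, cr in enumerate(chimp_regs):
        h_span = alignment.map_interval("chimpanzee", cr.start, cr.end)
        for hi_, hr in enumerate(human_regs):
            if h_span[0] < hr.end and hr.start < h_span[1]:
                links.append((ci, hi_))

    c_links = {ci: [h for c, h in links if c == ci] for ci in range(len(chimp_regs))}
    h_links = {hi_: [c for c, h in links if h == hi_] for hi_ in range(len(human_regs))}

    findings: list[tuple[str, str, str]] = []  # (class, affected, detail)

    def roteq(a, b):
        return rotation_equivalent(a, b)

    consumed_c, consumed_h = set(), set()

    # one region in one species opposite two in the other: disruption candidate
    for hi_, cs in h_links.items():
        if len(cs) == 2 and all(len(c_links[c]) == 1 for c in cs):
            c1, c2 = sorted(cs)
            gap = chimp_regs[c2].start - chimp_regs[c1].end
            if (roteq(chimp_regs[c1].motif, human_regs[hi_].motif)
                    and roteq(chimp_regs[c2].motif, human_regs[hi_].motif)
                    and 0 < gap <= DISRUPTION_GAP_NT):
                findings.append((DISRUPTED, "chimpanzee",
                                 f"human region {human_regs[hi_].motif} split in chimpanzee "
                                 f"by a {gap}-nt interruption"))
                consumed_c.update(cs)
                consumed_h.add(hi_)
    for ci, hs in c_links.items():
        if ci in consumed_c:
            continue
        if len(hs) == 2 and all(len(h_links[h]) == 1 for h in hs):
            h1, h2 = sorted(hs)
            gap = human_regs[h2].start - human_regs[h1].end
            if (roteq(human_regs[h1].motif, chimp_regs[ci].motif)
                    and roteq(human_regs[h2].motif, chimp_regs[ci].motif)
                    and 0 < gap <= DISRUPTION_GAP_NT):
                findings.append((DISRUPTED, "human",
                                 f"chimpanzee region {chimp_regs[ci].motif} split in human "
                                 f"by a {gap}-nt interruption"))
                consumed_h.update(hs)
                consumed_c.add(ci)

    # one-to-one pairs
    for ci, hs in c_links.items():
        if ci in consumed_c:
            continue
        if len(hs) == 1 and len(h_links[hs[0]]) == 1:
            hi_ = hs[0]
            cr, hr = chimp_regs[ci], human_regs[hi_]
            consumed_c.add(ci)
            consumed_h.add(hi_)
            if not roteq(cr.motif, hr.motif) or cr.unit_size != hr.unit_size:
                findings.append((DISCORDANT, "both",
                                 f"different motifs expanded at the same aligned "
                                 f"position ({cr.motif}/{hr.motif})"))
        elif len(hs) >= 1:
            # tangled many-to-many pairing that is not a clean disruption
            consumed_c.add(ci)
            consumed_h.update(hs)
            findings.append((DISCORDANT, "both", "unalignable region sets"))

    # regions detected in only one species: probe the other for a short remnant
    for ci, cr in enumerate(chimp_regs):
        if ci in consumed_c:
            continue
        span = alignment.map_interval("chimpanzee", cr.start, cr.end)
        count = _probe_short_run(human_seq, span, cr.motif)
        if count == 3:
            findings.append((THREE_REPEAT, "human",
                             f"{cr.motif} region has only 3 repeats in human"))
        elif count == 2:
            findings.append((TWO_REPEAT, "human",
                             f"{cr.motif} region has only 2 repeats in human"))
        else:
            if not human_regs:
                findings.append((NO_STR, "human", "no STR region in human fragment"))
            else:
                findings.append((DISCORDANT, "both",
                                 f"chimpanzee {cr.motif} region has no human counterpart"))
    for hi_, hr in enumerate(human_regs):
        if hi_ in consumed_h:
            continue
        span = alignment.map_interval("human", hr.start, hr.end)
        count = _probe_short_run(chimp_seq, span, hr.motif)
        if count == 3:
            findings.append((THREE_REPEAT, "chimpanzee",
                             f"{hr.motif} region has only 3 repeats in chimpanzee"))
        elif count == 2:
            findings.append((TWO_REPEAT, "chimpanzee",
                             f"{hr.motif} region has only 2 repeats in chimpanzee"))
        else:
            if not chimp_regs:
                findings.append((NO_STR, "chimpanzee", "no STR region in chimpanzee fragment"))
            else:
                findings.append((DISCORDANT, "both",
                                 f"human {hr.motif} region has no chimpanzee counterpart"))

    precedence = [DISCORDANT, DISRUPTED, TWO_REPEAT, THREE_REPEAT, NO_STR]
    for cls in precedence:
        hits = [f for f in findings if f[0] == cls]
        if hits:
            affected = {f[1] for f in hits}
            who = affected.pop() if len(affected) == 1 else "both"
            if cls == NO_STR:
                who = "none"
            return StructureConcordance(cls, who, "; ".join(f[2] for f in hits))
    return StructureConcordance(IDENTICAL, "none",
                                f"{len(chimp_regs)} concordant region(s)")
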