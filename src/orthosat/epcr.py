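"""In-silico PCR: primer scanning, amplicon demarcation, and retention logic.

The scan emulates a BLASTN-style primer search with the two acceptance
thresholds the pipeline is built around: a hit may be up to 10 nt shorter
than the (genomic) primer in alignment length and must reach at least 90%
sequence identity.  The engine is an exhaustive ungapped diagonal scan:
every reference offset is tried and, per diagonal, every contiguous
sub-segment of the primer is assessed against the thresholds.  Primers are
short (<= ~30 nt), so this is exact and fast without gap modelling; an indel
inside such a short site is indistinguishable under the two thresholds from
end-trimming the alignment.

Fragment lengths follow the 5'-to-5' convention, counted inclusively: the
amplicon spans both primers, so ``raw_length = reverse 5' position - forward
5' position + 1``.  The inclusive convention is isolated in
:func:`_five_prime_distance` so the exclusive alternative is a one-line change.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (EPCRFragment, LengthRange, PrimerHit, PrimerPair,
                    _check_dna, revcomp)

MAX_AMPLICON_BP = 2000      # hard cap on plausible amplicon size
MAX_LENGTH_SHORTFALL = 10   # primer_length - alignment_length <= 10
MIN_IDENTITY = 0.90
DEFAULT_SLACK_BP = 6        # retention window around the observed length range

OUTCOME_RETAINED = "retained"
OUTCOME_REJECTED_LENGTH = "rejected_length"
OUTCOME_REJECTED_NO_HIT = "rejected_no_hit"
OUTCOME_REJECTED_MULTI_HIT = "rejected_multi_hit"
OUTCOME_RESOLVED_OVERLAP = "resolved_overlap"


@dataclass(frozen=True)
class EPCRDecision:
    """Per-marker outcome of the amplicon identification decision tree."""

    marker: str
    outcome: str
    chosen_fragment: Optional[EPCRFragment]
    candidates_considered: int
    margin_bp: Optional[int] = None

    def __post_init__(self):
        chosen_ok = self.outcome in (OUTCOME_RETAINED, OUTCOME_RESOLVED_OVERLAP)
        if (self.chosen_fragment is not None) != chosen_ok:
            raise ValueError("chosen_fragment present iff retained/resolved_overlap")


def _diagonal_best_segment(matches: np.ndarray, primer_len: int):
    """Best accepted (length, identity) sub-segment of one ungapped diagonal.

    Enumerates every contiguous window of the boolean match vector; among the
    windows satisfying both thresholds, prefers longer alignment, then higher
    identity.  Returns (aln_len, identity) or None.
    """
    m = matches.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(m)])
    n = len(m)
    min_len = max(1, primer_len - MAX_LENGTH_SHORTFALL)
    best = None
    for length in range(n, min_len - 1, -1):
        window_matches = csum[length:] - csum[:-length]
        if window_matches.size == 0:
            continue
        top = window_matches.max()
        ident = top / length
        if ident >= MIN_IDENTITY:
            cand = (length, ident)
            if best is None or cand > best:
                best = cand
            break  # longer is preferred; first (longest) accepted wins
    return best


def scan_primer(primer: str, reference: str, chromosome: str = "ref",
                tail_bp: int = 0) -> list[PrimerHit]:
    """Locate acceptable alignments of a primer on both strands of a reference.

    ``tail_bp`` non-genomic bases at the primer's 5' end (pig-tail or extra
    adenine) take part in the scan but are excluded from the alignment-length
    assessment.  A hit is accepted iff primer_length - alignment_length <= 10
    and identity >= 0.90.  The 5'-terminal genomic position of the aligned
    primer is reported 1-based.
    """
    primer = _check_dna(primer, "primer")
    reference = _check_dna(reference, "reference")
    if len(primer) < 15:
        raise ValueError("primer shorter than 15 nt")
    genomic = primer[tail_bp:] if tail_bp else primer
    p_l = len(genomic)

    hits: list[PrimerHit] = []
    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    for strand in ("+", "-"):
        query = genomic if strand == "+" else revcomp(genomic)
        q_arr = np.frombuffer(query.encode(), dtype="S1")
        L = len(reference) - p_l
        for offset in range(L + 1):
            matches = ref_arr[offset:offset + p_l] == q_arr
            best = _diagonal_best_segment(matches, p_l)
            if best is None:
                continue
            aln_len, ident = best
            if strand == "+":
                five_prime = offset + 1
            else:
                five_prime = offset + p_l  # rightmost base of the revcomp match
            hits.append(PrimerHit(chromosome=chromosome, strand=strand,
                                  five_prime_pos=five_prime,
                                  alignment_length=aln_len, identity=float(ident),
                                  primer_length=p_l))
    return hits


def _five_prime_distance(forward_pos: int, reverse_pos: int) -> int:
    # inclusive 5'-to-5' span: the amplicon covers both primer 5' termini
    return reverse_pos - forward_pos + 1


def demarcate_fragments(forward_hits: list[PrimerHit], reverse_hits: list[PrimerHit],
                        reference: str, marker: str, species: str = "") -> list[EPCRFragment]:
    """Pair forward (+ strand) and reverse (- strand) hits into candidate amplicons.

    Pairs in invalid orientation or implying an amplicon above the plausibility
    cap are discarded; an empty result is allowed.
    """
    fragments = []
    for fh in forward_hits:
        if fh.strand != "+":
            continue
        for rh in reverse_hits:
            if rh.strand != "-" or rh.chromosome != fh.chromosome:
                continue
            raw = _five_prime_distance(fh.five_prime_pos, rh.five_prime_pos)
            if raw <= 0 or raw > MAX_AMPLICON_BP:
                continue
            start0 = fh.five_prime_pos - 1
            seq = reference[start0:start0 + raw] if reference else ""
            fragments.append(EPCRFragment(
                marker_name=marker, chromosome=fh.chromosome, sequence=seq,
                raw_length=raw, adjusted_length=raw, species=species, start=start0))
    return fragments


def adjust_length(fragment: EPCRFragment, primer_pair: PrimerPair,
                  merge_correction: int | None = None) -> int:
    """Adjusted fragment length in bp.

    Non-genomic primer additions (7-bp pig-tail / 1 extra adenine) are added
    so the in-silico length is comparable with sized PCR products; the merge
    correction that was applied to the genotype data is reversed (subtracted).
    """
    if merge_correction is None:
        merge_correction = primer_pair.merge_offset
    return (fragment.raw_length + primer_pair.forward_extra_bp
            + primer_pair.reverse_extra_bp - merge_correction)


def retention_filter(x: int, observed: LengthRange,
                     slack: int = DEFAULT_SLACK_BP) -> tuple[bool, int]:
    """Keep an adjusted length iff it lies within the observed range +/- slack.

    Returns (keep, margin) where margin is the distance of x from the nearest
    range bound, negative when x lies inside the range.
    """
    margin = max(observed.lo - x, x - observed.hi)
    return margin <= slack, margin


def resolve_candidates(fragments: list[EPCRFragment], primer_pair: PrimerPair,
                       observed: LengthRange | None, marker: str,
                       slack: int = DEFAULT_SLACK_BP) -> EPCRDecision:
    """Apply the full per-marker retention decision tree.

    No candidates -> rejected_no_hit.  Exactly two overlapping candidates
    sharing the reverse primer 5' position -> the smaller is chosen (it is the
    more efficiently amplified product) and then length-filtered.  A single
    length-passing candidate -> retained; several independent length-passing
    candidates -> rejected_multi_hit; all failing the length window ->
    rejected_length.
    """
    n = len(fragments)
    if n == 0 or observed is None:
        return EPCRDecision(marker, OUTCOME_REJECTED_NO_HIT, None, n)

    def adj(f: EPCRFragment) -> int:
        return adjust_length(f, primer_pair)

    overlap_resolved = False
    if n == 2:
        f1, f2 = fragments
        rev1 = f1.start + f1.raw_length
        rev2 = f2.start + f2.raw_length
        overlapping = f1.start < f2.start + f2.raw_length and f2.start < f1.start + f1.raw_length
        if rev1 == rev2 and f1.chromosome == f2.chromosome and overlapping:
            chosen = min(fragments, key=lambda f: f.raw_length)
            keep, margin = retention_filter(adj(chosen), observed, slack)
            if keep:
                return EPCRDecision(marker, OUTCOME_RESOLVED_OVERLAP, chosen, n, margin)
            return EPCRDecision(marker, OUTCOME_REJECTED_LENGTH, None, n, margin)

    passing = []
    margins = []
    for f in fragments:
        keep, margin = retention_filter(adj(f), observed, slack)
        margins.append(margin)
        if keep:
            passing.append((f, margin))
    if len(passing) == 1:
        f, margin = passing[0]
        return EPCRDecision(marker, OUTCOME_RETAINED, f, n, margin)
    if len(passing) > 1:
        return EPCRDecision(marker, OUTCOME_REJECTED_MULTI_HIT, None, n)
    return EPCRDecision(marker, OUTCOME_REJECTED_LENGTH, None, n, min(margins))


def run_epcr(primer_pair: PrimerPair, reference: str, observed: LengthRange | None,
             species: str = "", chromosome: str = "ref",
             slack: int = DEFAULT_SLACK_BP) -> EPCRDecision:
    """Scan both primers, demarcate candidates, and resolve to a decision."""
    fwd_tail = primer_pair.forward_extra_bp and (7 if primer_pair.forward_extra_bp == 7 else 1)
    rev_tail = primer_pair.reverse_extra_bp and (7 if primer_pair.reverse_extra_bp == 7 else 1)
    fwd_hits = scan_primer(primer_pair.forward, reference, chromosome,
                           tail_bp=int(fwd_tail or 0))
    rev_hits = scan_primer(primer_pair.reverse, reference, chromosome,
                           tail_bp=int(rev_tail or 0))
    fwd_plus = [h for h in fwd_hits if h.strand == "+"]
    rev_minus = [h for h in rev_hits if h.strand == "-"]
    fragments = demarcate_fragments(fwd_plus, rev_minus, reference,
                                    primer_pair.marker_name, species)
    decision = resolve_candidates(fragments, primer_pair, observed,
                                  primer_pair.marker_name, slack)
    if decision.chosen_fragment is not None:
        f = decision.chosen_fragment
        adjusted = adjust_length(f, primer_pair)
        decision = EPCRDecision(
            decision.marker, decision.outcome,
            EPCRFragment(f.marker_name, f.chromosome, f.sequence, f.raw_length,
                         adjusted, f.species or species, f.start),
            decision.candidates_considered, decision.margin_bp)
    return decision
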