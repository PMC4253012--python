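"""In-silico PCR: primer scanning, demarcation, adjustment, decision tree."""
import numpy as np
import pytest

import orthosat as o
from orthosat import epcr
from orthosat.types import revcomp

from oracles import oracle_primer_site_accepted

RNG = np.random.default_rng(2024)
BASES = np.array(list("ACGT"))


def _random_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, size=n))


def test_exact_hit_both_strands():
    rng = np.random.default_rng(5)
    primer = _random_seq(20, rng)
    ref = _random_seq(80, rng) + primer + _random_seq(80, rng)
    plus = [h for h in o.scan_primer(primer, ref) if h.strand == "+"]
    exact = [h for h in plus if h.identity == 1.0]
    assert any(h.five_prime_pos == 81 and h.alignment_length == 20 for h in exact)
    # the same primer hits the reverse complement on the minus strand
    ref_rc = revcomp(ref)
    minus = [h for h in o.scan_primer(primer, ref_rc) if h.strand == "-"]
    # 5' of the minus-strand hit = rightmost base of the match, 1-based
    assert any(h.five_prime_pos == len(ref) - 80 and h.identity == 1.0
               for h in minus)


def test_primer_too_short():
    with pytest.raises(ValueError, match="shorter than 15"):
        o.scan_primer("ACGTACGTACGTAC", "ACGT" * 30)


def test_alignment_shortfall_boundary():
    """25-nt primer vs a site matching only a prefix: 14 contiguous matches can
    still reach both thresholds (window 15, identity 14/15 >= 0.9) while 13
    cannot; and a site at the reference end leaves no room for the primer."""
    rng = np.random.default_rng(11)
    primer = _random_seq(25, rng)

    def plant(n_match):
        site = primer[:n_match] + "".join(
            {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in primer[n_match:])
        return _random_seq(60, rng) + site + _random_seq(60, rng), site

    ref14, site14 = plant(14)
    assert oracle_primer_site_accepted(primer, site14)
    assert any(h.strand == "+" and h.five_prime_pos == 61
               for h in o.scan_primer(primer, ref14))

    ref13, site13 = plant(13)
    assert not oracle_primer_site_accepted(primer, site13)
    assert not any(h.strand == "+" and h.five_prime_pos == 61
                   for h in o.scan_primer(primer, ref13))

    # 11 trailing primer bases absent: reference ends with the 20-nt match,
    # so the 31-nt primer cannot be placed at all
    primer31 = _random_seq(31, rng)
    ref_end = _random_seq(100, rng) + primer31[:20]
    assert not [h for h in o.scan_primer(primer31, ref_end) if h.strand == "+"
                and h.five_prime_pos > 80]


def test_identity_boundary():
    rng = np.random.default_rng(13)
    primer = _random_seq(20, rng)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    # 2 mismatches spread out: full-length identity exactly 18/20 = 0.90
    site = list(primer)
    site[5], site[14] = flip[site[5]], flip[site[14]]
    ref = _random_seq(50, rng) + "".join(site) + _random_seq(50, rng)
    hit = [h for h in o.scan_primer(primer, ref)
           if h.strand == "+" and h.five_prime_pos == 51]
    assert hit and hit[0].alignment_length == 20 and hit[0].identity == 0.90


def test_scan_oracle_planted_mutations():
    """Acceptance decisions at a planted site equal the exhaustive window oracle."""
    rng = np.random.default_rng(99)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    checked_accept = checked_reject = 0
    for _ in range(100):
        p_len = int(rng.integers(18, 26))
        primer = _random_seq(p_len, rng)
        site = list(primer)
        n_mut = int(rng.integers(0, 7))
        for pos in rng.choice(p_len, size=n_mut, replace=False):
            site[pos] = flip[site[pos]]
        site = "".join(site)
        offset = int(rng.integers(10, 120))
        ref = _random_seq(offset, rng) + site + _random_seq(40, rng)
        expected = oracle_primer_site_accepted(primer, site)
        got = any(h.strand == "+" and h.five_prime_pos == offset + 1
                  for h in o.scan_primer(primer, ref))
        assert got == expected, (primer, site, n_mut)
        checked_accept += expected
        checked_reject += not expected
    assert checked_accept and checked_reject  # both outcomes exercised


def test_tail_excluded_from_assessment():
    rng = np.random.default_rng(21)
    genomic = _random_seq(20, rng)
    ref = _random_seq(40, rng) + genomic + _random_seq(40, rng)
    hits = [h for h in o.scan_primer("GTTTCTT" + genomic, ref, tail_bp=7)
            if h.strand == "+" and h.five_prime_pos == 41]
    assert hits and hits[0].alignment_length == 20 and hits[0].primer_length == 20


def _hit(strand, pos, chrom="ref"):
    return o.PrimerHit(chromosome=chrom, strand=strand, five_prime_pos=pos,
                       alignment_length=20, identity=1.0, primer_length=20)


def test_demarcation_arithmetic():
    ref = "A" * 400
    frags = epcr.demarcate_fragments([_hit("+", 101)], [_hit("-", 300)], ref, "m")
    assert len(frags) == 1 and frags[0].raw_length == 200
    assert frags[0].start == 100 and len(frags[0].sequence) == 200
    # reverse upstream of forward: discarded
    assert not epcr.demarcate_fragments([_hit("+", 300)], [_hit("-", 101)], ref, "m")
    # above the plausibility cap: discarded
    long_ref = "A" * 3000
    assert not epcr.demarcate_fragments([_hit("+", 1)], [_hit("-", 2500)],
                                        long_ref, "m")
    # different chromosomes never pair
    assert not epcr.demarcate_fragments([_hit("+", 101)],
                                        [_hit("-", 300, chrom="other")], ref, "m")


def _frag(raw, start=0, marker="m"):
    return o.EPCRFragment(marker, "ref", "", raw, raw, "human", start)


def test_adjust_length():
    pp_plain = o.PrimerPair("m", "ACGT" * 5, "ACGT" * 5)
    pp_pig = o.PrimerPair("m", "ACGT" * 5, "ACGT" * 5, reverse_extra_bp=7)
    pp_merge = o.PrimerPair("m", "ACGT" * 5, "ACGT" * 5, merge_offset=1)
    f = _frag(200)
    assert epcr.adjust_length(f, pp_plain) == 200
    assert epcr.adjust_length(f, pp_pig) == 207
    assert epcr.adjust_length(f, pp_merge) == 199
    assert epcr.adjust_length(f, pp_plain, merge_correction=2) == 198


def test_retention_filter_boundaries():
    observed = o.LengthRange(100, 110)
    assert epcr.retention_filter(116, observed) == (True, 6)
    assert epcr.retention_filter(117, observed) == (False, 7)
    assert epcr.retention_filter(94, observed) == (True, 6)
    keep, margin = epcr.retention_filter(105, observed)
    assert keep and margin < 0
    # a 27-bp-off reference length (the outlier scale) is always rejected
    assert epcr.retention_filter(137, observed) == (False, 27)


def test_retention_slack_monotone():
    rng = np.random.default_rng(3)
    observed = o.LengthRange(100, 120)
    for x in rng.integers(60, 160, size=200):
        for s in range(0, 12):
            keep_s, _ = epcr.retention_filter(int(x), observed, slack=s)
            keep_s1, _ = epcr.retention_filter(int(x), observed, slack=s + 1)
            assert keep_s <= keep_s1  # keeping can only grow with slack


PP = o.PrimerPair("m", "ACGT" * 5, "ACGT" * 5)
OBS = o.LengthRange(195, 205)


def test_resolve_no_candidates():
    d = epcr.resolve_candidates([], PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_REJECTED_NO_HIT and d.chosen_fragment is None


def test_resolve_single():
    d = epcr.resolve_candidates([_frag(200)], PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_RETAINED
    assert d.margin_bp < 0
    d = epcr.resolve_candidates([_frag(260)], PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_REJECTED_LENGTH and d.margin_bp == 55


def test_resolve_shared_reverse_overlap():
    # two overlapping candidates ending at the same reverse 5' position:
    # smaller product amplifies preferentially and is chosen
    small, large = _frag(200, start=32), _frag(232, start=0)
    d = epcr.resolve_candidates([large, small], PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_RESOLVED_OVERLAP
    assert d.chosen_fragment.raw_length == 200
    # but it must still pass the length window
    d = epcr.resolve_candidates([_frag(250, start=32), _frag(282, start=0)],
                                PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_REJECTED_LENGTH


def test_resolve_multi_hit():
    d = epcr.resolve_candidates([_frag(200, start=0), _frag(201, start=500)],
                                PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_REJECTED_MULTI_HIT
    # several candidates but only one in the window: retained
    d = epcr.resolve_candidates([_frag(200, start=0), _frag(400, start=500)],
                                PP, OBS, "m")
    assert d.outcome == epcr.OUTCOME_RETAINED


def test_decision_invariant():
    with pytest.raises(ValueError):
        epcr.EPCRDecision("m", epcr.OUTCOME_RETAINED, None, 1)
    with pytest.raises(ValueError):
        epcr.EPCRDecision("m", epcr.OUTCOME_REJECTED_LENGTH, _frag(200), 1)


def test_run_epcr_end_to_end():
    """A planted primer pair around a known insert recovers the construction length."""
    rng = np.random.default_rng(8)
    fwd = _random_seq(20, rng)
    rev_site = _random_seq(20, rng)
    insert = _random_seq(160, rng)
    amplicon = fwd + insert + rev_site
    ref = _random_seq(30, rng) + amplicon + _random_seq(30, rng)
    pp = o.PrimerPair("m", fwd, revcomp(rev_site))
    d = epcr.run_epcr(pp, ref, o.LengthRange(len(amplicon) - 3, len(amplicon) + 3))
    assert d.outcome == epcr.OUTCOME_RETAINED
    assert d.chosen_fragment.raw_length == len(amplicon) == 200
    assert d.chosen_fragment.sequence == amplicon
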