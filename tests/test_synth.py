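"""Synthetic-study generator: exact ground truth, determinism, scenarios."""
import numpy as np
import pytest

import orthosat as o
from orthosat import epcr, synth
from orthosat.strdetect import find_str_regions, harmonize_boundaries


def _regions(structure):
    return [(r.start, r.end, r.motif) for r in structure.regions]


def test_make_study_deterministic():
    a = o.make_study(seed=3)
    b = o.make_study(seed=3)
    assert a.genotypes == b.genotypes
    assert a.true_repeats == b.true_repeats
    for ta, tb in zip(a.markers, b.markers):
        assert ta.amplicons == tb.amplicons
        assert ta.references == tb.references
        assert ta.primer_pair == tb.primer_pair
    c = o.make_study(seed=4)
    assert any(ta.amplicons != tc.amplicons for ta, tc in zip(a.markers, c.markers))


def test_detection_matches_planted_structures(study):
    """The detector run on each amplicon recovers the planted structure exactly."""
    for truth in study.markers:
        for sp in ("chimpanzee", "human"):
            found = harmonize_boundaries(
                find_str_regions(truth.amplicons[sp], min_repeats=4),
                truth.amplicons[sp])
            assert _regions(found) == _regions(truth.structures[sp]), \
                (truth.config.name, sp)


def test_adjusted_length_arithmetic(study):
    for truth in study.markers:
        pp = truth.primer_pair
        extras = pp.forward_extra_bp + pp.reverse_extra_bp
        for sp in ("chimpanzee", "human"):
            want = len(truth.amplicons[sp]) + extras - pp.merge_offset
            assert truth.adjusted_lengths[sp] == want


def test_primers_flank_the_amplicon(study):
    from orthosat.types import revcomp
    for truth in study.markers:
        pp = truth.primer_pair
        for sp in ("chimpanzee", "human"):
            amp = truth.amplicons[sp]
            assert amp.startswith(pp.forward[pp.forward_extra_bp:])
            assert amp.endswith(revcomp(pp.reverse[pp.reverse_extra_bp:]))


def test_default_supports_are_ref_plus_minus_two():
    truth = o.make_ortholog_pair(o.MarkerConfig("t"), 5)
    assert truth.supports["chimpanzee"] == (8, 12)    # ref 10 +/- 2
    assert truth.supports["human"] == (10, 14)        # ref 12 +/- 2
    assert truth.ref_totals == {"chimpanzee": 10, "human": 12}
    assert truth.varying_unit == 4


def test_length_of_and_model_consistency():
    truth = o.make_ortholog_pair(o.MarkerConfig("t"), 5)
    m = truth.model("human")
    for k in range(10, 15):
        L = truth.length_of("human", k)
        assert o.length_to_repeats(L, m) == k


def test_simulate_genotypes_pinned_ranges(study):
    lengths, repeats = study.genotypes, study.true_repeats
    by_name = {t.config.name: t for t in study.markers}
    for j, locus in enumerate(repeats.loci):
        truth = by_name[locus]
        for sp in ("chimpanzee", "human"):
            mask = np.array([s == sp for s in repeats.species])
            vals = repeats.alleles[mask, j, :]
            vals = vals[~np.isnan(vals)]
            lo, hi = truth.supports[sp]
            assert vals.min() == lo and vals.max() == hi, (locus, sp)
            # lengths are the affine image of repeats under the species model
            lvals = lengths.alleles[mask, j, :]
            expect = truth.adjusted_lengths[sp] \
                + (repeats.alleles[mask, j, :] - truth.ref_totals[sp]) * truth.varying_unit
            np.testing.assert_allclose(lvals, expect)


def test_simulate_genotypes_f_drift_bounds(study):
    pops = [synth.PopulationSpec("A", "human", 5),
            synth.PopulationSpec("B", "chimpanzee", 5)]
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError, match="F_drift"):
            synth.simulate_genotypes(study.markers[:1], pops, bad, seed=1)


def test_simulate_genotypes_missing_rate():
    truth = o.make_ortholog_pair(o.MarkerConfig("t"), 5)
    pops = [synth.PopulationSpec("A", "human", 200)]
    lens, reps = synth.simulate_genotypes([truth], pops, 0.05, seed=2,
                                          missing_rate=0.25)
    frac = np.isnan(reps.alleles).mean()
    assert 0.1 < frac < 0.45
    # missingness is consistent between the two representations
    np.testing.assert_array_equal(np.isnan(lens.alleles), np.isnan(reps.alleles))


def test_scenario_epcr_outcomes(study):
    """Each scenario marker drives its intended decision-tree branch."""
    want = {
        "M_NOHIT": epcr.OUTCOME_REJECTED_NO_HIT,
        "M_FAR": epcr.OUTCOME_REJECTED_LENGTH,
        "M_OVL": epcr.OUTCOME_RESOLVED_OVERLAP,
        "M_MULTI": epcr.OUTCOME_REJECTED_MULTI_HIT,
        "M_RET": epcr.OUTCOME_RETAINED,
    }
    by_name = {t.config.name: t for t in study.markers}
    for name, outcome in want.items():
        truth = by_name[name]
        lo, hi = truth.supports["chimpanzee"]
        observed = o.LengthRange(truth.length_of("chimpanzee", lo),
                                 truth.length_of("chimpanzee", hi), "chimpanzee")
        d = epcr.run_epcr(truth.primer_pair, truth.references["chimpanzee"],
                          observed)
        assert d.outcome == outcome, name
        # the human record always amplifies cleanly
        lo, hi = truth.supports["human"]
        obs_h = o.LengthRange(truth.length_of("human", lo),
                              truth.length_of("human", hi), "human")
        dh = epcr.run_epcr(truth.primer_pair, truth.references["human"], obs_h)
        assert dh.outcome == epcr.OUTCOME_RETAINED, name


def test_stepwise_mutate():
    rng = np.random.default_rng(7)
    base = np.full((2000, 1, 2), 10.0)
    out = synth.stepwise_mutate(base, rate=0.3, rng=rng)
    changed = out != base
    assert 0.2 < changed.mean() < 0.4
    assert set(np.unique(out[changed] - base[changed])) == {-1.0, 1.0}
    assert synth.stepwise_mutate(np.full((50, 1, 2), 1.0), 1.0, rng).min() >= 1
    nan_in = np.full((4, 1, 2), np.nan)
    assert np.isnan(synth.stepwise_mutate(nan_in, 1.0, rng)).all()


def test_zero_indel_lengths_equal_across_species(zero_indel_study):
    """Without planted indels, a repeat number maps to the same PCR length in
    both species — the precondition for the zero-inflation acceptance check."""
    for truth in zero_indel_study.markers:
        assert truth.indel_totals == {"chimpanzee": 0, "human": 0}
        for k in range(6, 20):
            assert truth.length_of("chimpanzee", k) == truth.length_of("human", k)


def test_planted_indels_shift_length_map(mimic_study):
    shifted = 0
    for truth in mimic_study.markers:
        diff = truth.indel_totals["human"] - truth.indel_totals["chimpanzee"]
        got = truth.length_of("human", 12) - truth.length_of("chimpanzee", 12)
        assert got == diff
        shifted += diff != 0
    assert shifted >= 5  # the mimic panel actually plants indels


def test_random_chunk_repeat_free():
    rng = np.random.default_rng(9)
    for _ in range(25):
        chunk = synth._random_chunk(rng, 60)
        assert len(chunk) == 60
        assert not find_str_regions(chunk, min_repeats=3).regions
        assert not any(chunk[i] == chunk[i + 1] == chunk[i + 2]
                       for i in range(58))
    assert synth._random_chunk(rng, 0) == ""


def test_marker_config_validation():
    with pytest.raises(ValueError, match="spacer"):
        o.MarkerConfig("x", motifs=("GATA", "CA"), repeats_chimp=(8, 6),
                       repeats_human=(8, 6))
    with pytest.raises(ValueError, match="repeat counts"):
        o.MarkerConfig("x", motifs=("GATA",), repeats_chimp=(8, 6),
                       repeats_human=(8,))
    with pytest.raises(ValueError, match="indel"):
        o.MarkerConfig("x", indels=(("human", 40),))
    with pytest.raises(ValueError, match="flank"):
        o.MarkerConfig("x", flank_len=12)
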