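"""Population-genetic estimators, dual-route checks, and inflation analysis."""
import numpy as np
import pandas as pd
import pytest

import orthosat as o
from orthosat import popgen

from oracles import (oracle_heterozygosity, oracle_shared_allele_distance,
                     oracle_theta, oracle_theta_components)


def test_heterozygosity_closed_forms():
    assert o.heterozygosity([1, 1]) == pytest.approx(1.0)
    assert o.heterozygosity([2, 2]) == pytest.approx(2 / 3)
    assert o.heterozygosity([10]) == 0.0
    assert o.heterozygosity([5, 3, 2]) == pytest.approx(
        oracle_heterozygosity([5, 3, 2]))
    with pytest.raises(ValueError):
        o.heterozygosity([1])


def _dataset(genos_by_pop, representation="repeats", species=None):
    """genos_by_pop: {pop: (n_i, n_loci, 2) array}."""
    inds, pops, specs, blocks = [], [], [], []
    species = species or {}
    for p, g in genos_by_pop.items():
        g = np.asarray(g, dtype=float)
        for k in range(g.shape[0]):
            inds.append(f"{p}_{k}")
            pops.append(p)
            specs.append(species.get(p, "human"))
        blocks.append(g)
    alleles = np.concatenate(blocks, axis=0)
    loci = [f"L{j}" for j in range(alleles.shape[1])]
    return o.GenotypeDataset(inds, pops, specs, loci, alleles, representation)


def _fixed(value, n, n_loci=1):
    return np.full((n, n_loci, 2), float(value))


def test_theta_limits():
    # two populations fixed for different alleles: theta = 1
    ds = _dataset({"A": _fixed(10, 8), "B": _fixed(12, 8)})
    m = popgen.pairwise_fst(ds, min_pop_size=5)
    assert m.entry("A", "B") == pytest.approx(1.0)
    # identical genotype distributions: theta <= 0 (no among-population variance)
    g = np.array([[[10, 12]] * 1] * 6 + [[[12, 12]]] * 6, dtype=float)
    ds = _dataset({"A": g, "B": g.copy()})
    m = popgen.pairwise_fst(ds, min_pop_size=5)
    assert m.entry("A", "B") <= 0.0


def test_theta_matches_anova_oracle():
    """Dual route: W-C variance components vs nested-ANOVA sums of squares."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        n_loci = int(rng.integers(1, 4))
        genos = {p: rng.integers(1, 5, size=(int(rng.integers(5, 25)), n_loci, 2))
                 for p in ("A", "B")}
        ds = _dataset(genos)
        got = popgen.pairwise_fst(ds, min_pop_size=5).entry("A", "B")
        want = oracle_theta([[genos["A"][:, j, :], genos["B"][:, j, :]]
                             for j in range(n_loci)])
        assert got == pytest.approx(want, abs=1e-12)


def test_theta_relabelling_invariance():
    """Theta treats alleles categorically: any order-preserving relabelling
    (e.g. bp lengths vs repeat numbers within a species) leaves it unchanged."""
    rng = np.random.default_rng(23)
    genos = {p: rng.integers(8, 14, size=(12, 3, 2)) for p in ("A", "B", "C")}
    ds1 = _dataset(genos)
    ds2 = _dataset({p: 160 + 4 * g for p, g in genos.items()},
                   representation="length")
    m1 = popgen.pairwise_fst(ds1, 5)
    m2 = popgen.pairwise_fst(ds2, 5)
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)
    d1, d2 = popgen.pairwise_dps(ds1, 5), popgen.pairwise_dps(ds2, 5)
    np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


def test_monomorphic_loci_skipped():
    rng = np.random.default_rng(2)
    poly = {p: rng.integers(8, 12, size=(10, 1, 2)) for p in ("A", "B")}
    with_mono = {p: np.concatenate([poly[p], _fixed(5, 10)], axis=1)
                 for p in ("A", "B")}
    t1 = popgen.pairwise_fst(_dataset(poly), 5).entry("A", "B")
    t2 = popgen.pairwise_fst(_dataset(with_mono), 5).entry("A", "B")
    assert t1 == pytest.approx(t2)


def test_min_pop_size_and_too_few_pops():
    rng = np.random.default_rng(3)
    ds = _dataset({"A": rng.integers(8, 12, size=(10, 1, 2)),
                   "B": rng.integers(8, 12, size=(10, 1, 2)),
                   "tiny": rng.integers(8, 12, size=(3, 1, 2))})
    m = popgen.pairwise_fst(ds, min_pop_size=5)
    assert m.populations == ["A", "B"]
    with pytest.raises(ValueError, match="fewer than 2"):
        popgen.pairwise_fst(_dataset({"A": rng.integers(8, 12, size=(10, 1, 2))}), 5)


def test_dps_limits_and_example():
    # identical allele frequencies: D_PS = 0
    g = np.array([[[10, 12]]] * 4 + [[[12, 14]]] * 4, dtype=float)
    ds = _dataset({"A": g, "B": g.copy()})
    assert popgen.pairwise_dps(ds, 4).entry("A", "B") == pytest.approx(0.0)
    # disjoint allele sets: D_PS = 1
    ds = _dataset({"A": _fixed(10, 6), "B": _fixed(20, 6)})
    assert popgen.pairwise_dps(ds, 5).entry("A", "B") == pytest.approx(1.0)
    # hand example: p = {10: .5, 12: .5}, q = {10: .4, 14: .6} -> 1 - 0.4
    a = np.array([[[10, 10]]] * 3 + [[[12, 12]]] * 3, dtype=float)
    b = np.array([[[10, 10]]] * 2 + [[[14, 14]]] * 3, dtype=float)
    ds = _dataset({"A": a, "B": b})
    got = popgen.pairwise_dps(ds, 5).entry("A", "B")
    assert got == pytest.approx(0.6)
    assert got == pytest.approx(oracle_shared_allele_distance(
        {10: 0.5, 12: 0.5}, {10: 0.4, 14: 0.6}))


def _interspecies_matrices(values_len, values_rep, pops=("C1", "H1", "H2")):
    species = {"C1": "chimpanzee", "H1": "human", "H2": "human"}
    return (popgen.PairwiseMatrix(list(pops), values_len, "FST", "length", species),
            popgen.PairwiseMatrix(list(pops), values_rep, "FST", "repeats", species))


def test_inflation_summary_zero_case():
    v = np.array([[0.0, 0.4, 0.5], [0.4, 0.0, 0.1], [0.5, 0.1, 0.0]])
    ml, mr = _interspecies_matrices(v, v.copy())
    rep = popgen.inflation_summary(ml, mr)
    assert rep.mean_reduction_pct == pytest.approx(0.0)
    assert rep.max_reduction_pct == pytest.approx(0.0)
    assert rep.wilcoxon_p == 1.0
    assert rep.r_squared == pytest.approx(1.0)


def test_inflation_summary_planted():
    vl = np.array([[0.0, 0.5, 0.4], [0.5, 0.0, 0.1], [0.4, 0.1, 0.0]])
    vr = np.array([[0.0, 0.45, 0.38], [0.45, 0.0, 0.1], [0.38, 0.1, 0.0]])
    ml, mr = _interspecies_matrices(vl, vr)
    rep = popgen.inflation_summary(ml, mr)
    # pairs are (C1,H1): 10% and (C1,H2): 5%
    assert rep.max_reduction_pct == pytest.approx(10.0)
    assert rep.mean_reduction_pct == pytest.approx(7.5)
    assert len(rep.per_pair) == 2
    dist = {"H1": o.PopulationDistance("H1", 0.0),
            "H2": o.PopulationDistance("H2", 4000.0)}
    rep = popgen.inflation_summary(ml, mr, dist)
    assert np.isnan(rep.distance_spearman_rho)  # < 3 human populations


def test_inflation_summary_errors():
    v = np.zeros((3, 3))
    ml, _ = _interspecies_matrices(v, v)
    other = popgen.PairwiseMatrix(["X", "Y"], np.zeros((2, 2)), "FST", "repeats",
                                  {"X": "human", "Y": "human"})
    with pytest.raises(ValueError):
        popgen.inflation_summary(ml, other)
    same_species = popgen.PairwiseMatrix(
        ["A", "B", "C"], v, "FST", "repeats",
        {p: "human" for p in "ABC"})
    with pytest.raises(ValueError, match="both species"):
        popgen.inflation_summary(same_species, same_species)


def _profile_datasets(n_chimp=10, n_human=30, seed=1):
    rng = np.random.default_rng(seed)
    reps, lens, inds, pops, specs = [], [], [], [], []
    for sp, n, pop in (("chimpanzee", n_chimp, "C"), ("human", n_human, "H")):
        r = rng.integers(8, 15, size=(n, 2, 2)).astype(float)
        reps.append(r)
        lens.append(160 + 4 * r)
        for k in range(n):
            inds.append(f"{pop}{k}")
            pops.append(pop)
            specs.append(sp)
    reps, lens = np.concatenate(reps), np.concatenate(lens)
    loci = ["L0", "L1"]
    return (o.GenotypeDataset(inds, pops, specs, loci, reps, "repeats"),
            o.GenotypeDataset(inds, pops, specs, loci, lens, "length"))


def test_variability_profile_no_resampling():
    reps, lens = _profile_datasets()
    prof = popgen.variability_profile(reps, lens, resample_sets=10,
                                      resample_size=100)
    assert set(prof["species"]) == {"chimpanzee", "human"}
    assert len(prof) == 4  # 2 species x 2 loci
    row = prof[(prof.species == "human") & (prof.marker == "L0")].iloc[0]
    mask = np.array([s == "human" for s in reps.species])
    vals = reps.alleles[mask, 0, :]
    assert row["mean_repeats"] == pytest.approx(vals.mean())
    assert row["max_repeats"] == vals.max()
    assert row["mean_pcr_length"] == pytest.approx(160 + 4 * vals.mean())


def test_variability_profile_resampling():
    reps, lens = _profile_datasets()
    with pytest.raises(ValueError, match="seed"):
        popgen.variability_profile(reps, lens, resample_sets=5, resample_size=20)
    p1 = popgen.variability_profile(reps, lens, 50, 20, seed=9)
    p2 = popgen.variability_profile(reps, lens, 50, 20, seed=9)
    pd.testing.assert_frame_equal(p1, p2)
    # resampled human means stay near the full-sample values
    full = popgen.variability_profile(reps, lens, 5, 1000)
    a = p1[(p1.species == "human") & (p1.marker == "L0")]["mean_repeats"].iloc[0]
    b = full[(full.species == "human") & (full.marker == "L0")]["mean_repeats"].iloc[0]
    assert a == pytest.approx(b, rel=0.05)


def test_group_compare_and_rdm():
    reps, lens = _profile_datasets(n_chimp=20, n_human=20, seed=4)
    prof = popgen.variability_profile(reps, lens, 5, 100)
    grouping = {"L0": (1, 4), "L1": (1, 4)}
    out = popgen.group_compare(prof, grouping, min_group_size=2)
    assert set(out["variable"]) == set(popgen.PROFILE_VARIABLES)
    # ARD is the mean chimp/human ratio over markers in the group
    row = out[out["variable"] == "mean_repeats"].iloc[0]
    cv = prof.pivot_table(index="marker", columns="species",
                          values="mean_repeats", aggfunc="first")
    want = (cv["chimpanzee"] / cv["human"]).mean()
    assert row["ard"] == pytest.approx(want)
    rdm, p = popgen.rdm_contrast(prof, ["L0"], ["L1"], "human", "heterozygosity")
    assert rdm > 0 and 0 <= p <= 1
    with pytest.raises(ValueError):
        popgen.rdm_contrast(prof, [], ["L1"], "human", "heterozygosity")
    corr = popgen.he_correlations(prof, grouping, min_group_size=2)
    assert "heterozygosity" not in set(corr["variable"])


def test_classify_outliers():
    he_h = np.full(20, 0.8)
    d = np.zeros(20)
    d[3] = -0.5  # strongly reduced chimpanzee H_e at one marker
    outliers, band = popgen.classify_outliers(he_h + d, he_h)
    assert outliers[3] and outliers.sum() == 1
    assert band.sum() == 19 and not band[3]
    with pytest.raises(ValueError):
        popgen.classify_outliers([0.5], [0.5])


def test_pairwise_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        popgen.PairwiseMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]),
                              "FST", "length")
    m = popgen.PairwiseMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0.0]]),
                              "FST", "length")
    assert m.entry("b", "a") == pytest.approx(0.2)
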