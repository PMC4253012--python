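"""Population-genetic statistics on length- and repeat-represented genotypes.

Core estimators
---------------
* Expected heterozygosity with the standard small-sample correction:
  H_e = n/(n-1) * (1 - sum p_i^2) over n non-missing allele copies.
* Pairwise Weir-Cockerham (1984) theta, multi-allelic, combined across loci
  as a ratio of summed variance components; alleles are unordered categorical
  states, so theta is identical under any order-preserving relabelling of
  alleles within a species.
* Pairwise allele-sharing distance D_PS = 1 - mean over loci of
  sum_a min(p_a, q_a).

Inflation analysis
------------------
Within a species both representations (bp lengths, repeat numbers) are affine
images of each other, so within-species statistics agree exactly.  Across
species, flank-sequence indels shift one species' whole length distribution
relative to the other, so alleles that match in repeat number no longer match
in length: length-based interspecies F_ST and D_PS are inflated relative to
repeat-based values.  :func:`inflation_summary` quantifies this per
interspecies pair as a percent reduction.

Negative theta estimates are reported as computed (not clamped); percent
reductions skip pairs whose length-based value is <= 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeDataset, PopulationDistance

STAT_FST = "FST"
STAT_DPS = "DPS"

PROFILE_VARIABLES = (
    "heterozygosity", "n_distinct_alleles", "variance_repeats", "range_repeats",
    "skewness_repeats", "mean_pcr_length", "mean_repeats", "max_repeats",
    "min_repeats",
)


@dataclass
class PairwiseMatrix:
    populations: list[str]
    values: np.ndarray
    statistic: str
    representation: str
    pop_species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.populations),) * 2:
            raise ValueError("matrix shape inconsistent with population list")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def entry(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])


def heterozygosity(allele_counts) -> float:
    """Sample-size-corrected expected heterozygosity from allele copy counts."""
    counts = np.asarray(list(allele_counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 allele copies")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def _locus_genotypes(dataset: GenotypeDataset, j: int, mask: np.ndarray) -> np.ndarray:
    g = dataset.alleles[mask, j, :]
    return g[~np.isnan(g[:, 0])]


def _wc_components(genos_by_pop: list[np.ndarray]):
    """Weir-Cockerham (1984) per-allele variance components at one locus.

    ``genos_by_pop``: per population an (n_i, 2) array of non-missing diploid
    genotypes coded as allele states.  Returns (sum_a, sum_abc) over alleles,
    or None when fewer than two populations have data or the locus is
    monomorphic across them.
    """
    genos_by_pop = [g for g in genos_by_pop if len(g)]
    r = len(genos_by_pop)
    if r < 2:
        return None
    alleles = np.unique(np.concatenate([g.ravel() for g in genos_by_pop]))
    if alleles.size < 2:
        return None
    n_i = np.array([len(g) for g in genos_by_pop], dtype=float)
    nbar = n_i.mean()
    r_f = float(r)
    n_c = (r_f * nbar - np.sum(n_i ** 2) / (r_f * nbar)) / (r_f - 1)
    sum_a = sum_abc = 0.0
    for allele in alleles:
        p_i = np.array([np.mean(g == allele) for g in genos_by_pop])
        h_i = np.array([np.mean(np.sum(g == allele, axis=1) == 1)
                        for g in genos_by_pop])
        pbar = np.sum(n_i * p_i) / (r_f * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r_f - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r_f * nbar)
        if nbar <= 1:
            return None
        a = (nbar / n_c) * (s2 - (pbar * (1 - pbar) - s2 * (r_f - 1) / r_f
                                  - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r_f - 1) / r_f
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def _retained_populations(dataset: GenotypeDataset, min_pop_size: int) -> list[str]:
    sizes: dict[str, int] = {}
    for p in dataset.populations:
        sizes[p] = sizes.get(p, 0) + 1
    pops = [p for p in dict.fromkeys(dataset.populations) if sizes[p] >= min_pop_size]
    if len(pops) < 2:
        raise ValueError("fewer than 2 populations meet the minimum size")
    return pops


def pairwise_fst(dataset: GenotypeDataset, min_pop_size: int = 5) -> PairwiseMatrix:
    """Multi-locus Weir-Cockerham theta between every pair of populations."""
    pops = _retained_populations(dataset, min_pop_size)
    masks = {p: dataset.population_mask(p) for p in pops}
    genos = {p: [_locus_genotypes(dataset, j, masks[p])
                 for j in range(dataset.n_loci)] for p in pops}
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            num = den = 0.0
            for j in range(dataset.n_loci):
                comp = _wc_components([genos[pops[i]][j], genos[pops[k]][j]])
                if comp is not None:
                    num += comp[0]
                    den += comp[1]
            theta = num / den if den != 0 else np.nan
            mat[i, k] = mat[k, i] = theta
    pop_species = {p: dataset.pop_to_species[p] for p in pops}
    return PairwiseMatrix(pops, mat, STAT_FST, dataset.representation, pop_species)


def pairwise_dps(dataset: GenotypeDataset, min_pop_size: int = 5) -> PairwiseMatrix:
    """Allele-sharing distance between every pair of populations."""
    pops = _retained_populations(dataset, min_pop_size)
    masks = {p: dataset.population_mask(p) for p in pops}
    freqs: dict[str, list[dict]] = {}
    for p in pops:
        per_locus = []
        for j in range(dataset.n_loci):
            g = _locus_genotypes(dataset, j, masks[p]).ravel()
            if g.size == 0:
                per_locus.append(None)
            else:
                vals, counts = np.unique(g, return_counts=True)
                per_locus.append(dict(zip(vals, counts / g.size)))
        freqs[p] = per_locus
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            shared = []
            for j in range(dataset.n_loci):
                fp, fq = freqs[pops[i]][j], freqs[pops[k]][j]
                if fp is None or fq is None:
                    continue
                shared.append(sum(min(fp[a], fq[a]) for a in set(fp) & set(fq)))
            if not shared:
                raise ValueError(f"no shared loci with data for {pops[i]} vs {pops[k]}")
            mat[i, k] = mat[k, i] = 1.0 - float(np.mean(shared))
    pop_species = {p: dataset.pop_to_species[p] for p in pops}
    return PairwiseMatrix(pops, mat, STAT_DPS, dataset.representation, pop_species)


@dataclass
class InflationReport:
    statistic: str
    per_pair: pd.DataFrame          # chimp_pop, human_pop, value_length, value_repeats, reduction_pct
    max_reduction_pct: float
    mean_reduction_pct: float
    sd_reduction_pct: float
    r_squared: float                # all pairs, length vs repeats
    wilcoxon_p: float               # interspecies entries, length vs repeats
    distance_spearman_rho: float = np.nan
    distance_spearman_p: float = np.nan


def inflation_summary(m_length: PairwiseMatrix, m_repeats: PairwiseMatrix,
                      distances: dict[str, PopulationDistance] | None = None
                      ) -> InflationReport:
    """Quantify how length-based interspecies values exceed repeat-based ones.

    Per human-chimpanzee pair the percent reduction is
    100 * (v_len - v_rep) / v_len; pairs with v_len <= 0 are skipped.  Also
    reports R^2 between all matched entries of the two matrices, a Wilcoxon
    signed-rank P over interspecies entries, and, when geographic distances
    are supplied, the Spearman correlation between each human population's
    mean reduction and its distance from the reference origin.
    """
    if m_length.populations != m_repeats.populations:
        raise ValueError("matrices cover different population sets")
    if m_length.statistic != m_repeats.statistic:
        raise ValueError("matrices carry different statistics")
    pops = m_length.populations
    species = m_length.pop_species
    chimp_pops = [p for p in pops if species.get(p) == "chimpanzee"]
    human_pops = [p for p in pops if species.get(p) == "human"]
    if not chimp_pops or not human_pops:
        raise ValueError("need populations of both species")

    rows = []
    len_vals, rep_vals = [], []
    for cp in chimp_pops:
        for hp in human_pops:
            vl = m_length.entry(cp, hp)
            vr = m_repeats.entry(cp, hp)
            len_vals.append(vl)
            rep_vals.append(vr)
            red = 100.0 * (vl - vr) / vl if vl > 0 else np.nan
            rows.append((cp, hp, vl, vr, red))
    per_pair = pd.DataFrame(rows, columns=["chimp_pop", "human_pop",
                                           "value_length", "value_repeats",
                                           "reduction_pct"])
    reductions = per_pair["reduction_pct"].dropna().to_numpy()

    iu = np.triu_indices(len(pops), k=1)
    all_len = m_length.values[iu]
    all_rep = m_repeats.values[iu]
    ok = ~(np.isnan(all_len) | np.isnan(all_rep))
    if ok.sum() >= 2 and np.std(all_len[ok]) > 0 and np.std(all_rep[ok]) > 0:
        r = np.corrcoef(all_len[ok], all_rep[ok])[0, 1]
        r_squared = float(r ** 2)
    else:
        r_squared = np.nan

    lv, rv = np.array(len_vals), np.array(rep_vals)
    diffs = lv - rv
    if np.allclose(diffs, 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(lv, rv, zero_method="wilcox",
                                          correction=True).pvalue)

    rho = rho_p = np.nan
    if distances:
        per_human = per_pair.groupby("human_pop")["reduction_pct"].mean()
        common = [p for p in per_human.index if p in distances]
        if len(common) >= 3:
            d = [distances[p].distance_km for p in common]
            m = [per_human[p] for p in common]
            res = stats.spearmanr(m, d)
            rho, rho_p = float(res.statistic), float(res.pvalue)

    return InflationReport(
        statistic=m_length.statistic, per_pair=per_pair,
        max_reduction_pct=float(np.max(reductions)) if reductions.size else np.nan,
        mean_reduction_pct=float(np.mean(reductions)) if reductions.size else np.nan,
        sd_reduction_pct=float(np.std(reductions, ddof=1)) if reductions.size > 1 else np.nan,
        r_squared=r_squared, wilcoxon_p=wilcoxon_p,
        distance_spearman_rho=rho, distance_spearman_p=rho_p)


def _profile_values(lengths: np.ndarray, repeats: np.ndarray) -> dict[str, float]:
    """All nine per-marker variables from matched non-missing genotype arrays."""
    lens = lengths[~np.isnan(lengths)]
    reps = repeats[~np.isnan(repeats)]
    vals, counts = np.unique(lens, return_counts=True)
    return {
        "heterozygosity": heterozygosity(counts),
        "n_distinct_alleles": float(vals.size),
        "variance_repeats": float(np.var(reps, ddof=1)) if reps.size > 1 else 0.0,
        "range_repeats": float(reps.max() - reps.min()),
        "skewness_repeats": float(stats.skew(reps, bias=True)),
        "mean_pcr_length": float(lens.mean()),
        "mean_repeats": float(reps.mean()),
        "max_repeats": float(reps.max()),
        "min_repeats": float(reps.min()),
    }


def variability_profile(dataset_repeats: GenotypeDataset,
                        dataset_lengths: GenotypeDataset,
                        resample_sets: int = 1000, resample_size: int = 84,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-marker, per-species variability variables.

    The species with more individuals than ``resample_size`` is summarised by
    the mean of each variable across ``resample_sets`` draws of
    ``resample_size`` individuals without replacement; the other species uses
    all its individuals directly.  ``seed`` is required whenever resampling is
    active (no silent default entropy).
    """
    if dataset_repeats.loci != dataset_lengths.loci:
        raise ValueError("datasets cover different loci")
    rows = []
    for sp in sorted(set(dataset_repeats.species)):
        mask = dataset_repeats.species_mask(sp)
        n_sp = int(mask.sum())
        resample = n_sp > resample_size
        if resample and seed is None:
            raise ValueError("seed is required when resampling is active")
        rng = np.random.default_rng(seed) if resample else None
        idx_all = np.flatnonzero(mask)
        if resample:
            draws = [rng.choice(idx_all, size=resample_size, replace=False)
                     for _ in range(resample_sets)]
        for j, marker in enumerate(dataset_repeats.loci):
            if resample:
                acc: dict[str, list[float]] = {v: [] for v in PROFILE_VARIABLES}
                for draw in draws:
                    vals = _profile_values(dataset_lengths.alleles[draw, j, :],
                                           dataset_repeats.alleles[draw, j, :])
                    for k, v in vals.items():
                        acc[k].append(v)
                vals = {k: float(np.mean(v)) for k, v in acc.items()}
            else:
                vals = _profile_values(dataset_lengths.alleles[idx_all, j, :],
                                       dataset_repeats.alleles[idx_all, j, :])
            rows.append({"marker": marker, "species": sp, **vals})
    return pd.DataFrame(rows)


def group_compare(profiles: pd.DataFrame, grouping: dict[str, tuple],
                  min_group_size: int = 5) -> pd.DataFrame:
    """Interspecies ARD and Wilcoxon signed-rank tests per variable per group.

    ``grouping`` maps marker -> group key, typically (number of STR regions,
    repeat unit size).  The average relative difference (ARD) of a variable is
    the mean across markers of (chimpanzee value / human value); groups with
    fewer than ``min_group_size`` markers are skipped.
    """
    rows = []
    wide = profiles.pivot_table(index="marker", columns="species",
                                values=list(PROFILE_VARIABLES), aggfunc="first")
    markers_by_group: dict[tuple, list[str]] = {}
    for marker, key in grouping.items():
        markers_by_group.setdefault(key, []).append(marker)
    for key, markers in sorted(markers_by_group.items()):
        markers = [m for m in markers if m in wide.index]
        if len(markers) < min_group_size:
            continue
        for var in PROFILE_VARIABLES:
            cv = wide.loc[markers, (var, "chimpanzee")].to_numpy(dtype=float)
            hv = wide.loc[markers, (var, "human")].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = cv / hv
            ratios = ratios[np.isfinite(ratios)]
            ard = float(np.mean(ratios)) if ratios.size else np.nan
            sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else np.nan
            if np.allclose(cv, hv):
                p = 1.0
            else:
                p = float(stats.wilcoxon(cv, hv, zero_method="wilcox",
                                         correction=True).pvalue)
            rows.append({"group": key, "n": len(markers), "variable": var,
                         "ard": ard, "sd": sd, "p_signed_rank": p})
    return pd.DataFrame(rows)


def rdm_contrast(profiles: pd.DataFrame, group_a: list[str], group_b: list[str],
                 species: str, variable: str) -> tuple[float, float]:
    """Relative difference in means between two marker groups within one species.

    RDM = mean(variable over group_a markers) / mean(over group_b markers);
    the P value is a Wilcoxon rank-sum test between the two groups.
    """
    sub = profiles[profiles["species"] == species].set_index("marker")
    a = sub.loc[[m for m in group_a if m in sub.index], variable].to_numpy(dtype=float)
    b = sub.loc[[m for m in group_b if m in sub.index], variable].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in RDM contrast")
    rdm = float(a.mean() / b.mean())
    p = float(stats.ranksums(a, b).pvalue)
    return rdm, p


def he_correlations(profiles: pd.DataFrame, grouping: dict[str, tuple],
                    min_group_size: int = 5) -> pd.DataFrame:
    """Spearman correlation of each variable with H_e, per group per species."""
    rows = []
    markers_by_group: dict[tuple, list[str]] = {}
    for marker, key in grouping.items():
        markers_by_group.setdefault(key, []).append(marker)
    for key, markers in sorted(markers_by_group.items()):
        if len(markers) < min_group_size:
            continue
        for sp in sorted(profiles["species"].unique()):
            sub = profiles[(profiles["species"] == sp)
                           & profiles["marker"].isin(markers)]
            if len(sub) < min_group_size:
                continue
            for var in PROFILE_VARIABLES:
                if var == "heterozygosity":
                    continue
                res = stats.spearmanr(sub[var], sub["heterozygosity"])
                rows.append({"group": key, "species": sp, "variable": var,
                             "rho": float(res.statistic), "p": float(res.pvalue),
                             "n": len(sub)})
    return pd.DataFrame(rows)


def classify_outliers(he_chimp: np.ndarray, he_human: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Flag markers with markedly lower chimpanzee than human heterozygosity.

    d = H_e(chimp) - H_e(human); with s the SD of d across the whole panel, a
    marker is an outlier iff d < -2s.  Also returns membership of the
    within-1-SD band around the identity line.
    """
    he_chimp = np.asarray(he_chimp, dtype=float)
    he_human = np.asarray(he_human, dtype=float)
    if he_chimp.size < 2:
        raise ValueError("need at least 2 markers")
    d = he_chimp - he_human
    s = float(np.std(d, ddof=1))
    if s == 0:
        return np.zeros(d.size, dtype=bool), np.ones(d.size, dtype=bool)
    return d < -2 * s, np.abs(d) <= s
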