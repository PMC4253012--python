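"""Independent brute-force reference implementations used by the test suite.

These are deliberately naive and written from the definitions, not from the
production code, so that agreement between the two is evidence of correctness
rather than of shared bugs:

* ``oracle_str_regions``: enumerate every (start, unit size) pair, extend the
  motif maximally, keep leftward-maximal runs of >= min_repeats primitive
  motifs, then apply the documented deterministic overlap-resolution rule.
* ``oracle_primer_site_accepted``: exhaustive sub-window scan of one ungapped
  primer-vs-site diagonal under the two acceptance thresholds
  (shortfall <= 10 nt, identity >= 0.90).
* ``oracle_theta_components``: Weir-Cockerham theta via the three-level
  ANOVA sums-of-squares route (gametes within individuals within
  populations), algebraically equivalent to the 1984 variance-component
  formulas but coded independently.
* Closed-form heterozygosity and allele-sharing helpers.
"""
from __future__ import annotations

import numpy as np

MAX_SHORTFALL = 10
MIN_IDENTITY = 0.90


def _reducible(motif: str) -> bool:
    n = len(motif)
    return any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def oracle_str_regions(seq: str, min_repeats: int,
                       unit_sizes=(2, 3, 4, 5, 6)):
    """Region set as (start, end, motif, unit, count) tuples, sorted by start."""
    n = len(seq)
    candidates = []
    for u in unit_sizes:
        for s in range(n - u * min_repeats + 1):
            motif = seq[s:s + u]
            if _reducible(motif):
                continue
            if s >= u and seq[s - u:s] == motif:
                continue  # not leftward-maximal: an earlier start covers this run
            c = 1
            while seq[s + c * u:s + (c + 1) * u] == motif:
                c += 1
            if c >= min_repeats:
                candidates.append((s, s + c * u, motif, u, c))
    # deterministic overlap resolution: longer span, then smaller unit, then leftmost
    ordered = sorted(candidates, key=lambda t: (-(t[1] - t[0]), t[3], t[0]))
    kept = []
    for cand in ordered:
        if all(cand[1] <= k[0] or cand[0] >= k[1] for k in kept):
            kept.append(cand)
    return sorted(kept)


def oracle_primer_site_accepted(primer: str, site: str) -> bool:
    """Any sub-window of the primer-vs-site diagonal passing both thresholds?"""
    p = len(primer)
    assert len(site) == p
    for a in range(p):
        for b in range(a + 1, p + 1):
            length = b - a
            if p - length > MAX_SHORTFALL:
                continue
            matches = sum(primer[i] == site[i] for i in range(a, b))
            if matches / length >= MIN_IDENTITY:
                return True
    return False


def oracle_heterozygosity(counts) -> float:
    counts = np.asarray(list(counts), dtype=float)
    n = counts.sum()
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def oracle_shared_allele_distance(freq_p: dict, freq_q: dict) -> float:
    shared = sum(min(freq_p[a], freq_q[a]) for a in set(freq_p) & set(freq_q))
    return 1.0 - shared


def oracle_theta_components(genos_by_pop):
    """(numerator, denominator) of W-C theta at one locus via nested ANOVA.

    ``genos_by_pop``: list of (n_i, 2) integer-coded diploid genotype arrays.
    Returns the per-locus sums over alleles of the among-population variance
    component and of the total variance, or None when undefined.
    """
    genos_by_pop = [np.asarray(g) for g in genos_by_pop if len(g)]
    r = len(genos_by_pop)
    if r < 2:
        return None
    alleles = np.unique(np.concatenate([g.ravel() for g in genos_by_pop]))
    if alleles.size < 2:
        return None
    n_i = np.array([len(g) for g in genos_by_pop], dtype=float)
    n_tot = n_i.sum()
    n_c = (n_tot - np.sum(n_i ** 2) / n_tot) / (r - 1)
    num = den = 0.0
    for allele in alleles:
        # per-individual allele dosage / 2 = individual frequency
        ybar_ij = [np.mean(g == allele, axis=1) for g in genos_by_pop]
        p_i = np.array([y.mean() for y in ybar_ij])
        pbar = np.sum(n_i * p_i) / n_tot
        het_i = [np.sum(g == allele, axis=1) == 1 for g in genos_by_pop]
        n_het = float(sum(h.sum() for h in het_i))
        # sums of squares: populations / individuals-in-populations / gametes
        ssp = np.sum(2 * n_i * (p_i - pbar) ** 2)
        ssi = sum(2 * np.sum((y - p) ** 2) for y, p in zip(ybar_ij, p_i))
        ssg = 0.5 * n_het
        msp = ssp / (r - 1)
        msi = ssi / (n_tot - r)
        msg = ssg / n_tot
        sigma_p = (msp - msi) / (2 * n_c)
        sigma_i = (msi - msg) / 2.0
        sigma_g = msg
        num += sigma_p
        den += sigma_p + sigma_i + sigma_g
    return num, den


def oracle_theta(genos_by_pop_by_locus) -> float:
    """Multi-locus ratio-of-sums theta from per-locus genotype lists."""
    num = den = 0.0
    for genos_by_pop in genos_by_pop_by_locus:
        comp = oracle_theta_components(genos_by_pop)
        if comp is not None:
            num += comp[0]
            den += comp[1]
    return num / den
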