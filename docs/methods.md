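# Methods

This document records the model conventions, algorithmic and numerical
choices, the realism and limits of the synthetic-data generator, and known
limitations. Everything stated here about behaviour is computed by the test
suite or the acceptance script; no external empirical claims are made.

## 1. The core model

A microsatellite genotype can be expressed two ways:

* **repeat number** `k` — copies of the repeat motif in the array, the
  quantity mutation models (stepwise mutation) and differentiation
  statistics implicitly assume;
* **fragment length** `L` — the sized PCR product, what fragment analysis
  actually measures.

Within one species the two are related by an affine map per locus,

```
L = L_ref + (k − k_ref) · u
```

where `u` is the repeat unit size and `(L_ref, k_ref)` come from one
sequenced reference individual. Because the map is affine and injective,
any statistic that treats alleles categorically (heterozygosity,
Weir–Cockerham θ, D_PS) is invariant under it **within** a species
(verified exactly in `tests/test_acceptance.py::test_criterion_3_*` and
`test_popgen.py::test_theta_relabelling_invariance`).

Across species the intercept differs whenever the flanking sequence between
the primer sites differs (insertion/deletion outside the array). Then the
same `k` yields different `L` in the two species, alleles that are identical
in state no longer co-migrate, and interspecies F_ST and D_PS computed from
lengths are inflated relative to repeat numbers. That inflation — and its
exact disappearance when the flank offset is 0 bp — is the package's
headline computation.

## 2. STR detection (`strdetect`)

* A **region** is a maximal run of ≥ `min_repeats` contiguous copies of a
  primitive motif of 2–6 nt (primitive: not itself a repetition of a
  shorter motif; homopolymers are therefore never reported as 2-nt motifs
  like `AA`).
* Candidates are found with a lag-`u` periodicity scan: positions where
  `seq[i] == seq[i−u]` delimit maximal periodic segments, and **every phase**
  of a segment is emitted as a candidate (a segment of length `m` contains
  up to `u` distinct maximal runs offset by 1..u−1; emitting only the
  leftmost phase loses regions whose left end is clipped by a neighbour
  during overlap resolution — a defect the brute-force oracle caught).
* Overlapping candidates are resolved deterministically: longer span first,
  then smaller unit, then leftmost start. The brute-force oracle in
  `tests/oracles.py` applies the same published rule to an exhaustively
  enumerated candidate set; agreement over random and repeat-enriched
  sequences is an acceptance criterion.
* **Boundary harmonization** re-phases a region to a rotation of its motif
  when that removes a partial repeat at a junction, so orthologous arrays
  written as `GATA…` vs `ATAG…` compare cleanly.
* **Structure concordance** between species uses detection at
  `min_repeats=4` plus a short-run probe (`min_repeats=2`, ±3 nt slop) to
  distinguish: identical, three-repeat variant, two-repeat variant,
  disrupted (interruptions ≤ 6 nt between same-motif runs), discordant
  (different motifs), and no-STR. Precedence when several could apply:
  discordant > disrupted > two-repeat > three-repeat > no-STR.

## 3. In-silico PCR (`epcr`)

* Primers are scanned against both strands, **ungapped**: for each diagonal
  the best-scoring contiguous sub-segment is found by cumulative sums.
  Gapped primer alignment is deliberately not modelled — a bulge under a
  primer suppresses amplification rather than shifting it, and the ungapped
  model keeps acceptance decisions exhaustively checkable (the test oracle
  enumerates every sub-window of the primer/site diagonal).
* A hit requires alignment length ≥ primer length − 10 and identity ≥ 0.90.
  Primers shorter than 15 nt are rejected as inputs.
* Fragment length convention: **inclusive 5′-to-5′** distance between the
  forward and reverse hit positions (+1), matching how sized products are
  reported. Non-genomic 5′ additions (7 nt pig-tail `GTTTCTT`, or a single
  adenine) participate in scanning but are excluded from the length
  assessment of the hit and added back arithmetically
  (`adjusted = raw + extra_bp − merge_offset`).
* Decision tree over candidate fragments at one locus: no candidate →
  `rejected_no_hit`; one candidate inside the observed allele range ± 6 bp →
  `retained`, outside → `rejected_length` (margin reported); exactly two
  candidates sharing the reverse-primer end → the smaller product (which
  amplifies preferentially) is chosen, `resolved_overlap`, still subject to
  the length window; otherwise, more than one window-passing candidate →
  `rejected_multi_hit`. Products above 2000 bp are discarded as
  implausible amplicons.

## 4. Ortholog assessment (`assess`)

Given each species' observed allele-length range and reference length:

* six **range classes**: identical, chimp-subsumed, human-subsumed,
  partial (chimp lower / higher), disjoint; ranges touching at one value
  overlap.
* **range-overlap score** `ROS = |intersection| / |union|` with inclusive
  (endpoint-counting) widths, so `ROS([100,106],[100,106]) = 1` and single
  shared endpoints score > 0.
* retention criteria, evaluated in order: (i) both reference lengths in the
  intersection; (ii) in the union; (iii) `ROS ≥ threshold` (default 0.289)
  and the offending length within 6 bp of the union. Disjoint ranges fail
  with a "regression"-style reason. ROS is only reported when criterion iii
  was actually evaluated. `derive_ros_threshold` recovers a data-driven
  threshold as the minimum ROS over criterion-i markers.

## 5. Flank alignment (`flankalign`)

Orthologous amplicons are aligned with the detected STR arrays as anchors
(longest-common-subsequence pairing of motif-compatible arrays; arrays
split by ≤ 6 nt interruptions are grouped). Between anchors, Biopython's
`PairwiseAligner` (match +1, mismatch −1, gap open −3, extend −1) aligns the
non-STR segments; surplus repeats of the anchored array are gapped as whole
units. `nonstr_imbalance` counts gap-opposed **non-STR** bases per species —
exactly the planted indel totals on generator-constructed pairs (verified
for random constructions in `tests/test_flankalign.py`).

## 6. Calibration (`calibrate`)

`repeats(L) = k_ref + (L − L_ref)/u` computed as exact `fractions.Fraction`;
loci whose regions mix unit sizes raise `MixedUnitError` (no principled
single-unit conversion exists). `normalize_dataset` converts a length
dataset marker by marker and flags each as:

* `integer` — all conversions integral;
* `common-fraction rounded` — all values share one non-zero fraction
  (a constant offset, e.g. a primer redesign); rounded half-away-from-zero;
* `mixed-fraction unadjusted` — inconsistent fractions (typically an
  unmerged inter-laboratory offset); left untouched for inspection.

The pass is idempotent: repeat-number input (recovered via
`Fraction.limit_denominator(64)`) is only re-rounded, which is a no-op.

## 7. Population genetics (`popgen`)

* Expected heterozygosity with small-sample correction:
  `H_e = n/(n−1) · (1 − Σ p²)` over allele counts.
* Multi-allelic **Weir–Cockerham θ** from the a/b/c variance components,
  summed over alleles and loci (ratio of sums). The test suite validates it
  against an independently coded three-level nested-ANOVA route
  (sums of squares over gametes/individuals/populations) to ~1e−16, and an
  acceptance criterion recovers the drift F of a Balding–Nichols simulation
  (100 loci, 10 populations × 50 diploids, F = 0.1) within 20 % relative
  error (observed ≈ 2 %).
* **D_PS** = 1 − mean over loci of Σ_a min(p_a, q_a); exact 0/1 limits for
  identical frequencies / disjoint allele sets.
* `inflation_summary` compares a length-based and a repeat-based matrix over
  interspecies pairs: per-pair reduction `100·(len − rep)/len` (skipped when
  `len ≤ 0`), mean/max/SD, all-pairs R², Wilcoxon signed-rank test, and a
  Spearman correlation of per-human-population mean reduction against
  distance (requires ≥ 3 human populations).
* Variability profiles (per species per marker: mean/max repeats and
  lengths, H_e, skewness, …) support group comparisons (average relative
  difference chimp/human), a Mann-Whitney RDM contrast, H_e correlations and
  an outlier rule (`d < mean − 2·SD` on the interspecies H_e difference).

## 8. Synthetic data generator (`synth`)

The generator is **constructive**: it does not sample sequences and hope,
it builds amplicons whose STR structure, primer sites, calibration models
and flank-indel totals are known exactly, then *verifies* each property and
re-draws on the rare failure. Specifically:

* flanks and spacers are repeat-free chunks (no run of ≥ 3 copies of any
  2–6 nt motif, no homopolymer triples), with junction bases fixed so
  arrays cannot extend across boundaries;
* the detector is run on every generated amplicon and the construction is
  re-drawn until detection equals the planted structure (so "truth" is
  detector-verified, not assumed);
* primer sites are checked against both full reference records so that each
  scenario yields its intended hit count (e.g. `no_hit` really has zero
  acceptable forward sites) — a construction guarantee that makes
  decision-tree fates independent of the study seed;
* scenario records exercise each ePCR branch: missing forward site, distant
  extra amplicon, nested products sharing the reverse end, two well-
  separated in-window products;
* genotypes are Balding–Nichols draws (per-population Dirichlet with
  concentration `(1−F)/F` around a double-geometric base distribution over
  the configured repeat support); the first individual per species carries
  the support endpoints so the observed range equals the configured range
  the decision trees see. Lengths are derived from repeats through each
  species' reference calibration, so planted flank offsets propagate.

**Realism and limits.** Motifs are single tetra- (and occasionally di-)
nucleotide arrays with double-geometric allele distributions — adequate for
exercising the statistics, not a mutation-model study. No sequencing or
sizing noise, no null alleles, no linkage; population structure is the
plain Balding–Nichols island model. Flank indels are single blocks ≤ 32 bp.
These choices keep every ground truth exact and every test deterministic.

## 9. Numerical choices

* All randomness flows from explicit `numpy.random.default_rng` seeds;
  reruns are byte-identical (tested on the written reports).
* Calibration is exact rational arithmetic (`fractions.Fraction`); repeat
  recovery uses `limit_denominator(64)` (units are 2–6, so true
  denominators divide 60; 64 bounds the search).
* θ and D_PS accumulate in float64 as ratio of sums (loci never averaged
  separately), monomorphic loci contribute nothing, and pairs are computed
  on the two populations' own data only.
* Missing genotypes are NaN internally, `-9` in files; a half-missing
  genotype is treated as fully missing.

## 10. Problem sizes and runtime

Designed for marker panels (tens to hundreds of loci) and population samples
in the hundreds of diploids. The full test suite runs in ~20 s and the
acceptance script in ~8 s on one CPU; the heaviest step, the 100-locus ×
500-diploid θ recovery, takes a few seconds.

## 11. Limitations

* The ungapped primer model cannot represent amplification across a primer-
  site indel; such markers would be rejected as `no_hit` rather than sized
  incorrectly.
* Structure concordance compares the single best detection per species; it
  does not enumerate alternative phase decompositions.
* `derive_ros_threshold` needs at least one criterion-i marker.
* The inflation analysis assumes exactly two species labelled
  `chimpanzee`/`human` in the dataset metadata.
* The CLI is a thin wrapper exposing `detect-str`, `simulate` and `run-all`;
  the individual stages (ePCR, assessment, alignment, calibration, popgen)
  are library API only.
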