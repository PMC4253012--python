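"""The headline effect: flank indels inflate interspecies differentiation.

We simulate a panel of orthologous tetranucleotide loci where half carry a
species-specific flank insertion, genotype two chimpanzee and four human
populations under Balding-Nichols drift, and compare Weir-Cockerham F_ST and
the allele-sharing distance D_PS computed from raw fragment lengths against
the same statistics computed from true repeat numbers.  Lengths and repeats
are identical data up to a per-locus affine map within each species, so any
interspecies difference is pure flank-indel artefact.
"""
import orthosat as o
from orthosat import popgen

study = o.make_study(o.concordant_panel_configs(n_loci=24, indel_fraction=0.5,
                                           seed=7), seed=7)

fst_len = popgen.pairwise_fst(study.genotypes, min_pop_size=5)
fst_rep = popgen.pairwise_fst(study.true_repeats, min_pop_size=5)
report = popgen.inflation_summary(fst_len, fst_rep, study.distances)

print(report.per_pair.to_string(index=False, float_format="%.4f"))
print(f"\nmean F_ST reduction when using repeats: {report.mean_reduction_pct:.2f}%")
print(f"max reduction: {report.max_reduction_pct:.2f}%")
print(f"length vs repeats R^2 across all pairs: {report.r_squared:.4f}")
print(f"Wilcoxon signed-rank p (interspecies pairs): {report.wilcoxon_p:.4f}")

dps = popgen.inflation_summary(popgen.pairwise_dps(study.genotypes, 5),
                               popgen.pairwise_dps(study.true_repeats, 5))
print(f"D_PS mean reduction: {dps.mean_reduction_pct:.2f}%")
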