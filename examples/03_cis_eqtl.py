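"""Robust expression adjustment and cis-eQTL mapping in the reference panel.

Residualizes probe expression on age and sex (Huber robust fit, 3-SD outlier
mask), then maps every SNP-probe pair within 1 Mb by OLS and prunes the
significant records of the top probe to LD-independent SNPs (r2 < 0.8).
"""

from twasmr import (adjust_expression, count_eqtls, map_cis_eqtl,
                    prune_independent, simulate_cohort, study_config)

cohort = simulate_cohort(study_config(seed=7))
adj = adjust_expression(cohort.ref_expression, cohort.ref_covariates)
print(f"masked outlier entries: {(~adj.mask).sum()} "
      f"of {adj.mask.size} ({100 * (~adj.mask).mean():.2f}%)")

records = map_cis_eqtl(cohort.ref_genotypes, adj)
counts = count_eqtls(records, cohort.ref_genotypes)
print(f"tested pairs: {counts.pairs_tested}, significant at p<1e-8: "
      f"{counts.pairs_significant}, independent after pruning: "
      f"{counts.independent_after_pruning}")

top = records.sort_values("p").iloc[0]
print(f"top eQTL: {top['snp']} -> {top['probe']}  beta={top['beta']:.3f}  "
      f"r2={top['r2']:.3f}  p={top['p']:.2e}")
sig = records[(records["probe"] == top["probe"]) & records["significant"]]
indep = prune_independent(sig, cohort.ref_genotypes)
print(f"{len(sig)} significant SNPs for {top['probe']} collapse to "
      f"{len(indep)} independent signals")
# r2 here is the fraction of (adjusted) expression variance the SNP explains.
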