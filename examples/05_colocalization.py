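"""Bayesian colocalization of the GWAS and eQTL signals at one probe.

Combines per-SNP summary statistics from both traits into approximate Bayes
factors and evaluates the five-hypothesis posterior; PP4 > 0.75 means the
two signals are consistent with a shared causal variant.
"""

from twasmr import (adjust_expression, colocalize_region, logistic_assoc,
                    map_cis_eqtl, simulate_cohort, study_config)

cfg = study_config(seed=7)
cohort = simulate_cohort(cfg)
adj = adjust_expression(cohort.ref_expression, cohort.ref_covariates)
gwas = logistic_assoc(cohort.gwas_genotypes, cohort.gwas_samples,
                      ["age", "sex"])
eqtl = map_cis_eqtl(cohort.ref_genotypes, adj)

probe = f"probe{cfg.causal_probe_index}"
gw = gwas.rename(columns={"id": "snp"})[["snp", "beta", "se"]].dropna()
eq = eqtl[eqtl["probe"] == probe][["snp", "beta", "se"]].dropna()
res = colocalize_region(gw, eq)

labels = ["H0 neither", "H1 eQTL only", "H2 GWAS only",
          "H3 both, distinct", "H4 both, shared"]
for lab, pp in zip(labels, res.pp):
    print(f"{lab:18s} PP = {pp:.4f}")
print(f"colocalized (PP4 > 0.75): {res.colocalized}  over {res.n_snps} SNPs")
top = res.snp_h4.sort_values("h4_contribution").iloc[-1]
print(f"SNP contributing most to H4: {top['snp']} "
      f"({100 * top['h4_contribution']:.1f}% of the H4 mass)")
# High PP4 at the mediating probe: the same variants drive disease risk and
# expression, as the simulation planted.
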