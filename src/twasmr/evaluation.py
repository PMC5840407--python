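"""Parameter-recovery and calibration studies for the whole pipeline.

These are the package's standing benchmarks: a multi-seed end-to-end
recovery study on the study-scale mediated cohort (does the mediating gene
top the TWAS scan, does the region colocalize, does MR recover the causal
direction), and null-calibration runs (genomic inflation, p-value
uniformity, bootstrap type-I error) on no-effect cohorts. Both the test
suite and the reproduction script drive the pipeline through this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc as coloc_mod
from . import eqtl as eqtl_mod
from . import mr as mr_mod
from . import twas as twas_mod
from .gwas import genomic_inflation, logistic_assoc
from .pipeline import run_pipeline
from .simulate import (SimulationConfig, simulate_cohort, simulate_covariates,
                       simulate_expression, simulate_genotypes, study_config)

_SEED_MOD = 2**31 - 1


def _derive_seeds(base_seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([int(base_seed) % _SEED_MOD, salt])
    return [int(s) % _SEED_MOD for s in ss.generate_state(n)]


def recovery_study(n_seeds: int = 20, base_seed: int = 0,
                   n_bootstrap: int = 10_000) -> pd.DataFrame:
    """End-to-end recovery across seeds on the study-scale mediated cohort.

    Each replicate simulates a 233-sample reference panel and a 1000/1000
    case-control cohort over 100 cis-SNPs, with one probe whose expression
    (cis h2 ~ 0.25) mediates disease at log-OR 0.4 per genetic-expression
    SD, then runs GWAS, eQTL, TWAS, colocalization at the mediating probe
    and MR. Returns one row per seed with the recovery indicators.
    """
    rows = []
    for seed in _derive_seeds(base_seed, n_seeds, salt=101):
        cfg = study_config(seed=seed)
        cohort = simulate_cohort(cfg)
        causal_probe = f"probe{cfg.causal_probe_index}"
        res = run_pipeline(cohort, seed=seed, n_bootstrap=n_bootstrap,
                           target_probe=causal_probe)
        scanned = res.twas[~res.twas["excluded"] & res.twas["p_twas"].notna()]
        rank1 = bool(len(scanned) and scanned.iloc[0]["probe"] == causal_probe)
        row_c = scanned[scanned["probe"] == causal_probe]
        p_twas = float(row_c["p_twas"].iloc[0]) if len(row_c) else np.nan
        pp4 = res.coloc.pp4 if res.coloc is not None else np.nan
        slope = res.mr.wald_slope if res.mr is not None else np.nan
        egger_p = (res.mr.egger_intercept_p
                   if res.mr is not None and res.mr.egger_intercept_p is not None
                   else np.nan)
        # Egger on the oracle instrument (the true causal SNPs, no selection):
        # isolates selection-induced winner's curse from the test's own
        # calibration under pure mediation.
        causal_ids = [f"snp{i}" for i, b in enumerate(cfg.effect_vector())
                      if b != 0]
        probe_eqtl = res.eqtl[(res.eqtl["probe"] == causal_probe)
                              & res.eqtl["snp"].isin(causal_ids)]
        egger_oracle_p = np.nan
        if len(probe_eqtl) >= 3:
            mafs = pd.Series(cohort.gwas_genotypes.maf(),
                             index=cohort.gwas_genotypes.variants["id"])
            inst_o = mr_mod.build_instrument(probe_eqtl, res.gwas, mafs)
            if len(inst_o) >= 3:
                egger_oracle_p = mr_mod.egger_mr(inst_o)["egger_intercept_p"]
        rows.append({
            "seed": seed,
            "twas_rank1": rank1,
            "twas_p": p_twas,
            "twas_hit": bool(rank1 and np.isfinite(p_twas) and p_twas < 1e-4),
            "pp4": pp4,
            "coloc_hit": bool(np.isfinite(pp4) and pp4 > 0.75),
            "mr_slope": slope,
            "mr_sign_correct": bool(np.isfinite(slope) and
                                    np.sign(slope) ==
                                    np.sign(cfg.disease_logit_per_expr_sd)),
            "mr_p": res.mr.bootstrap_p if res.mr is not None else np.nan,
            "egger_p": egger_p,
            "egger_clean": bool(np.isfinite(egger_p) and egger_p > 0.05),
            "egger_oracle_p": egger_oracle_p,
            "egger_oracle_clean": bool(np.isfinite(egger_oracle_p)
                                       and egger_oracle_p > 0.05),
            "lambda_gc": res.lambda_gc,
        })
    return pd.DataFrame(rows)


def null_gwas_calibration(seed: int = 0, n_snps: int = 5000,
                          n_cases: int = 1000, n_controls: int = 1000
                          ) -> dict:
    """No-effect cohort: genomic inflation and GWAS/eQTL p-value uniformity."""
    cfg = SimulationConfig(seed=seed, n_snps=n_snps, n_probes=5,
                           n_gwas_cases=n_cases, n_gwas_controls=n_controls,
                           ld_rho=0.0, eqtl_effects={},
                           disease_logit_per_expr_sd=0.0, baseline_logit=0.0)
    cohort = simulate_cohort(cfg)
    gwas_res = logistic_assoc(cohort.gwas_genotypes, cohort.gwas_samples,
                              ["age", "sex"])
    gwas_p = gwas_res["p"].dropna().to_numpy()
    lam = genomic_inflation(gwas_p)
    adj = eqtl_mod.adjust_expression(cohort.ref_expression,
                                     cohort.ref_covariates)
    eqtl_res = eqtl_mod.map_cis_eqtl(cohort.ref_genotypes, adj)
    return {
        "lambda_gc": lam,
        "gwas_pvalues": gwas_p,
        "gwas_ks_p": float(stats.kstest(gwas_p, "uniform").pvalue),
        "eqtl_pvalues": eqtl_res["p"].to_numpy(),
        "eqtl_ks_p": float(stats.kstest(eqtl_res["p"], "uniform").pvalue),
    }


def null_twas_pvalues(n_regions: int = 200, base_seed: int = 0) -> np.ndarray:
    """TWAS p-values over independent null regions (validates the denominator).

    Each region has its own reference panel and case-control cohort with no
    genetic effect anywhere; probes passing the heritability pre-filter by
    chance contribute a TWAS p-value, which should be uniform.
    """
    pvals = []
    for seed in _derive_seeds(base_seed, n_regions, salt=202):
        cfg = SimulationConfig(seed=seed, n_snps=20, n_probes=1,
                               causal_probe_index=0, eqtl_effects={},
                               n_gwas_cases=500, n_gwas_controls=500,
                               disease_logit_per_expr_sd=0.0,
                               baseline_logit=0.0, ld_rho=0.5)
        cohort = simulate_cohort(cfg)
        adj = eqtl_mod.adjust_expression(cohort.ref_expression,
                                         cohort.ref_covariates)
        ws = twas_mod.compute_weights(cohort.ref_genotypes, adj, "probe0",
                                      seed=seed)
        if ws is None or not ws.heritable:
            continue
        gwas_res = logistic_assoc(cohort.gwas_genotypes, cohort.gwas_samples,
                                  ["age", "sex"])
        ld = twas_mod.LDMatrix.from_genotypes(cohort.ref_genotypes, ws.snp_ids)
        res = twas_mod.twas_assoc(ws, gwas_res.set_index("id")["z"], ld)
        if np.isfinite(res.p_twas):
            pvals.append(res.p_twas)
    return np.asarray(pvals)


def mr_bootstrap_type1(n_replicates: int = 400, n_sims: int = 2000,
                       n_snps: int = 12, base_seed: int = 0,
                       alpha: float = 0.05) -> dict:
    """Type-I error of the bootstrap p under a zero-slope generating model.

    Exposure effects are strong (well-estimated); disease effects are pure
    estimation noise around zero, so any rejection is a false positive.
    """
    rng = np.random.default_rng([int(base_seed) % _SEED_MOD, 303])
    rejections = 0
    for r in range(n_replicates):
        x_true = rng.uniform(0.3, 0.8, n_snps) * rng.choice([-1, 1], n_snps)
        sx, sy = 0.05, 0.05
        maf = rng.uniform(0.1, 0.5, n_snps)
        fac = np.sqrt(2 * maf * (1 - maf))
        bx = x_true + rng.normal(0, sx, n_snps)
        by = rng.normal(0, sy, n_snps)  # true slope 0
        inst = pd.DataFrame({
            "snp": [f"s{i}" for i in range(n_snps)], "maf": maf,
            "beta_expr": bx, "se_expr": sx,
            "beta_disease": by, "se_disease": sy,
            "scaled_beta_expr": bx * fac, "scaled_se_expr": sx * fac,
            "scaled_beta_disease": by * fac, "scaled_se_disease": sy * fac,
        })
        p = mr_mod.bootstrap_p(inst, n_sims=n_sims,
                               seed=int(rng.integers(1 << 30)))["p"]
        rejections += p < alpha
    rate = rejections / n_replicates
    se = np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"rate": rate, "n": n_replicates, "binomial_se": se,
            "within_3se": bool(abs(rate - alpha) <= 3 * se)}
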