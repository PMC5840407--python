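"""End-to-end discovery pipeline on a simulated (or loaded) two-cohort study.

Chains the stages in study order: robust expression adjustment in the
reference panel; dosage logistic GWAS in the case-control cohort; cis-eQTL
mapping; TWAS weight learning and scan; colocalization of the GWAS and eQTL
signals at the top TWAS probe; and Mendelian randomization of that probe's
expression on disease, with the parametric bootstrap and the Egger check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import eqtl as eqtl_mod
from . import mr as mr_mod
from . import twas as twas_mod
from .gwas import genomic_inflation, logistic_assoc
from .simulate import Cohort


@dataclass
class PipelineResult:
    gwas: pd.DataFrame
    lambda_gc: float
    eqtl: pd.DataFrame
    twas: pd.DataFrame
    target_probe: str | None
    coloc: coloc_mod.ColocResult | None
    mr: mr_mod.MRResult | None


def run_pipeline(cohort: Cohort, seed: int = 0,
                 n_bootstrap: int = 10_000,
                 covariates: list[str] = ("age", "sex"),
                 target_probe: str | None = None) -> PipelineResult:
    """Run every stage on a cohort; target defaults to the top TWAS probe.

    Coloc and MR are skipped (None) when the TWAS scan yields no usable
    probe or the MR instrument is empty.
    """
    covariates = list(covariates)
    adj = eqtl_mod.adjust_expression(cohort.ref_expression, cohort.ref_covariates)
    gwas_res = logistic_assoc(cohort.gwas_genotypes, cohort.gwas_samples,
                              covariates)
    ok_p = gwas_res["p"].dropna()
    lam = genomic_inflation(ok_p.to_numpy()) if len(ok_p) else np.nan
    eqtl_res = eqtl_mod.map_cis_eqtl(cohort.ref_genotypes, adj)

    weight_sets = []
    for probe in adj.probes["probe"]:
        ws = twas_mod.compute_weights(cohort.ref_genotypes, adj, probe,
                                      seed=seed)
        if ws is not None:
            weight_sets.append(ws)
    twas_res = twas_mod.transcriptome_scan(weight_sets, gwas_res,
                                           cohort.ref_genotypes)

    if target_probe is None:
        usable = twas_res[~twas_res["excluded"] & twas_res["p_twas"].notna()]
        target_probe = usable.iloc[0]["probe"] if len(usable) else None

    coloc_res = None
    mr_res = None
    if target_probe is not None:
        probe_eqtl = eqtl_res[eqtl_res["probe"] == target_probe]
        gw = gwas_res.rename(columns={"id": "snp"})[["snp", "beta", "se"]].dropna()
        eq = probe_eqtl.rename(columns={"beta": "beta", "se": "se"})[
            ["snp", "beta", "se"]].dropna()
        if len(gw.merge(eq, on="snp")):
            coloc_res = coloc_mod.colocalize_region(gw, eq)
        prow = adj.probes.loc[adj.probes["probe"] == target_probe].iloc[0]
        try:
            selected = mr_mod.select_instrument(
                probe_eqtl, cohort.ref_genotypes, adj, target_probe,
                gene_chrom=prow["chrom"], gene_pos=int(prow["position"]))
            mafs = cohort.gwas_genotypes.variants.set_index("id")["maf"] \
                if "maf" in cohort.gwas_genotypes.variants else pd.Series(
                    cohort.gwas_genotypes.maf(),
                    index=cohort.gwas_genotypes.variants["id"])
            instrument = mr_mod.build_instrument(selected, gwas_res, mafs)
            mr_res = mr_mod.run_mr(instrument, n_sims=n_bootstrap, seed=seed)
        except (mr_mod.InstrumentError, ValueError):
            mr_res = None

    return PipelineResult(gwas=gwas_res, lambda_gc=lam, eqtl=eqtl_res,
                          twas=twas_res, target_probe=target_probe,
                          coloc=coloc_res, mr=mr_res)
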