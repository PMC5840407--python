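"""Bayesian colocalization of a GWAS and an eQTL signal in one region.

Each variant's evidence is a Wald approximate Bayes factor computed from its
effect estimate and variance under a Normal(0, W) effect prior:

    log ABF = 1/2 log(V / (V + W)) + z^2 W / (2 (V + W)),  z = beta / sqrt(V)

Per-hypothesis likelihood sums (H0: no association; H1/H2: one trait only;
H3: both, distinct variants; H4: both, shared variant) are accumulated in
log space and normalized with the standard per-variant priors p1, p2, p12.
The model assumes at most one causal variant per trait in the region. A
posterior PP4 above 0.75 is flagged as colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

PRIOR_P1 = 1e-4
PRIOR_P2 = 1e-4
PRIOR_P12 = 1e-5
PRIOR_SD_CC = 0.2       # case-control effects (log-odds scale)
PRIOR_SD_QUANT = 0.15   # quantitative-trait effects
PP4_RULE = 0.75


def log_abf(beta: float | np.ndarray, var_beta: float | np.ndarray,
            prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for one association estimate."""
    V = np.asarray(var_beta, dtype=float)
    if np.any(V <= 0):
        raise ValueError("var_beta must be positive")
    W = prior_sd**2
    z2 = np.asarray(beta, dtype=float) ** 2 / V
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


@dataclass
class ColocResult:
    pp: np.ndarray                  # posteriors of H0..H4
    n_snps: int
    priors: tuple[float, float, float]
    snp_h4: pd.DataFrame = field(default=None, repr=False)  # per-SNP H4 share

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def colocalized(self) -> bool:
        return self.pp4 > PP4_RULE

    def as_dict(self) -> dict[str, float]:
        return {f"pp{i}": float(self.pp[i]) for i in range(5)}


def coloc_posteriors(labf1: np.ndarray, labf2: np.ndarray,
                     p1: float = PRIOR_P1, p2: float = PRIOR_P2,
                     p12: float = PRIOR_P12,
                     snp_ids: list[str] | None = None) -> ColocResult:
    """Five-hypothesis posteriors from two aligned log-ABF vectors."""
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.size == 0 or l1.shape != l2.shape:
        raise ValueError("log-ABF vectors must be nonempty and aligned")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12),
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    h4_terms = np.exp(l1 + l2 - s12)
    snp_h4 = pd.DataFrame({
        "snp": snp_ids if snp_ids is not None else [f"snp{i}" for i in range(l1.size)],
        "h4_contribution": h4_terms,
    })
    return ColocResult(pp=pp, n_snps=int(l1.size), priors=(p1, p2, p12),
                       snp_h4=snp_h4)


def _align(gwas: pd.DataFrame, eqtl: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect on snp id; flip eQTL beta where ref/alt are swapped."""
    shared = gwas.merge(eqtl, on="snp", suffixes=("_g", "_e"))
    if shared.empty:
        raise ValueError("no shared SNPs between the two summary sets")
    if {"ref_g", "alt_g", "ref_e", "alt_e"}.issubset(shared.columns):
        same = (shared["ref_g"] == shared["ref_e"]) & (shared["alt_g"] == shared["alt_e"])
        swapped = (shared["ref_g"] == shared["alt_e"]) & (shared["alt_g"] == shared["ref_e"])
        bad = ~(same | swapped)
        if bad.any():
            raise ValueError(f"allele mismatch at {shared.loc[bad, 'snp'].tolist()}")
        shared.loc[swapped, "beta_e"] *= -1.0
    g = shared[["snp", "beta_g", "se_g"]].rename(columns={"beta_g": "beta", "se_g": "se"})
    e = shared[["snp", "beta_e", "se_e"]].rename(columns={"beta_e": "beta", "se_e": "se"})
    return g, e


def colocalize_region(gwas_stats: pd.DataFrame, eqtl_stats: pd.DataFrame,
                      p1: float = PRIOR_P1, p2: float = PRIOR_P2,
                      p12: float = PRIOR_P12,
                      gwas_prior_sd: float = PRIOR_SD_CC,
                      eqtl_prior_sd: float = PRIOR_SD_QUANT) -> ColocResult:
    """End-to-end region colocalization from two summary-statistic tables.

    Tables need columns (snp, beta, se); optional ref/alt trigger an
    allele-consistency check with sign flipping. The GWAS trait uses the
    case-control effect prior SD, the eQTL trait the quantitative one.
    """
    g, e = _align(gwas_stats, eqtl_stats)
    # hypothesis convention: H1 = eQTL-only, H2 = GWAS-only
    l1 = log_abf(e["beta"].to_numpy(), e["se"].to_numpy() ** 2, eqtl_prior_sd)
    l2 = log_abf(g["beta"].to_numpy(), g["se"].to_numpy() ** 2, gwas_prior_sd)
    return coloc_posteriors(l1, l2, p1=p1, p2=p2, p12=p12,
                            snp_ids=list(g["snp"]))
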