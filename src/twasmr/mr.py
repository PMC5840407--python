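"""Expression-to-disease Mendelian randomization with a parametric bootstrap.

Instrument SNPs are taken within a window of the target gene, kept at
marginal eQTL p < 0.05, and reduced by bidirectional stepwise multiple
regression of expression on dosages under AIC, so the retained SNPs are
independently associated with expression. Effects on both scales are
variance-standardized per variant as beta * sqrt(2 * MAF * (1 - MAF)), the
causal slope is the through-origin regression of scaled disease effects on
scaled expression effects (the Wald method; a single SNP reduces to the
Wald ratio), and its two-tailed p-value comes from a parametric bootstrap
that redraws every effect from Normal(estimate, SE). Directional pleiotropy
is assessed with the Egger variant (free intercept, inverse-variance
weights, exposure effects oriented nonnegative) and with a scan of the
instrument against nearby genes' expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import AdjustedExpression, GenotypeMatrix

MR_WINDOW = 200_000
MARGINAL_P = 0.05
N_BOOTSTRAP = 100_000


class InstrumentError(ValueError):
    """No valid instrument can be formed."""


def scale_effect(beta: float | np.ndarray, maf: float | np.ndarray
                 ) -> float | np.ndarray:
    """Variance-standardize an effect: beta * sqrt(2 * MAF * (1 - MAF))."""
    maf_arr = np.asarray(maf, dtype=float)
    if np.any((maf_arr <= 0) | (maf_arr > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    out = np.asarray(beta, dtype=float) * np.sqrt(2.0 * maf_arr * (1.0 - maf_arr))
    return float(out) if np.isscalar(beta) and np.isscalar(maf) else out


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of an OLS fit (n log(RSS/n) + 2k, R step convention)."""
    n = y.size
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * X.shape[1]


def stepwise_aic(y: np.ndarray, X: np.ndarray,
                 start: str = "full") -> list[int]:
    """Bidirectional stepwise column selection under AIC.

    Starts from the full candidate model (bidirectional elimination) and at
    each step takes the single add-or-drop move that most improves AIC,
    until no move improves it. Returns the retained column indices.
    """
    n, m = X.shape
    current = set(range(m)) if start == "full" else set()

    def model_aic(cols: set[int]) -> float:
        Xm = np.column_stack([np.ones(n)] + [X[:, c] for c in sorted(cols)])
        return _aic(y, Xm)

    best = model_aic(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, set[int]]] = []
        for c in sorted(current):
            moves.append((model_aic(current - {c}), current - {c}))
        for c in range(m):
            if c not in current:
                moves.append((model_aic(current | {c}), current | {c}))
        if moves:
            cand_aic, cand = min(moves, key=lambda t: t[0])
            if cand_aic < best - 1e-10:
                best, current, improved = cand_aic, cand, True
    return sorted(current)


def select_instrument(eqtl_records: pd.DataFrame, g_ref: GenotypeMatrix,
                      adj: AdjustedExpression, probe: str,
                      gene_chrom: str, gene_pos: int,
                      window: int = MR_WINDOW,
                      p_threshold: float = MARGINAL_P) -> pd.DataFrame:
    """Candidate SNPs near the gene at marginal p < threshold, stepwise-reduced.

    eqtl_records holds the marginal cis-eQTL stats for the probe (snp, beta,
    se, p). Returns the retained rows with joint-model effects appended; the
    marginal effects remain the exposure effects used downstream.
    """
    var = g_ref.variants
    recs = eqtl_records[eqtl_records["probe"] == probe] \
        if "probe" in eqtl_records else eqtl_records
    pos = var.set_index("id")["pos"]
    chrom = var.set_index("id")["chrom"]
    cand = recs[recs["snp"].map(chrom).eq(gene_chrom)
                & (recs["snp"].map(pos) - gene_pos).abs().le(window)
                & (recs["p"] < p_threshold)].copy()
    if cand.empty:
        raise InstrumentError("no valid instrument: no candidate SNP passes "
                              f"p<{p_threshold} within {window} bp")
    pj = int(adj.probes.index[adj.probes["probe"] == probe][0])
    usable = adj.mask[:, pj]
    y = adj.residuals[usable, pj]
    snp_cols = [list(var["id"]).index(s) for s in cand["snp"]]
    X = g_ref.dosages[np.ix_(np.flatnonzero(usable), snp_cols)].copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    keep = stepwise_aic(y, X)
    selected = cand.iloc[keep].copy()
    Xk = np.column_stack([np.ones(y.size), X[:, keep]])
    coef, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    selected["beta_joint"] = coef[1:]
    return selected.reset_index(drop=True)


def build_instrument(selected: pd.DataFrame, gwas_results: pd.DataFrame,
                     mafs: pd.Series | dict) -> pd.DataFrame:
    """Join exposure (eQTL) and outcome (GWAS) effects, MAF-scale both.

    Returns one row per instrument SNP with raw and scaled effects/SEs; the
    scaling factor sqrt(2 MAF (1-MAF)) is applied to effects and SEs alike.
    """
    gw = gwas_results.set_index("id")
    maf_map = dict(mafs) if not isinstance(mafs, dict) else mafs
    rows = []
    for _, r in selected.iterrows():
        snp = r["snp"]
        if snp not in gw.index:
            continue
        maf = float(maf_map[snp])
        fac = np.sqrt(2.0 * maf * (1.0 - maf))
        rows.append({
            "snp": snp, "maf": maf,
            "beta_expr": r["beta"], "se_expr": r["se"],
            "beta_disease": gw.loc[snp, "beta"], "se_disease": gw.loc[snp, "se"],
            "scaled_beta_expr": r["beta"] * fac, "scaled_se_expr": r["se"] * fac,
            "scaled_beta_disease": gw.loc[snp, "beta"] * fac,
            "scaled_se_disease": gw.loc[snp, "se"] * fac,
        })
    if not rows:
        raise InstrumentError("no instrument SNP present in the GWAS results")
    return pd.DataFrame(rows)


def wald_mr(instrument: pd.DataFrame) -> float:
    """Through-origin OLS slope of scaled disease effects on scaled expression effects."""
    x = instrument["scaled_beta_expr"].to_numpy(dtype=float)
    y = instrument["scaled_beta_disease"].to_numpy(dtype=float)
    sxx = float((x**2).sum())
    if sxx == 0:
        raise ValueError("all expression effects are zero: Wald ratio undefined")
    return float((x * y).sum() / sxx)


def bootstrap_p(instrument: pd.DataFrame, n_sims: int = N_BOOTSTRAP,
                seed: int = 0) -> dict:
    """Parametric-bootstrap two-tailed p and percentile 95% CI for the slope.

    Each simulation redraws every SNP's expression and disease effects
    independently from Normal(estimate, SE) on the raw scale, rescales by
    the MAF factor, and recomputes the through-origin slope. The two-tailed
    p is 2 * min(frac <= 0, frac >= 0), floored at 2/n_sims.
    """
    if n_sims < 100:
        raise ValueError("n_sims < 100 gives a meaningless bootstrap")
    if n_sims < 1000:
        warnings.warn("n_sims < 1000: bootstrap p is coarse", stacklevel=2)
    if (instrument[["se_expr", "se_disease"]] <= 0).any().any():
        raise ValueError("all SEs must be positive")
    rng = np.random.default_rng(seed)
    fac = np.sqrt(2.0 * instrument["maf"].to_numpy()
                  * (1.0 - instrument["maf"].to_numpy()))
    bx = instrument["beta_expr"].to_numpy()
    by = instrument["beta_disease"].to_numpy()
    sx = instrument["se_expr"].to_numpy()
    sy = instrument["se_disease"].to_numpy()
    k = len(instrument)
    x = (bx + rng.standard_normal((n_sims, k)) * sx) * fac
    y = (by + rng.standard_normal((n_sims, k)) * sy) * fac
    sxx = (x**2).sum(axis=1)
    sxx[sxx == 0] = np.nan
    slopes = (x * y).sum(axis=1) / sxx
    slopes = slopes[np.isfinite(slopes)]
    frac_le = (slopes <= 0).mean()
    frac_ge = (slopes >= 0).mean()
    p = max(2.0 * min(frac_le, frac_ge), 2.0 / n_sims)
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return {"p": float(min(p, 1.0)), "ci_low": float(lo), "ci_high": float(hi),
            "n_sims": int(n_sims), "seed": int(seed)}


def egger_mr(instrument: pd.DataFrame) -> dict:
    """Egger regression: free intercept, inverse-variance weights.

    Alleles are oriented so every scaled expression effect is nonnegative
    (disease effect flipped coherently) before the weighted fit; a nonzero
    intercept signals directional pleiotropy.
    """
    if len(instrument) < 3:
        raise ValueError("Egger regression needs at least 3 instrument SNPs")
    x = instrument["scaled_beta_expr"].to_numpy(dtype=float).copy()
    y = instrument["scaled_beta_disease"].to_numpy(dtype=float).copy()
    flip = x < 0
    x[flip] *= -1.0
    y[flip] *= -1.0
    w = 1.0 / instrument["scaled_se_disease"].to_numpy(dtype=float) ** 2
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    return {"egger_intercept": float(fit.params[0]),
            "egger_intercept_p": float(fit.pvalues[0]),
            "egger_slope": float(fit.params[1]),
            "egger_slope_p": float(fit.pvalues[1])}


@dataclass
class MRResult:
    instrument: pd.DataFrame
    wald_slope: float
    bootstrap_p: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    egger_intercept: float | None
    egger_intercept_p: float | None
    egger_slope: float | None
    seed: int


def run_mr(instrument: pd.DataFrame, n_sims: int = N_BOOTSTRAP,
           seed: int = 0) -> MRResult:
    """Wald slope + bootstrap inference + Egger check on a built instrument."""
    slope = wald_mr(instrument)
    boot = bootstrap_p(instrument, n_sims=n_sims, seed=seed)
    egger = {"egger_intercept": None, "egger_intercept_p": None,
             "egger_slope": None}
    if len(instrument) >= 3:
        egger = egger_mr(instrument)
    return MRResult(instrument=instrument, wald_slope=slope,
                    bootstrap_p=boot["p"], ci_low=boot["ci_low"],
                    ci_high=boot["ci_high"], n_bootstrap=n_sims,
                    egger_intercept=egger["egger_intercept"],
                    egger_intercept_p=egger["egger_intercept_p"],
                    egger_slope=egger["egger_slope"], seed=seed)


def pleiotropy_scan(instrument: pd.DataFrame, neighbor_adj: AdjustedExpression,
                    g: GenotypeMatrix, alpha: float = 0.05,
                    per_snp_denominator: bool = False) -> pd.DataFrame:
    """Association of each instrument SNP with each nearby gene's expression.

    OLS of every neighbor probe's adjusted expression on every instrument
    SNP's dosage. Flags p below the Bonferroni threshold alpha /
    (n_snps * n_genes), or alpha / n_snps with per_snp_denominator=True.
    Returns the full table regardless of flags.
    """
    genes = list(neighbor_adj.probes["probe"])
    if not genes:
        warnings.warn("no neighbor genes supplied: empty pleiotropy table",
                      stacklevel=2)
        return pd.DataFrame(columns=["snp", "probe", "beta", "se", "p",
                                     "threshold", "flagged"])
    snps = list(instrument["snp"])
    n_tests = len(snps) if per_snp_denominator else len(snps) * len(genes)
    threshold = alpha / n_tests
    var_ids = list(g.variants["id"])
    expr = neighbor_adj.masked_values()
    rows = []
    for snp in snps:
        d = g.dosages[:, var_ids.index(snp)]
        for pj, probe in enumerate(genes):
            yv = expr[:, pj]
            ok = ~np.isnan(d) & ~np.isnan(yv)
            x, yy = d[ok], yv[ok]
            sx = x - x.mean()
            sxx = float((sx**2).sum())
            if sxx == 0 or ok.sum() < 3:
                beta = se = p = np.nan
            else:
                beta = float((sx * (yy - yy.mean())).sum() / sxx)
                resid = (yy - yy.mean()) - beta * sx
                df = ok.sum() - 2
                se = float(np.sqrt((resid**2).sum() / df / sxx))
                tstat = beta / se if se > 0 else np.inf
                p = float(2 * stats.t.sf(abs(tstat), df))
            rows.append({"snp": snp, "probe": probe, "beta": beta, "se": se,
                         "p": p, "threshold": threshold,
                         "flagged": bool(p < threshold) if np.isfinite(p) else False})
    return pd.DataFrame(rows)
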