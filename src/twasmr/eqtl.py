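"""Expression adjustment and cis-eQTL mapping.

Expression is first residualized on age and sex with a robust (Huber
M-estimator) linear fit per probe, and residuals more than three SDs from
the per-probe median are masked. cis-eQTLs are then mapped by ordinary
least squares of the adjusted expression on allele dosage for every
SNP-probe pair within 1 Mb (a 2 Mb window centered on the probe anchor),
with the variance explained reported as the squared dosage-expression
correlation and Benjamini-Hochberg q-values over all tested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AdjustedExpression, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
CIS_WINDOW = 1_000_000  # 1 Mb each side of the probe anchor
SIGNIFICANCE_P = 1e-8


def adjust_expression(expr: ExpressionMatrix, samples: pd.DataFrame,
                      covariates: tuple[str, ...] = ("age", "sex"),
                      outlier_sd: float = 3.0) -> AdjustedExpression:
    """Residualize each probe on covariates robustly; mask extreme residuals.

    A Huber M-estimated linear model is fitted per probe; residuals replace
    raw values, and entries with |residual - median| > outlier_sd * SD (both
    computed per probe) are masked out of all downstream fits. Constant
    probes yield zero residuals without error.
    """
    tbl = samples.set_index("id").loc[expr.samples]
    for c in covariates:
        if c not in tbl or tbl[c].isna().any():
            raise ValueError(f"covariate '{c}' missing or incomplete")
    X = sm.add_constant(tbl[list(covariates)].to_numpy(dtype=float))
    n, p = expr.values.shape
    resid = np.empty((n, p))
    mask = np.ones((n, p), dtype=bool)
    for j in range(p):
        y = expr.values[:, j]
        if np.ptp(y) == 0:
            resid[:, j] = 0.0
            continue
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # perfect fits emit a scale warning
                fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        r = fit.resid
        resid[:, j] = r
        sd = r.std(ddof=1)
        if sd > 0:
            mask[:, j] = np.abs(r - np.median(r)) <= outlier_sd * sd
    return AdjustedExpression(samples=list(expr.samples), probes=expr.probes,
                              residuals=resid, mask=mask,
                              covariates_used=list(covariates))


def _ols_snp_probe(dosage: np.ndarray, expr: np.ndarray) -> tuple[float, ...]:
    """Simple OLS of expression on dosage: beta, se, t, p, r2, n."""
    ok = ~np.isnan(dosage) & ~np.isnan(expr)
    n = int(ok.sum())
    if n < 3:
        return (np.nan,) * 5 + (n,)
    x, y = dosage[ok], expr[ok]
    sx = x - x.mean()
    sy = y - y.mean()
    sxx = (sx**2).sum()
    if sxx == 0:
        return (np.nan,) * 5 + (n,)
    beta = (sx * sy).sum() / sxx
    resid = sy - beta * sx
    df = n - 2
    sigma2 = (resid**2).sum() / df
    se = np.sqrt(sigma2 / sxx)
    syy = (sy**2).sum()
    r2 = (sx * sy).sum() ** 2 / (sxx * syy) if syy > 0 else np.nan
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = P_FLOOR if beta != 0 else 1.0
    else:
        t = beta / se
        p = max(2 * stats.t.sf(abs(t), df), P_FLOOR)
    return beta, se, t, p, r2, n


def cis_pairs(variants: pd.DataFrame, probes: pd.DataFrame,
              window: int = CIS_WINDOW) -> list[tuple[int, int]]:
    """Indices (snp, probe) with |snp.pos - probe.position| <= window, same chrom."""
    pairs = []
    for pj, probe in probes.iterrows():
        same = variants["chrom"] == probe["chrom"]
        near = (variants["pos"] - probe["position"]).abs() <= window
        for sj in np.flatnonzero(same & near):
            pairs.append((int(sj), int(pj)))
    return pairs


def map_cis_eqtl(g: GenotypeMatrix, adj: AdjustedExpression,
                 window: int = CIS_WINDOW,
                 significance_p: float = SIGNIFICANCE_P) -> pd.DataFrame:
    """OLS cis-eQTL scan over all SNP-probe pairs within the window.

    Masked expression entries are dropped pairwise per fit; n is reported per
    record. Returns a table with (snp, probe, gene, beta, se, t, p, r2, fdr,
    n, significant); q-values are BH over all tested pairs.
    """
    shared = [s for s in g.samples if s in set(adj.samples)]
    if len(shared) < 30:
        raise ValueError(f"only {len(shared)} shared samples (< 30)")
    g_idx = [g.samples.index(s) for s in shared]
    e_idx = [adj.samples.index(s) for s in shared]
    dosages = g.dosages[g_idx]
    expr = adj.masked_values()[e_idx]
    pairs = cis_pairs(g.variants, adj.probes, window)
    if not pairs:
        logger.warning("no cis SNP-probe pairs within %d bp", window)
        return pd.DataFrame(columns=["snp", "probe", "gene", "beta", "se", "t",
                                     "p", "r2", "fdr", "n", "significant"])
    rows = []
    for sj, pj in pairs:
        beta, se, t, p, r2, n = _ols_snp_probe(dosages[:, sj], expr[:, pj])
        rows.append({"snp": g.variants["id"].iloc[sj],
                     "probe": adj.probes["probe"].iloc[pj],
                     "gene": adj.probes["gene"].iloc[pj],
                     "beta": beta, "se": se, "t": t, "p": p, "r2": r2, "n": n})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["p"] < significance_p
    return out


def prune_independent(records: pd.DataFrame, g: GenotypeMatrix,
                      r2_threshold: float = 0.8) -> pd.DataFrame:
    """Greedy LD pruning of one probe's eQTL records to independent SNPs.

    Repeatedly takes the most significant remaining SNP and drops every SNP
    whose squared dosage correlation with any selected SNP is >= threshold.
    Ties on p are broken by |t| then position.
    """
    if records.empty:
        return records
    recs = records.copy()
    snp_order = {s: i for i, s in enumerate(g.variants["id"])}
    recs["_col"] = recs["snp"].map(snp_order)
    recs["_pos"] = recs["_col"].map(lambda c: g.variants["pos"].iloc[c])
    recs = recs.sort_values(["p", "t", "_pos"],
                            key=lambda col: -col.abs() if col.name == "t" else col)
    dos = g.dosages
    chosen: list[int] = []
    keep_rows = []
    for ridx, row in recs.iterrows():
        c = int(row["_col"])
        independent = True
        for sel in chosen:
            ok = ~np.isnan(dos[:, c]) & ~np.isnan(dos[:, sel])
            if ok.sum() < 3:
                continue
            r = np.corrcoef(dos[ok, c], dos[ok, sel])[0, 1]
            if r**2 >= r2_threshold:
                independent = False
                break
        if independent:
            chosen.append(c)
            keep_rows.append(ridx)
    return records.loc[keep_rows].copy()


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EqtlCounts:
    """Both conventions for counting 'independent eQTLs'."""

    pairs_tested: int
    pairs_significant: int
    independent_after_pruning: int
    probes_with_signal: int


def count_eqtls(records: pd.DataFrame, g: GenotypeMatrix,
                significance_p: float = SIGNIFICANCE_P,
                r2_threshold: float = 0.8) -> EqtlCounts:
    sig = records[records["p"] < significance_p]
    n_indep = 0
    for _, grp in sig.groupby("probe"):
        n_indep += len(prune_independent(grp, g, r2_threshold))
    return EqtlCounts(pairs_tested=len(records), pairs_significant=len(sig),
                      independent_after_pruning=n_indep,
                      probes_with_signal=sig["probe"].nunique())
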