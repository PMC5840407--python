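"""Population-attributable risk, fixed-effect meta-analysis, severity models.

PAR% = 100 * P * (OR - 1) / [P * (OR - 1) + 1] with P the control-group
risk-allele frequency (an external reference frequency may be substituted
explicitly). Study pooling is inverse-variance-weighted fixed-effect on the
log-odds scale. Expression-severity associations are ordinary linear
regressions of each hemodynamic severity measure on adjusted expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeMatrix
from .gwas import logistic_assoc


def par_percent(p_risk: float, or_: float) -> float:
    """Population-attributable risk percentage.

    p_risk is the risk-allele frequency in controls (or an explicit external
    reference frequency); or_ the allelic odds ratio. Protective alleles
    (OR < 1) return a negative PAR with a warning.
    """
    if not (0.0 < p_risk < 1.0):
        raise ValueError("p_risk must lie in (0, 1)")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    par = 100.0 * p_risk * (or_ - 1.0) / (p_risk * (or_ - 1.0) + 1.0)
    if or_ < 1.0:
        warnings.warn("OR < 1: negative PAR (protective allele)", stacklevel=2)
    return par


def ivw_meta(effects: pd.DataFrame) -> dict:
    """Fixed-effect inverse-variance-weighted pooling of log-odds effects.

    effects needs columns (label, beta, se). Returns pooled beta, se, z, p
    and the odds ratio with its 95% CI, plus per-study weights for a forest
    plot.
    """
    if effects.empty:
        raise ValueError("at least one study required")
    se = effects["se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("all study SEs must be positive")
    beta = effects["beta"].to_numpy(dtype=float)
    w = 1.0 / se**2
    pooled_beta = float((w * beta).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled_beta / pooled_se
    return {
        "beta": pooled_beta, "se": pooled_se, "z": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
        "or": float(np.exp(pooled_beta)),
        "ci_low": float(np.exp(pooled_beta - 1.96 * pooled_se)),
        "ci_high": float(np.exp(pooled_beta + 1.96 * pooled_se)),
        "weights": (w / w.sum()).tolist(),
    }


def severity_assoc(expression: np.ndarray, severity: pd.DataFrame,
                   covariates: pd.DataFrame | None = None,
                   min_n: int = 10) -> pd.DataFrame:
    """Regress each severity measure on adjusted expression.

    expression is the adjusted expression vector for one probe, aligned with
    the severity table rows; NaNs are dropped pairwise. Optional covariates
    (e.g. age, sex, body surface area) are added to the model. Returns one
    row per measure with slope, se, t, p, n and the 95% prediction-band
    inputs (fit, fit_se per observation are omitted; slope CI is returned).
    """
    x = np.asarray(expression, dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError("expression is constant")
    rows = []
    for col in severity.columns:
        if col == "id":
            continue
        y = severity[col].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        C = covariates.to_numpy(dtype=float) if covariates is not None else \
            np.empty((x.size, 0))
        if covariates is not None:
            ok &= ~np.isnan(C).any(axis=1)
        if ok.sum() < min_n:
            raise ValueError(f"measure '{col}': {ok.sum()} paired observations "
                             f"(< {min_n})")
        X = sm.add_constant(np.column_stack([x[ok], C[ok]]))
        fit = sm.OLS(y[ok], X).fit()
        rows.append({"measure": col, "slope": float(fit.params[1]),
                     "se": float(fit.bse[1]), "t": float(fit.tvalues[1]),
                     "p": float(fit.pvalues[1]), "n": int(ok.sum()),
                     "ci_low": float(fit.params[1] - 1.96 * fit.bse[1]),
                     "ci_high": float(fit.params[1] + 1.96 * fit.bse[1])})
    return pd.DataFrame(rows)


def dubois_bsa(height_cm: float | np.ndarray, weight_kg: float | np.ndarray
               ) -> float | np.ndarray:
    """DuBois & DuBois body surface area (m^2)."""
    return 0.007184 * np.asarray(height_cm, dtype=float) ** 0.725 \
        * np.asarray(weight_kg, dtype=float) ** 0.425


@dataclass
class StratumComparison:
    strata: dict[str, dict]
    ci_overlap: bool


def stratified_assoc(g: GenotypeMatrix, table: pd.DataFrame, stratum: str,
                     snp: str, covariates: list[str] | None = None,
                     min_cases: int = 50) -> StratumComparison:
    """Per-stratum logistic association for one SNP, with CI-overlap check."""
    var_idx = list(g.variants["id"]).index(snp)
    results = {}
    for level, sub in table.groupby(stratum):
        n_cases = int((sub["status"] == "case").sum())
        if len(sub) == 0:
            raise ValueError(f"stratum {level} is empty")
        if n_cases < min_cases:
            raise ValueError(f"stratum {level} has {n_cases} cases (< {min_cases})")
        idx = [g.samples.index(s) for s in sub["id"]]
        sub_g = g.subset(sample_idx=np.array(idx),
                         variant_idx=np.array([var_idx]))
        res = logistic_assoc(sub_g, sub, covariates or [])
        results[str(level)] = res.iloc[0].to_dict()
    levels = list(results)
    overlap = True
    if len(levels) >= 2:
        a, b = results[levels[0]], results[levels[1]]
        overlap = not (a["ci_low"] > b["ci_high"] or b["ci_low"] > a["ci_high"])
    return StratumComparison(strata=results, ci_overlap=bool(overlap))
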