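"""Transcriptome-wide association from reference-panel expression weights.

Per-probe cis expression-prediction weights (top1 / lasso / elastic net) are
learned in the reference panel on standardized dosages, with out-of-fold
cross-validation R2 deciding the model; the association statistic combines
the weights w with GWAS summary z-scores through the reference LD matrix R:

    z_TWAS = (w' z) / sqrt(w' R w)

with R mildly ridge-regularized before the quadratic form. Probes whose
best cross-validated R2 is <= 0 carry no predictive weights and are
excluded from the scan (the exclusion is reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

from .datatypes import AdjustedExpression, GenotypeMatrix

logger = logging.getLogger(__name__)

WEIGHT_WINDOW = 500_000  # each side of the probe anchor
TWAS_ALPHA = 1e-4
LD_RIDGE = 0.1
P_FLOOR = 1e-300
DENOM_FLOOR = 1e-12

MODELS = ("top1", "lasso", "enet")


@dataclass
class WeightSet:
    """Cis prediction weights for one probe, on the standardized-dosage scale."""

    probe: str
    gene: str
    snp_ids: list[str]
    weights: dict[str, np.ndarray]          # model -> weight vector
    cv_r2: dict[str, float]                 # model -> out-of-fold R2
    selected_model: str
    snp_mean: np.ndarray = field(default=None, repr=False)
    snp_sd: np.ndarray = field(default=None, repr=False)

    @property
    def heritable(self) -> bool:
        return max(self.cv_r2.values()) > 0

    def selected_weights(self) -> np.ndarray:
        return self.weights[self.selected_model]


@dataclass
class LDMatrix:
    """Reference-panel dosage correlation matrix over a SNP set."""

    snp_ids: list[str]
    matrix: np.ndarray

    @classmethod
    def from_genotypes(cls, g: GenotypeMatrix,
                       snp_ids: list[str] | None = None) -> "LDMatrix":
        ids = snp_ids if snp_ids is not None else list(g.variants["id"])
        cols = [list(g.variants["id"]).index(s) for s in ids]
        X = g.dosages[:, cols].copy()
        mu = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mu, inds[1])
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        R = (Xs.T @ Xs) / Xs.shape[0]
        np.fill_diagonal(R, 1.0)
        return cls(snp_ids=ids, matrix=R)

    def subset(self, snp_ids: list[str]) -> "LDMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LDMatrix(snp_ids=list(snp_ids),
                        matrix=self.matrix[np.ix_(idx, idx)])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


def _marginal_best(Xs: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Index and OLS slope of the SNP most correlated with y (standardized X)."""
    yc = y - y.mean()
    n = Xs.shape[0]
    cov = Xs.T @ yc / n
    varx = (Xs**2).mean(axis=0)
    varx[varx == 0] = np.inf
    slopes = cov / varx
    score = np.abs(cov) / np.sqrt(varx)
    j = int(np.argmax(score))
    return j, float(slopes[j])


def _oof_r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1.0 - ((y - pred) ** 2).sum() / ss_tot)


def compute_weights(g_ref: GenotypeMatrix, adj: AdjustedExpression,
                    probe: str, window: int = WEIGHT_WINDOW,
                    cv_folds: int = 5, seed: int = 0) -> WeightSet | None:
    """Learn top1 / lasso / elastic-net weights for one probe.

    Penalty strengths are chosen by internal cross-validation within each
    training fold, so the recorded per-model R2 is a genuine out-of-fold
    prediction R2; the model with the best R2 is selected and refitted on
    the full panel. Returns None (with a logged reason) if no SNP falls in
    the window.
    """
    prow = adj.probes.loc[adj.probes["probe"] == probe].iloc[0]
    near = ((g_ref.variants["chrom"] == prow["chrom"]) &
            ((g_ref.variants["pos"] - prow["position"]).abs() <= window))
    cols = np.flatnonzero(near.to_numpy())
    if cols.size == 0:
        logger.warning("probe %s skipped: no SNPs within %d bp", probe, window)
        return None
    pj = int(adj.probes.index[adj.probes["probe"] == probe][0])
    usable = adj.mask[:, pj]
    y = adj.residuals[usable, pj]
    X = g_ref.dosages[np.ix_(np.flatnonzero(usable), cols)].copy()
    mu_nan = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu_nan, inds[1])
    Xs, mu, sd = _standardize(X)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    oof = {m: np.zeros_like(y) for m in MODELS}
    for train, test in kf.split(Xs):
        jt, bt = _marginal_best(Xs[train], y[train])
        oof["top1"][test] = y[train].mean() + bt * (Xs[test, jt] - Xs[train, jt].mean())
        for m, est in (("lasso", LassoCV(cv=3, random_state=seed, max_iter=5000)),
                       ("enet", ElasticNetCV(l1_ratio=0.5, cv=3, random_state=seed,
                                             max_iter=5000))):
            est.fit(Xs[train], y[train])
            oof[m][test] = est.predict(Xs[test])
    cv_r2 = {m: _oof_r2(y, oof[m]) for m in MODELS}

    weights: dict[str, np.ndarray] = {}
    j1, b1 = _marginal_best(Xs, y)
    w_top1 = np.zeros(cols.size)
    w_top1[j1] = b1
    weights["top1"] = w_top1
    for m, est in (("lasso", LassoCV(cv=cv_folds, random_state=seed, max_iter=5000)),
                   ("enet", ElasticNetCV(l1_ratio=0.5, cv=cv_folds,
                                         random_state=seed, max_iter=5000))):
        est.fit(Xs, y)
        weights[m] = est.coef_.copy()
    selected = max(MODELS, key=lambda m: cv_r2[m])
    return WeightSet(probe=probe, gene=prow["gene"],
                     snp_ids=list(g_ref.variants["id"].iloc[cols]),
                     weights=weights, cv_r2=cv_r2, selected_model=selected,
                     snp_mean=mu, snp_sd=sd)


@dataclass
class TwasResult:
    probe: str
    gene: str
    z_twas: float
    p_twas: float
    n_snps: int
    n_dropped: int
    selected_model: str
    flagged: bool = False  # degenerate weight/LD combination

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_twas) and self.p_twas < TWAS_ALPHA


def twas_assoc(weights: WeightSet, gwas_z: pd.Series | dict,
               ld: LDMatrix, ridge: float = LD_RIDGE) -> TwasResult:
    """Summary-statistic TWAS test: z = w'z / sqrt(w'Rw).

    SNPs without a GWAS z-score are dropped (count recorded); the LD matrix
    is shrunk as (1-ridge)*R + ridge*I before the quadratic form. A
    non-positive (sub-floor) denominator yields a flagged result.
    """
    z_map = dict(gwas_z) if not isinstance(gwas_z, dict) else gwas_z
    have = [s for s in weights.snp_ids if s in z_map and np.isfinite(z_map[s])]
    dropped = len(weights.snp_ids) - len(have)
    w_full = weights.selected_weights()
    idx = [weights.snp_ids.index(s) for s in have]
    w = w_full[idx]
    if len(have) == 0 or not np.any(w != 0):
        return TwasResult(weights.probe, weights.gene, np.nan, np.nan,
                          0, dropped, weights.selected_model, flagged=True)
    z = np.array([z_map[s] for s in have])
    R = ld.subset(have).matrix
    R_reg = (1.0 - ridge) * R + ridge * np.eye(len(have))
    denom2 = float(w @ R_reg @ w)
    if denom2 <= DENOM_FLOOR:
        return TwasResult(weights.probe, weights.gene, np.nan, np.nan,
                          len(have), dropped, weights.selected_model, flagged=True)
    z_twas = float(w @ z) / np.sqrt(denom2)
    p = max(2 * stats.norm.sf(abs(z_twas)), P_FLOOR)
    return TwasResult(weights.probe, weights.gene, z_twas, p,
                      int(np.sum(w != 0)), dropped, weights.selected_model)


def transcriptome_scan(weight_sets: list[WeightSet], gwas_results: pd.DataFrame,
                       ld_reference: GenotypeMatrix,
                       alpha: float = TWAS_ALPHA,
                       ridge: float = LD_RIDGE) -> pd.DataFrame:
    """Run the TWAS test for every heritable probe; rank by p.

    gwas_results must carry columns (id, z). Probes with best CV R2 <= 0 are
    excluded and listed with excluded=True; the significance flag applies
    p < alpha to the scanned probes.
    """
    z = gwas_results.set_index("id")["z"]
    rows = []
    for ws in weight_sets:
        if ws is None:
            continue
        if not ws.heritable:
            rows.append({"probe": ws.probe, "gene": ws.gene, "z_twas": np.nan,
                         "p_twas": np.nan, "n_snps": 0, "model": ws.selected_model,
                         "cv_r2": max(ws.cv_r2.values()), "excluded": True,
                         "significant": False})
            continue
        ld = LDMatrix.from_genotypes(ld_reference, ws.snp_ids)
        res = twas_assoc(ws, z, ld, ridge=ridge)
        rows.append({"probe": res.probe, "gene": res.gene, "z_twas": res.z_twas,
                     "p_twas": res.p_twas, "n_snps": res.n_snps,
                     "model": res.selected_model, "cv_r2": max(ws.cv_r2.values()),
                     "excluded": False,
                     "significant": bool(np.isfinite(res.p_twas) and res.p_twas < alpha)})
    out = pd.DataFrame(rows, columns=["probe", "gene", "z_twas", "p_twas",
                                      "n_snps", "model", "cv_r2", "excluded",
                                      "significant"])
    if out.empty:
        return out
    return out.sort_values("p_twas", na_position="last").reset_index(drop=True)
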