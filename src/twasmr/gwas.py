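"""Case-control GWAS: variant/sample QC, dosage logistic regression, diagnostics.

The association model is the standard additive logistic regression on
expected allele dosages with age, sex and ancestry principal components as
covariates; per-variant Wald statistics are reported as log-odds (beta), SE,
Z, p and OR with 95% CI. QC mirrors array-genotyping practice: variant call
rate, minor allele frequency, Hardy-Weinberg equilibrium, differential
case/control missingness, then sample call rate, heterozygosity-based
inbreeding F, and identity-by-state relatedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeMatrix

CHI2_1DF_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45493...

P_FLOOR = 1e-300


@dataclass
class VariantThresholds:
    call_rate: float = 0.97
    maf: float = 0.01
    hwe_p: float = 1e-7
    diff_missing_p: float = 1e-6
    imputation_r2: float | None = 0.3  # variants with r2 <= this are removed

    def validate(self) -> None:
        for name in ("call_rate", "maf", "hwe_p", "diff_missing_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside [0, 1]")
        if self.imputation_r2 is not None and not (0.0 <= self.imputation_r2 <= 1.0):
            raise ValueError("imputation_r2 threshold outside [0, 1]")


@dataclass
class SampleThresholds:
    call_rate: float = 0.95
    inbreeding_f: float = 0.20
    relatedness: float = 0.4  # PI-HAT-style first-degree proxy

    def validate(self) -> None:
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError("sample call_rate threshold outside [0, 1]")


@dataclass
class QCReport:
    """Removal counts per filter (in application order) and survivors."""

    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    surviving_variants: list[str] = field(default_factory=list)
    surviving_samples: list[str] = field(default_factory=list)
    lambda_gc: float | None = None


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (with fixed allele
    counts) no more probable than the observed one.
    """
    n_hom_rare, n_hom_common = sorted((n_hom1, n_hom2))
    rare = 2 * n_hom_rare + n_het
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    # heterozygote count has the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each possible het count
    from scipy.special import gammaln
    hom_r = (rare - het_values) // 2
    hom_c = n - het_values - hom_r
    valid = hom_c >= 0
    het_values, hom_r, hom_c = het_values[valid], hom_r[valid], hom_c[valid]
    logp = (het_values * np.log(2.0)
            - gammaln(het_values + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[het_values == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom2 + n_het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, 1))


def hwe_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """HWE p-value: exact test for rare alleles or sparse cells, else chi-square."""
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    p_alt = (2 * n_hom_alt + n_het) / (2 * n)
    maf = min(p_alt, 1 - p_alt)
    expected = np.array([n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt),
                         n * p_alt**2])
    if maf < 0.05 or expected.min() < 5:
        return hwe_exact_p(n_het, n_hom_ref, n_hom_alt)
    return hwe_chi2_p(n_het, n_hom_ref, n_hom_alt)


def _genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(calls)
    c = calls[ok]
    return int((c == 1).sum()), int((c == 0).sum()), int((c == 2).sum())


def filter_variants(g: GenotypeMatrix, status: np.ndarray | pd.Series,
                    thresholds: VariantThresholds | None = None
                    ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant QC in a fixed, reported order.

    Order: call rate -> MAF -> HWE (full sample, on rounded calls) ->
    differential case/control call rate -> optional imputation r2. Each
    filter sees only variants surviving the previous ones, so the removal
    counts partition the removed set.
    """
    thresholds = thresholds or VariantThresholds()
    thresholds.validate()
    status = np.asarray(status)
    is_case = status == (1 if status.dtype.kind in "biuf" else "case")
    dos = g.dosages
    calls = g.hard_calls()
    report = QCReport()
    alive = np.ones(g.n_variants, dtype=bool)

    def apply(name: str, bad: np.ndarray) -> None:
        bad = bad & alive
        report.removed[name] = int(bad.sum())
        report.removed_ids[name] = list(g.variants.loc[bad, "id"])
        alive[bad] = False

    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    apply("call_rate", call_rate < thresholds.call_rate)

    maf = g.maf()
    apply("maf", maf < thresholds.maf)

    hwe = np.ones(g.n_variants)
    for j in np.flatnonzero(alive):
        het, hom_r, hom_a = _genotype_counts(calls[:, j])
        hwe[j] = hwe_p(het, hom_r, hom_a)
    apply("hwe", hwe < thresholds.hwe_p)

    diff_p = np.ones(g.n_variants)
    miss = np.isnan(dos)
    for j in np.flatnonzero(alive):
        m_case = int(miss[is_case, j].sum())
        m_ctrl = int(miss[~is_case, j].sum())
        n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
        if m_case + m_ctrl == 0:
            continue
        table = np.array([[m_case, n_case - m_case], [m_ctrl, n_ctrl - m_ctrl]])
        diff_p[j] = stats.chi2_contingency(table, correction=False)[1]
    apply("diff_missing", diff_p < thresholds.diff_missing_p)

    if thresholds.imputation_r2 is not None and "imputation_r2" in g.variants:
        r2 = g.variants["imputation_r2"].to_numpy(dtype=float)
        apply("imputation_r2", np.nan_to_num(r2, nan=1.0) <= thresholds.imputation_r2)

    report.surviving_variants = list(g.variants.loc[alive, "id"])
    return g.subset(variant_idx=np.flatnonzero(alive)), report


def inbreeding_f(calls: np.ndarray) -> np.ndarray:
    """Per-sample inbreeding coefficient F = 1 - observed het / expected het."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    exp_het_snp = 2.0 * p * (1.0 - p)
    obs_het = (calls == 1)
    seen = ~np.isnan(calls)
    f = np.empty(calls.shape[0])
    for i in range(calls.shape[0]):
        s = seen[i]
        exp = exp_het_snp[s].mean() if s.any() else np.nan
        obs = obs_het[i, s].mean() if s.any() else np.nan
        f[i] = 1.0 - obs / exp if exp and exp > 0 else np.nan
    return f


def relatedness_matrix(calls: np.ndarray) -> np.ndarray:
    """PI-HAT-style pairwise relatedness from identity-by-state sharing.

    For each pair, the mean IBS share (1 - |gi - gj|/2) over co-observed
    hard calls is normalized against its expectation under HWE independence:
    (observed - expected) / (1 - expected). Duplicates score 1, unrelated
    pairs ~0, first-degree relatives roughly 0.4-0.6.
    """
    n = calls.shape[0]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # genotype probs
    share = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
    exp_share_snp = np.einsum("as,ab,bs->s", probs, share, probs)
    rel = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            if not both.any():
                continue
            obs = (1.0 - np.abs(calls[i, both] - calls[j, both]) / 2.0).mean()
            exp = exp_share_snp[both].mean()
            rel[i, j] = rel[j, i] = (obs - exp) / (1.0 - exp) if exp < 1 else 1.0
    return rel


def filter_samples(g: GenotypeMatrix, table: pd.DataFrame,
                   thresholds: SampleThresholds | None = None,
                   exclude_ids: list[str] | None = None
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Sample QC: call rate, inbreeding F, IBS relatedness, external lists.

    Sex-mismatch / ancestry-outlier removals are accepted as a precomputed
    ``exclude_ids`` list. For each related pair above the first-degree proxy
    the member with the lower call rate is dropped.
    """
    thresholds = thresholds or SampleThresholds()
    thresholds.validate()
    if g.n_samples < 2:
        raise ValueError("sample QC needs at least 2 samples")
    calls = g.hard_calls()
    report = QCReport()
    alive = np.ones(g.n_samples, dtype=bool)
    ids = np.array(g.samples)

    def apply(name: str, bad: np.ndarray) -> None:
        bad = bad & alive
        report.removed[name] = int(bad.sum())
        report.removed_ids[name] = list(ids[bad])
        alive[bad] = False

    if exclude_ids:
        apply("exclusion_list", np.isin(ids, exclude_ids))

    call_rate = 1.0 - np.isnan(calls).mean(axis=1)
    apply("call_rate", call_rate < thresholds.call_rate)

    f = inbreeding_f(calls[alive])
    f_full = np.zeros(g.n_samples)
    f_full[alive] = f
    apply("inbreeding_f", np.nan_to_num(f_full, nan=0.0) > thresholds.inbreeding_f)

    idx = np.flatnonzero(alive)
    rel = relatedness_matrix(calls[idx])
    drop = set()
    pairs = np.argwhere(np.triu(rel, 1) > thresholds.relatedness)
    for a, b in pairs:
        if a in drop or b in drop:
            continue
        ca, cb = call_rate[idx[a]], call_rate[idx[b]]
        drop.add(a if ca <= cb else b)
    bad = np.zeros(g.n_samples, dtype=bool)
    bad[idx[list(drop)]] = True if drop else False
    apply("relatedness", bad)

    report.surviving_samples = list(ids[alive])
    return g.subset(sample_idx=np.flatnonzero(alive)), report


def _status_vector(table: pd.DataFrame) -> np.ndarray:
    s = table["status"]
    if s.dtype.kind in "biuf":
        return s.to_numpy(dtype=float)
    return (s == "case").to_numpy(dtype=float)


def logistic_assoc(g: GenotypeMatrix, table: pd.DataFrame,
                   covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-variant additive logistic regression of case status on dosage.

    Fits status ~ dosage + covariates by maximum likelihood for each variant,
    dropping samples with missing dosage per variant. Degenerate predictors
    (no dosage variance) and non-converged / separated fits are flagged with
    converged=False and missing (NaN) statistics, never silently.
    """
    covariates = covariates or []
    table = table.set_index("id").loc[g.samples]
    y = _status_vector(table.reset_index())
    covar = table[covariates].to_numpy(dtype=float) if covariates else \
        np.empty((g.n_samples, 0))
    if np.isnan(covar).any():
        raise ValueError("missing covariate values are not allowed")
    rows = []
    maf = g.maf()
    for j in range(g.n_variants):
        d = g.dosages[:, j]
        ok = ~np.isnan(d)
        res = {"id": g.variants["id"].iloc[j],
               "chrom": g.variants["chrom"].iloc[j],
               "pos": g.variants["pos"].iloc[j],
               "ref": g.variants["ref"].iloc[j],
               "alt": g.variants["alt"].iloc[j],
               "maf": maf[j], "n": int(ok.sum()),
               "beta": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
               "or_": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "converged": False}
        dj = d[ok]
        if np.ptp(dj) > 0:
            X = np.column_stack([np.ones(ok.sum()), covar[ok], dj])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y[ok], X).fit(disp=0, method="newton",
                                                 maxiter=100)
                beta = fit.params[-1]
                se = fit.bse[-1]
                if fit.mle_retvals.get("converged", False) and np.isfinite(se) \
                        and se < 1e3:
                    z = beta / se
                    res.update(beta=beta, se=se, z=z,
                               p=max(2 * stats.norm.sf(abs(z)), P_FLOOR),
                               or_=np.exp(beta),
                               ci_low=np.exp(beta - 1.96 * se),
                               ci_high=np.exp(beta + 1.96 * se),
                               converged=True)
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
                pass
        rows.append(res)
    return pd.DataFrame(rows)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor lambda_GC.

    Median of the p-values' implied 1-df chi-square statistics divided by the
    null chi-square median (~0.4549).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def pca_covariates(g: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Ancestry principal components from standardized dosages.

    Missing dosages are mean-imputed; monomorphic variants are skipped.
    Sample scores are eigen-ordered; each component's sign is fixed so its
    largest-magnitude variant loading is positive.
    """
    if k > g.n_samples:
        raise ValueError(f"k={k} exceeds sample count {g.n_samples}")
    X = g.dosages.copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= mu
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(scores, index=g.samples,
                        columns=[f"PC{i+1}" for i in range(k)])
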