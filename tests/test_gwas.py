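"""GWAS QC, dosage logistic association and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twasmr import (SimulationConfig, VariantThresholds, filter_samples,
                    filter_variants, genomic_inflation, logistic_assoc,
                    pca_covariates, simulate_genotypes)
from twasmr.gwas import hwe_chi2_p, hwe_exact_p, hwe_p, inbreeding_f

from conftest import make_genotypes


def _status(n_case, n_ctrl):
    return pd.Series(["case"] * n_case + ["control"] * n_ctrl)


def _from_counts(n_hom_ref, n_het, n_hom_alt):
    """Single-variant genotype matrix from genotype counts."""
    d = np.array([0.0] * n_hom_ref + [1.0] * n_het + [2.0] * n_hom_alt)
    return make_genotypes(d[:, None])


class TestVariantFilters:
    def test_exact_hwe_proportions_retained(self):
        g = _from_counts(25, 50, 25)
        status = _status(50, 50)
        kept, report = filter_variants(g, status)
        assert kept.n_variants == 1
        assert hwe_p(50, 25, 25) == pytest.approx(1.0, abs=0.05)

    def test_rare_variant_removed_by_maf(self):
        # MAF 0.005: one het among 100 samples
        g = _from_counts(99, 1, 0)
        kept, report = filter_variants(g, _status(50, 50))
        assert kept.n_variants == 0
        assert report.removed["maf"] == 1

    def test_het_deficit_fails_hwe(self):
        """AA=50, Aa=0, aa=50 gives chi-square 100 and p << 1e-7."""
        assert hwe_chi2_p(0, 50, 50) == pytest.approx(
            float(stats.chi2.sf(100.0, 1)), rel=1e-12)
        g = _from_counts(50, 0, 50)
        kept, report = filter_variants(g, _status(50, 50))
        assert kept.n_variants == 0
        assert report.removed["hwe"] == 1

    def test_low_call_rate_removed(self):
        d = np.full((100, 1), 1.0)
        d[:10, 0] = np.nan  # call rate 0.90 < 0.97
        kept, report = filter_variants(make_genotypes(d), _status(50, 50))
        assert report.removed["call_rate"] == 1

    def test_differential_missingness_removed(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(400, 2)).astype(float)
        d[:120, 0] = np.nan  # missing only in cases
        kept, report = filter_variants(make_genotypes(d), _status(200, 200))
        assert report.removed["call_rate"] == 1 or report.removed["diff_missing"] == 1

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_variants(_from_counts(25, 50, 25), _status(50, 50),
                            VariantThresholds(maf=1.5))

    def test_filters_idempotent(self):
        cfg = SimulationConfig(n_ref_samples=300, n_snps=50,
                               maf_range=(0.005, 0.5), seed=3)
        g = simulate_genotypes(cfg)
        status = _status(150, 150)
        once, _ = filter_variants(g, status)
        twice, rep2 = filter_variants(once, status)
        assert list(twice.variants["id"]) == list(once.variants["id"])
        assert sum(rep2.removed.values()) == 0


def test_hwe_exact_matches_chi2_at_common_maf():
    """Exact and chi-square HWE tests agree for large balanced counts."""
    p_exact = hwe_exact_p(500, 250, 250)
    p_chi2 = hwe_chi2_p(500, 250, 250)
    assert abs(p_exact - p_chi2) < 0.05


class TestSampleFilters:
    def test_duplicate_sample_flagged(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(20, 200)).astype(float)
        d[1] = d[0]  # exact duplicate
        g = make_genotypes(d)
        kept, report = filter_samples(g, pd.DataFrame({"id": g.samples}))
        assert report.removed["relatedness"] == 1
        removed = report.removed_ids["relatedness"][0]
        assert removed in (g.samples[0], g.samples[1])

    def test_all_missing_sample_removed(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        d[3] = np.nan
        g = make_genotypes(d)
        kept, report = filter_samples(g, pd.DataFrame({"id": g.samples}))
        assert g.samples[3] in report.removed_ids["call_rate"]

    def test_heterozygosity_outlier_removed(self):
        """A sample with half the expected het fraction has F ~ 0.5 > 0.2."""
        rng = np.random.default_rng(3)
        n, m = 40, 2000
        d = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        # rebuild sample 0 with het fraction halved (0.25 instead of 0.5)
        geno = rng.choice([0.0, 1.0, 2.0], size=m, p=[0.375, 0.25, 0.375])
        d[0] = geno
        f = inbreeding_f(d)
        assert abs(f[0] - 0.5) < 0.1
        g = make_genotypes(d)
        kept, report = filter_samples(g, pd.DataFrame({"id": g.samples}))
        assert g.samples[0] in report.removed_ids["inbreeding_f"]

    def test_fewer_than_two_samples_errors(self):
        g = make_genotypes(np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="2 samples"):
            filter_samples(g, pd.DataFrame({"id": g.samples}))


def _irls_logistic(y, X, tol=1e-12, max_iter=200):
    """Independent iteratively-reweighted least-squares ML logistic fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return beta, np.sqrt(np.diag(cov))


class TestLogisticAssoc:
    def test_constant_dosage_flagged(self):
        d = np.ones((100, 1))
        g = make_genotypes(d)
        table = pd.DataFrame({"id": g.samples, "status": _status(50, 50)})
        res = logistic_assoc(g, table)
        assert not res["converged"].iloc[0]
        assert np.isnan(res["p"].iloc[0])

    def test_allelic_or_and_irls_oracle(self):
        """Per-allele OR near the 2x2 allelic OR, exact match to an ML oracle.

        Cases carry 300 alt / 700 ref alleles, controls 200 / 800; the
        unadjusted allelic OR is (300/700)/(200/800) = 12/7.
        """
        # 500 cases, 500 controls; build dosages realizing those allele counts
        rng = np.random.default_rng(4)

        def dosages(n, alt):
            # HWE genotype counts realizing `alt` alternate alleles in n samples
            p = alt / (2 * n)
            n_hom = int(round(n * p**2))
            n_het = alt - 2 * n_hom
            d = np.zeros(n)
            d[:n_hom] = 2
            d[n_hom:n_hom + n_het] = 1
            return rng.permutation(d)

        d = np.concatenate([dosages(500, 300), dosages(500, 200)])[:, None]
        g = make_genotypes(d)
        table = pd.DataFrame({"id": g.samples, "status": _status(500, 500)})
        res = logistic_assoc(g, table)
        assert abs(res["or_"].iloc[0] - 12 / 7) / (12 / 7) < 0.10
        X = np.column_stack([np.ones(1000), d[:, 0]])
        y = np.array([1.0] * 500 + [0.0] * 500)
        beta_o, se_o = _irls_logistic(y, X)
        assert res["beta"].iloc[0] == pytest.approx(beta_o[1], abs=1e-6)
        assert res["se"].iloc[0] == pytest.approx(se_o[1], abs=1e-6)

    def test_null_calibration(self):
        """Under no genetic effect, ~5% of association p-values fall below 0.05."""
        rng = np.random.default_rng(5)
        n, m = 600, 400
        d = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float)
        g = make_genotypes(d)
        table = pd.DataFrame({"id": g.samples, "status": _status(300, 300)})
        res = logistic_assoc(g, table)
        frac = (res["p"].dropna() < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_internal_consistency_and_flip_sign(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, size=(400, 1)).astype(float)
        g = make_genotypes(d)
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.5 * d[:, 0] - 0.5)))).astype(int)
        table = pd.DataFrame({"id": g.samples, "status": np.where(y, "case", "control")})
        res = logistic_assoc(g, table)
        r = res.iloc[0]
        assert r["z"] == pytest.approx(r["beta"] / r["se"], abs=1e-10)
        assert r["p"] == pytest.approx(2 * stats.norm.sf(abs(r["z"])), abs=1e-10)
        flipped = make_genotypes(2.0 - d)
        res_f = logistic_assoc(flipped, table)
        assert res_f["beta"].iloc[0] == pytest.approx(-r["beta"], abs=1e-6)


class TestGenomicInflation:
    def test_all_half_gives_unity(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_near_unity(self):
        rng = np.random.default_rng(7)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert abs(lam - 1.0) < 0.02

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        chi2 = stats.chi2.rvs(1, size=5000, random_state=9)
        p1 = stats.chi2.sf(chi2, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        assert genomic_inflation(p2) == pytest.approx(2 * genomic_inflation(p1),
                                                      rel=1e-9)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))
        with pytest.raises(ValueError):
            genomic_inflation(np.array([0.0, 0.5]))


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(10)
        m = 200
        f1, f2 = rng.uniform(0.1, 0.5, m), rng.uniform(0.1, 0.5, m)
        d = np.vstack([rng.binomial(2, f1, size=(50, m)),
                       rng.binomial(2, f2, size=(50, m))]).astype(float)
        pcs = pca_covariates(make_genotypes(d), k=2)
        pc1 = pcs["PC1"].to_numpy()
        assert np.sign(pc1[:50].mean()) != np.sign(pc1[50:].mean())
        assert abs(pc1[:50].mean() - pc1[50:].mean()) > 2 * pc1.std() / np.sqrt(50)

    def test_orthogonality(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.3, size=(60, 120)).astype(float)
        pcs = pca_covariates(make_genotypes(d), k=5).to_numpy()
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_k_exceeding_rank_errors(self):
        d = np.tile(np.array([[0.0, 1.0, 2.0]]).T, (1, 8))  # rank-1
        with pytest.raises(ValueError, match="rank"):
            pca_covariates(make_genotypes(d), k=2)

    def test_rank_one_explains_everything(self):
        d = np.tile(np.array([[0.0, 1.0, 2.0]]).T, (1, 8))
        pcs = pca_covariates(make_genotypes(d), k=1)
        assert pcs["PC1"].to_numpy().var() > 0
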