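"""Synthetic genotype-expression-phenotype cohorts with known ground truth.

The simulator emulates the data structure the downstream analyses assume:

* biallelic SNPs in Hardy-Weinberg equilibrium with block-wise LD, generated
  by a Gaussian copula — each of the two allele copies is an AR(1) latent
  standard normal thresholded at ``Phi^-1(1 - MAF)``, so marginally each copy
  is Bernoulli(MAF) and adjacent SNPs are correlated through ``ld_rho``;
* probe expression with additive cis-eQTL effects plus age/sex covariate
  effects and Gaussian noise;
* case/control status from a logistic model in which the genetically
  regulated component of the causal probe's expression mediates disease risk,
  sampled by rejection until the requested case and control counts are met.

Every stage draws from an RNG derived from a single integer seed by a fixed
stream offset, so one seed reproduces the whole cohort bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix

# fixed RNG stream offsets (one per stage, single-seed reproducibility)
_STREAMS = {
    "maf": 0,
    "ref_genotypes": 1,
    "ref_covariates": 2,
    "ref_expression": 3,
    "gwas_genotypes": 4,
    "gwas_covariates": 5,
    "gwas_status": 6,
    "calibration": 7,
}

# cohort-level covariate marginals: age in years, probability male
AGE_MEAN, AGE_SD = 71.7, 8.3
P_MALE = 0.64

_CASE_CONTROL_DRAW_CAP = 10_000_000


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


class AlignmentError(ValueError):
    """Raised when sample sets of two inputs do not match."""


class SimulationError(RuntimeError):
    """Raised when case/control targets cannot be met within the draw cap."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design this simulator emulates: a 233-sample
    expression reference panel, a ~1000/1000 case-control GWAS, and a single
    cis region of common SNPs with moderate adjacent-SNP LD.
    """

    n_ref_samples: int = 233
    n_gwas_cases: int = 1000
    n_gwas_controls: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_probes: int = 5
    causal_probe_index: int = 0
    eqtl_effects: dict[int, float] = field(default_factory=dict)
    expr_noise_sd: float = 1.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    disease_logit_per_expr_sd: float = 0.0
    baseline_logit: float = -2.0
    seed: int = 0
    chrom: str = "1"
    snp_start: int = 1_000_000
    snp_spacing: int = 5_000

    def validate(self) -> None:
        for name in ("n_ref_samples", "n_gwas_cases", "n_gwas_controls",
                     "n_snps", "n_probes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.expr_noise_sd <= 0:
            raise ConfigurationError("expr_noise_sd must be > 0")
        if not (0 <= self.causal_probe_index < self.n_probes):
            raise ConfigurationError("causal_probe_index out of range")
        for idx in self.eqtl_effects:
            if not (0 <= idx < self.n_snps):
                raise ConfigurationError(f"eqtl_effects index {idx} out of range")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def snp_positions(self) -> np.ndarray:
        return self.snp_start + self.snp_spacing * np.arange(self.n_snps)

    def probe_positions(self) -> np.ndarray:
        """Probe anchors spread evenly across the SNP span (all cis-capable)."""
        pos = self.snp_positions()
        return np.linspace(pos[0], pos[-1], self.n_probes).round().astype(int)

    def true_mafs(self) -> np.ndarray:
        lo, hi = self.maf_range
        return self.rng("maf").uniform(lo, hi, size=self.n_snps)

    def effect_vector(self) -> np.ndarray:
        beta = np.zeros(self.n_snps)
        for idx, b in self.eqtl_effects.items():
            beta[idx] = b
        return beta


@dataclass
class SyntheticTruth:
    """Ground truth recorded exactly as simulated (round-trips through JSON)."""

    true_maf: list[float]
    eqtl_effects: list[float]
    causal_probe_index: int
    mediation_slope: float  # disease log-odds per unit of (raw) genetic expression
    genetic_value_sd: float  # SD of the genetic expression value used to standardize
    genetic_value_mean: float
    ref_genetic_values: list[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "SyntheticTruth":
        return cls(**json.loads(payload))


def _draw_allele_copies(rng: np.random.Generator, n: int, thresholds: np.ndarray,
                        ld_rho: float) -> np.ndarray:
    """One allele copy per (sample, SNP): AR(1) latent normal > threshold."""
    m = thresholds.size
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + innov[:, j - 1]
    return (z > thresholds).astype(float)


def _simulate_dosages(config: SimulationConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    mafs = config.true_mafs()
    thresholds = stats.norm.ppf(1.0 - mafs)
    a1 = _draw_allele_copies(rng, n, thresholds, config.ld_rho)
    a2 = _draw_allele_copies(rng, n, thresholds, config.ld_rho)
    return a1 + a2


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    pos = config.snp_positions()
    return pd.DataFrame({
        "id": [f"snp{i}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "maf": np.minimum(config.true_mafs(), 1 - config.true_mafs()),
    })


def probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    pos = config.probe_positions()
    return pd.DataFrame({
        "probe": [f"probe{i}" for i in range(config.n_probes)],
        "gene": [f"GENE{i}" for i in range(config.n_probes)],
        "chrom": config.chrom,
        "position": pos,
    })


def simulate_genotypes(config: SimulationConfig, n_samples: int | None = None,
                       stream: str = "ref_genotypes",
                       sample_prefix: str = "ref") -> GenotypeMatrix:
    """Draw a genotype matrix under the configured copula.

    Deterministic given ``config.seed`` and ``stream``; the true MAF vector is
    derived from the seed alone, so the reference panel and the GWAS cohort
    share allele frequencies and LD structure.
    """
    config.validate()
    n = config.n_ref_samples if n_samples is None else n_samples
    dosages = _simulate_dosages(config, n, config.rng(stream))
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=_variant_table(config),
                          dosages=dosages)


def simulate_covariates(config: SimulationConfig, samples: list[str],
                        stream: str = "ref_covariates") -> pd.DataFrame:
    rng = config.rng(stream)
    n = len(samples)
    return pd.DataFrame({
        "id": samples,
        "age": rng.normal(AGE_MEAN, AGE_SD, size=n),
        "sex": rng.binomial(1, P_MALE, size=n).astype(float),
    })


def genetic_values(dosages: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Per-sample genetic expression value of the causal probe."""
    return dosages @ config.effect_vector()


def simulate_expression(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                        config: SimulationConfig,
                        stream: str = "ref_expression"
                        ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Expression = cis genetic value + age/sex effects + Gaussian noise.

    Only the causal probe carries eQTL effects; all probes share the
    covariate effects and the noise SD. Returns the matrix and the vector of
    per-sample genetic values (the mediated component).
    """
    config.validate()
    if list(covariates["id"]) != list(genotypes.samples):
        raise AlignmentError("covariate sample ids do not match genotype samples")
    rng = config.rng(stream)
    n, p = genotypes.n_samples, config.n_probes
    g = genetic_values(genotypes.dosages, config)
    values = rng.normal(0.0, config.expr_noise_sd, size=(n, p))
    values += np.outer(covariates["age"].to_numpy(), np.full(p, config.age_effect))
    values += np.outer(covariates["sex"].to_numpy(), np.full(p, config.sex_effect))
    values[:, config.causal_probe_index] += g
    return (ExpressionMatrix(samples=list(genotypes.samples),
                             probes=probe_annotation(config), values=values), g)


def _standardization_constants(config: SimulationConfig,
                               n_calibration: int = 20_000) -> tuple[float, float]:
    """Mean/SD of the genetic value, from a dedicated seeded calibration draw."""
    beta = config.effect_vector()
    if not np.any(beta != 0):
        return 0.0, 0.0
    dos = _simulate_dosages(config, n_calibration, config.rng("calibration"))
    g = dos @ beta
    return float(g.mean()), float(g.std())


def simulate_case_control(config: SimulationConfig,
                          batch_size: int = 4096
                          ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Rejection-sample genotypes until case/control targets are met.

    P(case) = logistic(baseline_logit + disease_logit_per_expr_sd * G_std)
    where G_std is the genetic expression value standardized by calibration
    moments. Returns genotypes and a sample table (id, status, age, sex).
    """
    config.validate()
    beta = config.effect_vector()
    g_mean, g_sd = _standardization_constants(config)
    rng = config.rng("gwas_genotypes")
    status_rng = config.rng("gwas_status")
    want_cases, want_controls = config.n_gwas_cases, config.n_gwas_controls
    kept_dos: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_cases = n_controls = 0
    drawn = 0
    while n_cases < want_cases or n_controls < want_controls:
        if drawn >= _CASE_CONTROL_DRAW_CAP:
            raise SimulationError(
                f"case/control targets unattainable within {_CASE_CONTROL_DRAW_CAP} draws"
            )
        dos = _simulate_dosages(config, batch_size, rng)
        drawn += batch_size
        g = dos @ beta
        g_std = (g - g_mean) / g_sd if g_sd > 0 else np.zeros_like(g)
        logit = config.baseline_logit + config.disease_logit_per_expr_sd * g_std
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = status_rng.random(batch_size) < p_case
        take_case = np.flatnonzero(is_case)[: want_cases - n_cases]
        take_ctrl = np.flatnonzero(~is_case)[: want_controls - n_controls]
        keep = np.concatenate([take_case, take_ctrl])
        kept_dos.append(dos[keep])
        kept_status.append(is_case[keep])
        n_cases += take_case.size
        n_controls += take_ctrl.size
    dosages = np.vstack(kept_dos)
    status = np.concatenate(kept_status)
    samples = [f"gwas{i}" for i in range(dosages.shape[0])]
    covars = simulate_covariates(config, samples, stream="gwas_covariates")
    table = pd.DataFrame({
        "id": samples,
        "status": np.where(status, "case", "control"),
        "age": covars["age"].to_numpy(),
        "sex": covars["sex"].to_numpy(),
    })
    geno = GenotypeMatrix(samples=samples, variants=_variant_table(config),
                          dosages=dosages)
    return geno, table


def study_config(seed: int, heritability: float = 0.25,
                 mediation_logit: float = 0.4,
                 causal_snps: tuple[int, ...] | None = None,
                 n_gwas_cases: int = 1000, n_gwas_controls: int = 1000,
                 n_snps: int = 100, n_probes: int = 5) -> SimulationConfig:
    """Study-scale cohort configuration with a target cis heritability.

    One probe is mediated by ``len(causal_snps)`` equal-effect cis-SNPs whose
    shared effect size is solved (given the seed's true MAFs and unit noise)
    so the genetic fraction of expression variance equals ``heritability``;
    disease risk follows the mediation log-odds per genetic-expression SD.
    The causal SNPs sit far apart in the region, so their mutual LD under
    the AR(1) copula is negligible and the variance decomposition is
    additive.
    """
    if causal_snps is None:
        causal_snps = tuple(int(round(n_snps * f)) for f in (0.2, 0.5, 0.8))
    base = SimulationConfig(seed=seed, n_snps=n_snps, n_probes=n_probes,
                            n_gwas_cases=n_gwas_cases,
                            n_gwas_controls=n_gwas_controls)
    mafs = base.true_mafs()
    var_sum = float(sum(2.0 * mafs[i] * (1.0 - mafs[i]) for i in causal_snps))
    beta = np.sqrt(heritability / (1.0 - heritability) / var_sum)
    return SimulationConfig(
        seed=seed, n_snps=n_snps, n_probes=n_probes,
        n_gwas_cases=n_gwas_cases, n_gwas_controls=n_gwas_controls,
        causal_probe_index=n_probes // 2,
        eqtl_effects={i: float(beta) for i in causal_snps},
        expr_noise_sd=1.0,
        disease_logit_per_expr_sd=mediation_logit,
    )


@dataclass
class Cohort:
    """A complete simulated study: reference eQTL panel + case-control GWAS."""

    config: SimulationConfig
    ref_genotypes: GenotypeMatrix
    ref_covariates: pd.DataFrame
    ref_expression: ExpressionMatrix
    gwas_genotypes: GenotypeMatrix
    gwas_samples: pd.DataFrame
    truth: SyntheticTruth


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full two-cohort study design with recorded ground truth."""
    config.validate()
    ref_geno = simulate_genotypes(config)
    ref_cov = simulate_covariates(config, list(ref_geno.samples))
    ref_expr, g_ref = simulate_expression(ref_geno, ref_cov, config)
    gwas_geno, gwas_table = simulate_case_control(config)
    g_mean, g_sd = _standardization_constants(config)
    slope = (config.disease_logit_per_expr_sd / g_sd) if g_sd > 0 else 0.0
    truth = SyntheticTruth(
        true_maf=config.true_mafs().tolist(),
        eqtl_effects=config.effect_vector().tolist(),
        causal_probe_index=config.causal_probe_index,
        mediation_slope=slope,
        genetic_value_sd=g_sd,
        genetic_value_mean=g_mean,
        ref_genetic_values=g_ref.tolist(),
    )
    return Cohort(config=config, ref_genotypes=ref_geno, ref_covariates=ref_cov,
                  ref_expression=ref_expr, gwas_genotypes=gwas_geno,
                  gwas_samples=gwas_table, truth=truth)
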