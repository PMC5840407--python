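# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

The simulator produces the minimal data structure the discovery chain
assumes: a reference panel with genotypes, covariates and probe expression,
and a case-control cohort sharing the same allele frequencies and LD.

**Genotypes.** Each SNP's minor allele frequency is drawn uniformly from
`maf_range` (default 0.05–0.5, common variants as after a MAF ≥ 1% QC
screen). Each of the two allele copies is generated by thresholding a
latent AR(1) standard-normal process across SNPs at Φ⁻¹(1−MAF): marginally
every copy is Bernoulli(MAF) — hence Hardy-Weinberg genotype proportions —
while adjacent SNPs are correlated through the copula parameter `ld_rho`
(default 0.5; correlation decays as ρᵏ with distance in SNPs, a stationary
stand-in for haplotype-block LD). Dosage is the sum of the two copies.

**Expression.** One designated probe carries additive cis effects
(`expression = Σ βⱼ·dosageⱼ + β_age·age + β_sex·sex + N(0, σ²)`); all other
probes are covariates plus noise. Age ~ N(71.7, 8.3) years and
sex ~ Bernoulli(0.64 male) match the elderly, male-skewed surgical cohort
the package emulates. Noise SD defaults to 1, so effect sizes are in
expression SD units.

**Disease.** P(case) = logistic(α + γ·G_std), where G_std is the genetic
expression value standardized by moments from a dedicated 20,000-draw
calibration sample (deterministic given the seed). Cases and controls are
rejection-sampled to the target counts (cap 10⁷ draws), mirroring a
fixed-n case-control design. The baseline logit defaults to −2 (≈12%
population risk), so the case-control sample is risk-enriched as a real
case-control study is.

**Study-scale configuration.** `study_config(seed)` realizes the design
the recovery benchmarks use: 233 reference samples, 1000/1000
cases/controls, 100 SNPs 5 kb apart, 5 probes, and one mediating probe
whose cis heritability is set to 0.25 by solving the shared effect of three
well-separated causal SNPs against the seed's realized MAFs
(β²·Σ2pⱼ(1−pⱼ) = h²/(1−h²) with unit noise). Three causal SNPs rather than
one keep the MR instrument at ≥ 3 SNPs so the Egger regression is always
defined; their spacing makes their mutual LD negligible, so the variance
decomposition is additive. Mediation strength is log-OR 0.4 per
genetic-expression SD.

**What the simulator does not emulate** (and what passing tests therefore
do not show): population structure and admixture, imputation uncertainty,
haplotype-block LD with recombination hotspots, X-chromosome dosage,
multi-allelic sites, array normalization artifacts, hidden expression
factors beyond age/sex, and sample overlap between the panel and the GWAS.

Every stage draws from `default_rng([seed, stream_offset])` with fixed
per-stage offsets, so a single integer seed reproduces a cohort
bit-identically.

## GWAS

Association is additive logistic regression of case status on dosage with
covariates, by maximum likelihood (Newton); per-variant missing dosages are
dropped pairwise. Non-converged, separated or zero-variance fits are
returned flagged with missing statistics rather than silently dropped.
λ_GC is the median of the p-values' implied 1-df χ² statistics over the
null median 0.45494.

QC order is fixed and reported: variant call rate → MAF → HWE →
differential missingness (→ optional imputation r²), then sample filters,
so removal counts partition the removed set and are auditable. HWE is
computed in all samples combined (a conservative default; computing it in
controls only is a one-line change on the call side) on rounded hard
calls, using an exact test when MAF < 5% or an expected cell is below 5
and the χ² test otherwise. Relatedness uses an IBS-based score normalized
by its HWE expectation ((obs−exp)/(1−exp)); duplicates score 1 and
first-degree relatives fall around 0.4–0.6, so the first-degree proxy
cutoff is 0.4, removing the lower-call-rate member of each flagged pair.
Sex-mismatch and ancestry-outlier exclusions are accepted as precomputed
lists since they reference external panels.

## cis-eQTL

Expression is residualized per probe on age and sex with a Huber
M-estimator (robust to the heavy-tailed arrays this emulates); residuals
beyond 3 SD of the per-probe median are masked and dropped pairwise from
all downstream fits (per-probe SD is the only scale-consistent reading of
the rule). The eQTL model itself is plain OLS on dosage — robustness lives
in the adjustment step only. The cis window is 1 Mb either side of the
probe's single annotated coordinate. Variance explained is the squared
dosage-expression Pearson correlation, identical to t²/(t²+df) for simple
OLS (asserted to 1e-8 in tests). p-values are floored at 1e-300 for
serialization. Independent signals are obtained greedily: take the most
significant SNP, drop everything with genotype r² ≥ 0.8 against any
selected SNP, repeat; ties break by |t| then position. Both the
pair-level significant count and the post-pruning independent count are
reported, since "independent eQTLs" is ambiguous between them.

## TWAS

Weights are learned on standardized dosages within 500 kb of the probe.
`top1` is the best marginal SNP with its OLS coefficient; lasso and
elastic net (mixing 0.5, a conventional default) choose their penalty by
internal cross-validation inside each training fold, so the recorded
per-model R² is a genuine out-of-fold prediction R²; the best model is
refitted on the full panel. Probes whose best CV R² ≤ 0 carry no
predictive signal and are excluded from the scan (and from the
significance denominator), with the exclusion reported.

The association statistic is z_TWAS = wᵀz / √(wᵀRw), the defining
combination of expression weights with GWAS z-scores under an LD
reference. R is shrunk as 0.9·R + 0.1·I before the quadratic form to guard
against rank deficiency; the factor is configurable and the shrinkage is
mild enough that null z_TWAS passes a standard-normal KS check in the
calibration tests. Transcriptome-wide significance is p < 1e-4, taken as
given rather than derived from the number of probes.

## Colocalization

Per-SNP evidence is the Wald approximate Bayes factor with prior effect
SD 0.2 for case-control (log-odds) effects and 0.15 for quantitative
traits; hypothesis sums are accumulated with log-sum-exp and normalized
with priors p1 = p2 = 1e-4, p12 = 1e-5 (the published defaults of this
framework; all config-exposed). Hypothesis 1 is the eQTL-only hypothesis,
2 the GWAS-only one. The model assumes at most one causal variant per
trait per region; with several shared causal variants PP4 remains high in
practice because the diagonal (shared) terms carry a 1000-fold prior
advantage over the cross terms, but the posterior is then a summary, not a
faithful generative fit. SNPs are matched by id with an optional
ref/alt consistency check that sign-flips swapped alleles.

## Mendelian randomization

Candidates are cis SNPs within 200 kb of the gene anchor at marginal eQTL
p < 0.05; bidirectional stepwise selection starts from the full candidate
model and moves by AIC = n·log(RSS/n) + 2k until no single add/drop
improves it. The marginal eQTL effects (not the joint-model coefficients)
are the exposure effects downstream, so each SNP contributes one (x, y)
point. Both effect sets are scaled by √(2·MAF·(1−MAF)), putting effects on
a per-SD-of-genotype scale; the scaling cancels in the slope when effects
are exactly proportional, so the Wald slope stays interpretable as disease
log-odds per expression unit.

The Wald slope is through-origin OLS (the standard Wald/IVW contract); the
free-intercept variant is exactly the Egger regression and is implemented
separately, with inverse-variance weights and alleles oriented so exposure
effects are nonnegative (required for the intercept to be interpretable).
Inference is a parametric bootstrap: each draw resamples every SNP's
exposure and outcome effects independently from Normal(estimate, SE),
rescales, and recomputes the slope; p = 2·min(frac ≤ 0, frac ≥ 0) floored
at 2/n_sims, CI from the 2.5/97.5 percentiles. Draws are independent
across SNPs and traits — no LD or sample-overlap correlation — which is a
documented simplification. The default 100,000 draws make the p-value
floor 2e-5.

**Known limitation — Egger under winner's curse.** Because the instrument
is screened (p < 0.05) and stepwise-selected on the same reference panel
that supplies the exposure effects, SNPs with no real expression effect
enter the instrument with selection-inflated exposure estimates and null
disease effects. The Egger intercept test correctly reads this as
directional pleiotropy, so under the package's study-scale conditions the
intercept test rejects in a substantial fraction of replicates even though
disease risk is generated purely through expression. The evaluation module
therefore reports the Egger clean rate twice: for the procedurally
selected instrument and for the oracle instrument (the true causal SNPs),
where the test is calibrated. At the real study's eQTL strength (a single
SNP explaining a quarter of expression variance in an LD-saturated locus)
selection effects are far smaller; at the simulated effect sizes they are
not negligible, and users should read a significant Egger intercept after
in-sample selection with this failure mode in mind.

The nearby-gene pleiotropy scan regresses each neighbor probe's adjusted
expression on each instrument SNP, flagging p < 0.05/(n_snps·n_genes)
(Bonferroni over the full table); the per-SNP-only denominator 0.05/n_snps
is available by flag.

## Risk metrics

PAR% uses the control-group risk-allele frequency by default; an external
reference frequency must be passed explicitly because the two conventions
give different values. Meta-analysis is inverse-variance fixed-effect on
the log-odds scale (the scale on which the IVW formula's additivity
assumption holds). Severity associations are OLS per measure with optional
extra covariates (e.g. age, sex, DuBois BSA for aortic-root models);
stratified association reuses the GWAS logistic model per stratum and
reports whether the 95% CIs overlap.

## Evaluation design and problem sizes

`twasmr.evaluation` fixes the benchmark designs: the recovery study runs
20 seeds of the study-scale cohort end to end with 10,000 bootstrap draws
per MR; null calibration uses a 5,000-SNP no-effect cohort for λ and
GWAS/eQTL uniformity, 200 independent single-probe null regions for TWAS
uniformity (only probes passing the heritability pre-filter by chance
contribute, which preserves conditional uniformity because the filter only
sees the reference panel), and 400 zero-slope replicates at 2,000 draws
for the bootstrap type-I error. These sizes keep the full evaluation at a
few minutes on one CPU while leaving the binomial/KS checks adequately
powered; λ's sampling SD at 5,000 SNPs is ≈ 0.03, so its [0.95, 1.05]
acceptance band is inherently a ~1.5σ check.

Seeds for replicate studies are derived from one base seed via
`SeedSequence`, and every stochastic routine takes an explicit seed, so
all reported numbers are bit-reproducible.
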