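"""Shared in-memory containers for the genotype / expression / phenotype pipeline.

Genotypes travel as additive alternate-allele dosages in [0, 2] (imputed data
convention); hard calls are recovered by rounding where a filter needs genotype
counts. Expression is a dense samples x probes matrix with a one-coordinate
genomic anchor per probe, which is what cis-window logic keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    samples : list of sample ids (length n).
    variants : DataFrame with columns id, chrom, pos (1-based), ref, alt and
        optionally maf, call_rate, imputation_r2.
    dosages : (n_samples, n_variants) float array in [0, 2]; np.nan = missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def hard_calls(self) -> np.ndarray:
        """Rounded genotype calls in {0,1,2} (nan preserved)."""
        return np.round(self.dosages)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant from observed dosages."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        variant_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in s],
            variants=self.variants.iloc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(s, v)],
        )


@dataclass
class ExpressionMatrix:
    """Samples x probes expression with probe genomic annotation.

    probes : DataFrame with columns probe, gene, chrom, position (1-based).
    values : (n_samples, n_probes) float array.
    """

    samples: list[str]
    probes: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.probes)):
            raise ValueError("expression shape inconsistent with samples/probes")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass
class AdjustedExpression:
    """Residual expression after robust age/sex adjustment, with outlier mask.

    residuals : samples x probes; mask True where the entry is usable
    (non-outlier). Downstream fits must drop masked-out entries pairwise.
    """

    samples: list[str]
    probes: pd.DataFrame
    residuals: np.ndarray
    mask: np.ndarray
    covariates_used: list[str] = field(default_factory=lambda: ["age", "sex"])

    def masked_values(self) -> np.ndarray:
        out = self.residuals.copy()
        out[~self.mask] = np.nan
        return out
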