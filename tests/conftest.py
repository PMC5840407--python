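import numpy as np
import pandas as pd
import pytest

from twasmr import SimulationConfig, simulate_cohort
from twasmr.datatypes import GenotypeMatrix


def make_genotypes(dosages: np.ndarray, chrom: str = "1",
                   start: int = 1000, spacing: int = 1000) -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with synthetic metadata."""
    n, m = dosages.shape
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": start + spacing * np.arange(m),
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          variants=variants, dosages=dosages.astype(float))


@pytest.fixture(scope="session")
def small_cohort():
    """A small mediated-effect cohort shared by read-only tests."""
    cfg = SimulationConfig(n_ref_samples=200, n_gwas_cases=300,
                           n_gwas_controls=300, n_snps=40, n_probes=3,
                           causal_probe_index=1, eqtl_effects={10: 0.8},
                           disease_logit_per_expr_sd=0.5, seed=11)
    return simulate_cohort(cfg)
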