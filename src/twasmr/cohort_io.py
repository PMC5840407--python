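"""On-disk cohort exchange formats.

Genotypes are written as VCFv4.2 with FORMAT fields GT (hard call, dosage
rounded) and DS (dosage, 3 decimals); expression as a probes x samples TSV
with the probe id in the first column; probe annotation and sample tables as
plain TSV. All positions are 1-based. Reading VCF goes through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import ExpressionMatrix, GenotypeMatrix
from .simulate import Cohort

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
    ]
    chroms = pd.unique(genotypes.variants["chrom"])
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(genotypes.samples)
    lines.append("\t".join(header))
    dos = genotypes.dosages
    for j, var in genotypes.variants.iterrows():
        fields = [str(var["chrom"]), str(int(var["pos"])), str(var["id"]),
                  str(var["ref"]), str(var["alt"]), ".", "PASS", ".", "GT:DS"]
        col = dos[:, j]
        for d in col:
            if np.isnan(d):
                fields.append("./.:.")
            else:
                fields.append(f"{_GT_CODES[int(round(d))]}:{d:.3f}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for v in vcf:
        ids.append(v.ID)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
        ds = v.format("DS")
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
            row[row < 0] = np.nan  # cyvcf2 encodes missing floats as negative sentinel
        else:
            # fall back to hard calls
            gt = np.asarray(v.gt_types, dtype=float)
            gt[gt == 2] = np.nan  # UNKNOWN
            gt[gt == 3] = 2.0  # HOM_ALT
            row = gt
        rows.append(row)
    vcf.close()
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "ref": refs, "alt": alts})
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(expr.values.T, index=expr.probes["probe"],
                      columns=expr.samples)
    df.index.name = "probe"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_expression(path: str | Path, probes: pd.DataFrame) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    probes = probes.set_index("probe").loc[df.index].reset_index()
    return ExpressionMatrix(samples=list(df.columns), probes=probes,
                            values=df.to_numpy().T)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Emit VCFs, expression matrix, probe annotation and sample tables.

    Returns the path of every file written; read_cohort round-trips dosages
    to VCF precision (3 decimals) and everything else exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    paths = {
        "ref_vcf": write_vcf(cohort.ref_genotypes, directory / "reference.vcf"),
        "gwas_vcf": write_vcf(cohort.gwas_genotypes, directory / "gwas.vcf"),
        "expression": write_expression(cohort.ref_expression,
                                       directory / "expression.tsv"),
        "probes": directory / "probes.tsv",
        "ref_samples": directory / "reference_samples.tsv",
        "gwas_samples": directory / "gwas_samples.tsv",
        "truth": directory / "truth.json",
    }
    cohort.ref_expression.probes.to_csv(paths["probes"], sep="\t", index=False)
    cohort.ref_covariates.to_csv(paths["ref_samples"], sep="\t", index=False)
    cohort.gwas_samples.to_csv(paths["gwas_samples"], sep="\t", index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return paths


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
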