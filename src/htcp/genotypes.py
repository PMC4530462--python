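"""Genotype dosage container and VCF/TSV IO.

Dosages are per-sample counts of the declared risk allele in [0, 2]:
integers for hard calls, fractional expected dosages for imputed
genotypes.  VCF input uses the per-sample ``DS`` FORMAT field when
present, otherwise converts ``GT`` hard calls to risk-allele counts
(strand-literal allele matching only).  The TSV layout is a plain matrix
(rows = samples, columns = SNP ids) with a sidecar file declaring each
SNP's risk allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeDosageMatrix", "read_vcf_dosages", "read_tsv_dosages",
           "write_tsv_dosages"]


@dataclass
class GenotypeDosageMatrix:
    """Samples x SNPs risk-allele dosages; NaN marks missing calls."""

    dosages: pd.DataFrame            # index = sample ids, columns = snp ids
    risk_allele: dict[str, str]      # snp id -> risk allele label

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] or be missing")
        missing = set(self.dosages.columns) - set(self.risk_allele)
        if missing:
            raise ValueError(f"risk allele undeclared for SNPs: {sorted(missing)}")
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def hard_call(self, snp_id: str) -> bool:
        """True if every non-missing dosage at the SNP is an integer 0/1/2."""
        v = self.dosages[snp_id].dropna().to_numpy(dtype=float)
        return bool(np.all(np.isin(v, (0.0, 1.0, 2.0))))

    def merge(self, other: "GenotypeDosageMatrix") -> "GenotypeDosageMatrix":
        """Stack two matrices with disjoint samples; SNPs are unioned.

        A SNP present in only one source keeps missing dosages for the
        other source's samples.
        """
        overlap = set(self.sample_ids) & set(other.sample_ids)
        if overlap:
            raise ValueError(f"overlapping sample ids: {sorted(overlap)[:5]}")
        for snp in set(self.snp_ids) & set(other.snp_ids):
            if self.risk_allele[snp] != other.risk_allele[snp]:
                raise ValueError(f"risk-allele mismatch at {snp}")
        merged = pd.concat([self.dosages, other.dosages], axis=0)
        return GenotypeDosageMatrix(merged, {**self.risk_allele,
                                             **other.risk_allele})


def read_vcf_dosages(path: str | Path,
                     risk_allele: Mapping[str, str]) -> GenotypeDosageMatrix:
    """Read risk-allele dosages from a VCF (DS field, else GT hard calls)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    alleles: dict[str, str] = {}
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        if snp not in risk_allele:
            continue
        risk = risk_allele[snp].upper()
        site_alleles = [var.REF.upper()] + [a.upper() for a in var.ALT]
        if risk not in site_alleles:
            raise ValueError(
                f"declared risk allele {risk} absent at {snp} "
                f"(alleles {site_alleles})")
        try:
            ds_raw = var.format("DS")
        except KeyError:
            ds_raw = None
        if ds_raw is not None:
            ds = np.asarray(ds_raw, dtype=float).reshape(-1)
            # DS counts ALT alleles; flip if the risk allele is REF
            dos = ds if risk != site_alleles[0] else 2.0 - ds
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            risk_idx = site_alleles.index(risk)
            dos = np.where((gt < 0).any(axis=1), np.nan,
                           (gt == risk_idx).sum(axis=1).astype(float))
        cols[snp] = dos
        alleles[snp] = risk
    df = pd.DataFrame(cols, index=samples, dtype=float)
    return GenotypeDosageMatrix(df, alleles)


def read_tsv_dosages(matrix_path: str | Path,
                     risk_allele_path: str | Path) -> GenotypeDosageMatrix:
    """TSV matrix with sample-id index column + 2-column risk-allele sidecar."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    side = pd.read_csv(risk_allele_path, sep="\t", dtype=str)
    if not {"snp_id", "risk_allele"} <= set(side.columns):
        raise ValueError("risk-allele sidecar needs snp_id and risk_allele columns")
    alleles = dict(zip(side.snp_id, side.risk_allele))
    return GenotypeDosageMatrix(df.astype(float), alleles)


def write_tsv_dosages(matrix: GenotypeDosageMatrix, matrix_path: str | Path,
                      risk_allele_path: str | Path) -> None:
    matrix.dosages.to_csv(matrix_path, sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"snp_id": list(matrix.risk_allele),
         "risk_allele": [matrix.risk_allele[s] for s in matrix.risk_allele]}
    ).to_csv(risk_allele_path, sep="\t", index=False)
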