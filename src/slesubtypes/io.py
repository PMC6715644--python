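"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CriteriaMatrix, GenotypeMatrix

__all__ = [
    "read_criteria",
    "read_beta",
    "read_dosages",
    "read_vcf",
    "read_covariates",
    "read_gmt",
    "read_state_bed",
]


def read_criteria(path) -> CriteriaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CriteriaMatrix(df.astype(int))


def read_beta(beta_path, manifest_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col="cpg_id")
    manifest = pd.read_csv(manifest_path, sep="\t", index_col="cpg_id")
    if "pos_1based" in manifest.columns:
        manifest = manifest.rename(columns={"pos_1based": "pos"})
    manifest["chrom"] = manifest["chrom"].astype(str)
    return BetaMatrix(values, manifest)


def read_dosages(dosage_path, positions: pd.DataFrame) -> GenotypeMatrix:
    values = pd.read_csv(dosage_path, sep="\t", index_col="snp_id")
    return GenotypeMatrix(values, positions)


def read_vcf(path) -> GenotypeMatrix:
    """Parse GT fields of a VCF into additive ALT-allele dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        dose = np.array(
            [np.nan if g is None else g for g in _dosage_from_gt(var)], dtype=float
        )
        rows.append(dose)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    pos = pd.DataFrame(meta).set_index("snp_id")
    values = pd.DataFrame(rows, index=pos.index, columns=samples)
    return GenotypeMatrix(values, pos)


def _dosage_from_gt(variant):
    for gt in variant.genotypes:  # [allele1, allele2, phased]
        alleles = gt[:-1]
        if any(a < 0 for a in alleles):
            yield None
        else:
            yield float(sum(1 for a in alleles if a > 0))


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_state_bed(path) -> pd.DataFrame:
    """BED4+ chromatin-state segmentation (0-based half-open intervals)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
    )
    bed["chrom"] = bed["chrom"].astype(str)
    return bed
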