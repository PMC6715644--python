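"""Core in-memory containers shared by every stage of the pipeline.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that each stage can enforce sample alignment once, up front, instead of
inside every statistical routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CriteriaMatrix",
    "BetaMatrix",
    "GenotypeMatrix",
    "ClusterAssignment",
    "CovariateTable",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Raised when two containers do not share the same sample set/order."""


def check_aligned(*sample_id_lists) -> None:
    """Assert every argument carries the same ordered sample identifiers."""
    ref = list(sample_id_lists[0])
    for other in sample_id_lists[1:]:
        if list(other) != ref:
            raise AlignmentError(
                "sample identifiers are not aligned across containers; "
                "reindex all matrices to a common sample order first"
            )


@dataclass
class CriteriaMatrix:
    """Samples x binary clinical criteria (ACR criteria and sub-criteria)."""

    values: pd.DataFrame  # samples x criteria, entries in {0, 1}

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, [0, 1]).all():
            raise ValueError("criteria matrix must contain only 0/1 entries")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def criterion_names(self) -> list:
        return list(self.values.columns)

    def zero_variance_criteria(self) -> list:
        nun = self.values.nunique()
        return list(nun.index[nun <= 1])


@dataclass
class BetaMatrix:
    """CpGs x samples methylation beta values in [0, 1] plus a manifest.

    The manifest maps each CpG to (chrom, pos [1-based], gene, region); the
    region vocabulary follows the Illumina annotation (TSS200, TSS1500,
    5UTR, Body, 3UTR).
    """

    values: pd.DataFrame  # CpGs x samples
    manifest: pd.DataFrame  # index cpg_id; columns chrom, pos, gene, region

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.values.index.difference(self.manifest.index)
        if len(missing):
            raise ValueError(
                f"manifest does not cover {len(missing)} CpGs "
                f"(e.g. {list(missing[:3])})"
            )

    @property
    def cpg_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def subset(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(cpg_ids)], self.manifest)

    def m_values(self, eps: float = 1e-3) -> pd.DataFrame:
        """logit2 transform with boundary clipping (M-value scale)."""
        b = self.values.clip(eps, 1 - eps)
        return np.log2(b / (1 - b))


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive minor-allele dosages in {0,1,2} (NaN = missing)."""

    values: pd.DataFrame  # SNPs x samples
    positions: pd.DataFrame  # index snp_id; columns chrom, pos, ref, alt

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, [0.0, 1.0, 2.0])
        if arr.size and not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        missing = self.values.index.difference(self.positions.index)
        if len(missing):
            raise ValueError(f"positions missing for {len(missing)} SNPs")

    @property
    def snp_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP, ignoring missing calls."""
        p = self.values.mean(axis=1, skipna=True) / 2.0
        return np.minimum(p, 1 - p)

    def call_rate(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    def subset(self, snp_ids) -> "GenotypeMatrix":
        keep = list(snp_ids)
        return GenotypeMatrix(self.values.loc[keep], self.positions.loc[keep])


@dataclass
class ClusterAssignment:
    """Per-sample subtype label, ordered by severity (M < S1 < ... )."""

    labels: pd.Series  # index sample_id, values e.g. "M", "S1", "S2"
    centroids: np.ndarray | None = None  # k x dim, in clustering space
    severity_order: list = field(default_factory=list)  # least -> most severe

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every sample must carry a cluster label")
        if not self.severity_order:
            self.severity_order = sorted(self.labels.unique())

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    @property
    def k(self) -> int:
        return self.labels.nunique()

    def ordinal(self) -> pd.Series:
        """Severity-ordered integer codes (M=0, S1=1, S2=2, ...)."""
        rank = {lab: i for i, lab in enumerate(self.severity_order)}
        return self.labels.map(rank).astype(int)

    def proportions(self) -> pd.Series:
        return self.labels.value_counts(normalize=True).reindex(self.severity_order)


@dataclass
class CovariateTable:
    """Samples x modelling covariates with stable column names.

    Conventional columns: sex, age, smoke, alcohol, medpc1-3, ancpc1-3,
    cellc1-k, plus an 'ethnicity' categorical column kept out of numeric
    design matrices unless requested.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        num = self.values.select_dtypes(include=[np.number])
        if num.isna().any().any():
            bad = list(num.columns[num.isna().any()])
            raise ValueError(f"missing values in modelling columns: {bad}")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    def design(self, drop: tuple = ("ethnicity",)) -> pd.DataFrame:
        """Numeric design block (no intercept); categorical columns dropped."""
        keep = [c for c in self.values.columns if c not in drop]
        block = self.values[keep].select_dtypes(include=[np.number])
        return block.astype(float)
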