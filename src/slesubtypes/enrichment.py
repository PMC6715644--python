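"""Enrichment analyses of the cluster-associated CpG signature.

Three flavours: upper-tail hypergeometric gene-set enrichment, Fisher-exact
chromatin-state enrichment against a tiling 15-state segmentation per cell
type, and a permutation test for enrichment of ethnicity-associated CpGs
within the cluster signature after adjusting for genetic ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, CovariateTable, check_aligned
from .linalg import add_intercept, bh_adjust, nested_f_test
from .methylation import _norm_chrom, drop_collinear

log = logging.getLogger(__name__)

__all__ = [
    "hypergeom_enrichment",
    "assign_chromatin_states",
    "chromatin_enrichment",
    "ethnicity_permutation_enrichment",
    "EnrichmentPermResult",
]


@dataclass
class EnrichmentPermResult:
    """Permutation enrichment of ethnicity-associated CpGs among cluster CpGs."""

    n_cluster: int
    n_race_observed: int
    null_counts: np.ndarray
    enrichment_statistic: float
    p_perm: float
    n_perm: int
    seed: int
    null_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_mean = float(np.mean(self.null_counts)) if len(self.null_counts) else float("nan")


def hypergeom_enrichment(hit_genes, gene_set, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric p of the observed-or-larger overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes) & universe
    gset = set(gene_set) & universe
    overlap = len(hits & gset)
    N, K, n = len(universe), len(gset), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return overlap, p


def assign_chromatin_states(
    manifest: pd.DataFrame, state_bed: pd.DataFrame
) -> pd.Series:
    """State label for each CpG from a tiling BED segmentation.

    BED intervals are 0-based half-open; manifest positions are 1-based.
    CpGs falling outside every interval are returned as NaN (unassigned).
    """
    out = pd.Series(index=manifest.index, dtype=object)
    bed = state_bed.copy()
    bed["chrom"] = bed["chrom"].map(_norm_chrom)
    for chrom, cpgs in manifest.groupby(manifest["chrom"].map(_norm_chrom)):
        ivals = bed[bed["chrom"] == chrom].sort_values("start")
        if ivals.empty:
            continue
        starts = ivals["start"].to_numpy()
        ends = ivals["end"].to_numpy()
        names = ivals["state"].to_numpy()
        pos0 = cpgs["pos"].to_numpy() - 1  # 1-based -> 0-based
        ix = np.searchsorted(starts, pos0, side="right") - 1
        ok = (ix >= 0) & (pos0 < ends[np.clip(ix, 0, len(ends) - 1)])
        vals = np.where(ok, names[np.clip(ix, 0, len(names) - 1)], None)
        out.loc[cpgs.index] = vals
    return out


def chromatin_enrichment(
    hit_cpgs,
    universe_cpgs,
    manifest: pd.DataFrame,
    state_beds: dict,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-state, per-cell-type Fisher exact enrichment of hit CpGs.

    For each state the 2x2 table crosses hit/non-hit universe CpGs with
    in-state/out-of-state; two-sided Fisher exact p and odds ratio per
    state, BH across all states x cell types.  Unassigned CpGs are excluded
    and logged.
    """
    hit_cpgs = set(hit_cpgs)
    universe = list(universe_cpgs)
    rows = []
    for cell_type, bed in state_beds.items():
        states = assign_chromatin_states(manifest.loc[universe], bed)
        unassigned = states.isna()
        if unassigned.any():
            log.warning(
                "chromatin_enrichment[%s]: %d CpGs outside all intervals excluded",
                cell_type,
                int(unassigned.sum()),
            )
        states = states.dropna()
        is_hit = states.index.isin(hit_cpgs)
        for state in sorted(states.unique()):
            in_state = (states == state).to_numpy()
            a = int((is_hit & in_state).sum())
            b = int((is_hit & ~in_state).sum())
            c = int((~is_hit & in_state).sum())
            d = int((~is_hit & ~in_state).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            # Haldane-corrected OR when the sample OR is degenerate
            if not np.isfinite(odds) or odds == 0:
                odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            rows.append(
                {
                    "cell_type": cell_type,
                    "state": state,
                    "n_hit_in_state": a,
                    "odds_ratio": float(odds),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["odds_ratio"] < 1, "depleted", "enriched")
    out["significant"] = out["q"] < fdr_threshold
    return out


def _ethnicity_f_pvals(
    Y: np.ndarray, eth_codes: np.ndarray, n_levels: int, X_base: np.ndarray
) -> np.ndarray:
    """Joint partial-F p-value of the ethnicity factor for each CpG column."""
    dummies = np.eye(n_levels)[eth_codes][:, 1:]  # drop reference level
    X_full = np.column_stack([X_base, dummies])
    _, p, _, _, _ = nested_f_test(Y, X_full, X_base)
    return p


def ethnicity_permutation_enrichment(
    beta: BetaMatrix,
    ethnicity: pd.Series,
    covariates: CovariateTable | None,
    cluster_cpgs,
    n_perm: int = 1000,
    alpha: float = 0.05,
    use_fdr: bool = False,
    seed: int = 0,
) -> EnrichmentPermResult:
    """Permutation enrichment of ethnicity-associated CpGs in the signature.

    The observed count N_race is the number of cluster-associated CpGs whose
    covariate-adjusted linear model shows a significant joint ethnicity
    effect (raw p < alpha, or BH FDR < alpha when ``use_fdr``).  Null counts
    repeat the computation under random permutations of the ethnicity
    labels; p_perm uses the add-one estimator and the enrichment statistic
    is the observed proportion relative to the null mean.
    """
    cluster_cpgs = list(cluster_cpgs)
    if not cluster_cpgs:
        raise ValueError("cluster_cpgs must be non-empty")
    levels = pd.unique(ethnicity.dropna())
    if len(levels) < 2:
        raise ValueError("ethnicity must have at least 2 levels")
    sub = beta.subset(cluster_cpgs)
    check_aligned(sub.sample_ids, list(ethnicity.index))
    Y = sub.values.to_numpy().T  # n x m
    n = Y.shape[0]
    codes = pd.Categorical(ethnicity, categories=levels).codes.astype(int)
    X_base = (
        add_intercept(drop_collinear(covariates.design()).to_numpy(), n)
        if covariates is not None
        else add_intercept(None, n)
    )

    def count_assoc(c):
        p = _ethnicity_f_pvals(Y, c, len(levels), X_base)
        stat = bh_adjust(p) if use_fdr else p
        return int(np.sum(stat < alpha))

    observed = count_assoc(codes)
    rng = np.random.default_rng(seed)
    null_counts = np.array(
        [count_assoc(rng.permutation(codes)) for _ in range(n_perm)]
    )
    p_perm = float((1 + np.sum(null_counts >= observed)) / (n_perm + 1))
    null_mean = float(null_counts.mean())
    n_cluster = len(cluster_cpgs)
    stat = (
        (observed / n_cluster) / (null_mean / n_cluster) if null_mean > 0 else np.inf
    )
    return EnrichmentPermResult(
        n_cluster=n_cluster,
        n_race_observed=observed,
        null_counts=null_counts,
        enrichment_statistic=float(stat),
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )
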