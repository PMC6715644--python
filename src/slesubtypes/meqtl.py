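"""Genotype QC and cis-meQTL scanning.

SNP quality control (call rate, MAF, Hardy-Weinberg exact test) is applied
in a fixed order, SNPs are LD-pruned (windowed greedy, r^2 threshold), CpGs
are paired with every retained SNP within the cis window (< 1 Mb, strict),
and each pair is fitted with an additive-dosage covariate-adjusted linear
model; BH FDR runs across all tested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, CovariateTable, GenotypeMatrix, check_aligned
from .linalg import add_intercept, bh_adjust, residualize
from .methylation import _norm_chrom, drop_collinear

log = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_test",
    "genotype_qc",
    "ld_prune",
    "map_cis_pairs",
    "fit_meqtl",
    "distance_decay",
    "QCReport",
]

CIS_WINDOW_BP = 1_000_000


@dataclass
class QCReport:
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_kept: int


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style).

    The p-value sums the conditional probabilities (given the allele counts)
    of every heterozygote count no more probable than the observed one.
    Heterozygote counts share the parity of the minor-allele count.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_homref, n_homalt) + n_het
    # possible het counts share parity with the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    if hets.size == 1:
        return 1.0
    from scipy.special import gammaln

    def logfac(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        logfac(n)
        - logfac(rare_hom)
        - logfac(hets)
        - logfac(common_hom)
        + hets * np.log(2.0)
        + logfac(n_rare)
        + logfac(2 * n - n_rare)
        - logfac(2 * n)
    )
    probs = np.exp(logp - logp.max())
    probs = probs / probs.sum()
    observed = probs[hets == n_het][0]
    return float(np.minimum(probs[probs <= observed * (1 + 1e-12)].sum(), 1.0))


def genotype_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters in order call-rate -> MAF -> HWE.

    MAF strictly greater than ``maf_min`` is retained (a SNP at exactly 5%
    is removed); SNPs missing in more than 1 - call_rate_min of samples or
    deviating from Hardy-Weinberg equilibrium at ``hwe_alpha`` are removed.
    """
    G = genotypes.values
    keep = G.index[genotypes.call_rate() >= call_rate_min]
    n_call = len(G.index) - len(keep)
    maf = genotypes.maf().loc[keep]
    keep2 = keep[(maf > maf_min).to_numpy()]
    n_maf = len(keep) - len(keep2)
    hwe_drop = []
    for snp in keep2:
        row = G.loc[snp].dropna().to_numpy()
        counts = [(row == g).sum() for g in (0, 1, 2)]
        if hwe_exact_test(*counts) < hwe_alpha:
            hwe_drop.append(snp)
    keep3 = keep2.difference(pd.Index(hwe_drop), sort=False)
    report = QCReport(
        removed_call_rate=n_call,
        removed_maf=n_maf,
        removed_hwe=len(hwe_drop),
        n_kept=len(keep3),
    )
    log.info("genotype_qc: %s", report)
    if len(keep3) == 0:
        raise ValueError("genotype QC removed all SNPs")
    return genotypes.subset(keep3), report


def _dosage_r2(A: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation, mean-imputed missing."""
    A = A.astype(float)
    mean = np.nanmean(A, axis=1)
    inds = np.where(np.isnan(A))
    A[inds] = np.take(mean, inds[0])
    A = A - A.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(A, axis=1)
    norms[norms == 0] = 1.0
    C = (A @ A.T) / np.outer(norms, norms)
    return C**2


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.8,
    window: int = 50,
    step: int = 5,
) -> list:
    """Windowed greedy LD pruning so no retained pair has r^2 > r2_max.

    SNPs must be position-sorted within chromosome; within each sliding
    window the earlier-position SNP of a correlated pair is kept.
    """
    pos = genotypes.positions
    kept: list = []
    for chrom, grp in pos.groupby(pos["chrom"].map(_norm_chrom), sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")
        ids = list(grp.index)
        alive = {s: True for s in ids}
        G = genotypes.values.loc[ids].to_numpy()
        start = 0
        while start < len(ids):
            idx = [i for i in range(start, min(start + window, len(ids))) if alive[ids[i]]]
            if len(idx) > 1:
                r2 = _dosage_r2(G[idx])
                for a in range(len(idx)):
                    if not alive[ids[idx[a]]]:
                        continue
                    for b in range(a + 1, len(idx)):
                        if alive[ids[idx[b]]] and r2[a, b] > r2_max:
                            alive[ids[idx[b]]] = False  # later position removed
            if start + window >= len(ids):
                break
            start += step
        kept.extend([s for s in ids if alive[s]])
    return kept


def map_cis_pairs(
    snp_positions: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Exhaustive same-chromosome pairs with |snp_pos - cpg_pos| < window_bp.

    Chromosome names are normalized ('chr1' == '1'); positions are 1-based.
    The window is strict: a pair at exactly ``window_bp`` is excluded.
    """
    snp = snp_positions.copy()
    snp["chrom"] = snp["chrom"].map(_norm_chrom)
    cpg = cpg_positions.copy()
    cpg["chrom"] = cpg["chrom"].map(_norm_chrom)
    rows = []
    for chrom, snp_grp in snp.groupby("chrom", sort=False):
        cpg_grp = cpg[cpg["chrom"] == chrom]
        if cpg_grp.empty:
            continue
        spos = snp_grp["pos"].to_numpy()
        cpos = cpg_grp["pos"].to_numpy()
        dist = np.abs(spos[:, None] - cpos[None, :])
        si, ci = np.nonzero(dist < window_bp)
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp_grp.index.to_numpy()[si],
                    "cpg_id": cpg_grp.index.to_numpy()[ci],
                    "distance": dist[si, ci].astype(int),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["snp_id", "cpg_id", "distance"])
    return pd.concat(rows, ignore_index=True)


def fit_meqtl(
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None,
    pairs: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Additive-dosage linear model per (SNP, CpG) cis pair.

    Covariates are projected out of both methylation and dosage (missing
    dosages mean-imputed within SNP), the per-allele slope and its Wald test
    follow from the residual regression with the full-model degrees of
    freedom, and BH runs across all tested pairs.  Effects are on the
    minor-allele dosage scale.
    """
    check_aligned(beta.sample_ids, genotypes.sample_ids)
    known_snps = set(genotypes.snp_ids)
    known_cpgs = set(beta.cpg_ids)
    ok = pairs["snp_id"].isin(known_snps) & pairs["cpg_id"].isin(known_cpgs)
    if (~ok).any():
        log.warning("fit_meqtl: skipping %d pairs referencing filtered features", (~ok).sum())
    pairs = pairs.loc[ok].reset_index(drop=True)
    n = len(beta.sample_ids)
    if covariates is not None:
        check_aligned(beta.sample_ids, covariates.sample_ids)
        X = add_intercept(drop_collinear(covariates.design()).to_numpy(), n)
    else:
        X = add_intercept(None, n)
    p_cov = np.linalg.matrix_rank(X)
    df = n - p_cov - 1
    M = beta.values.to_numpy().T  # n x cpgs
    G = genotypes.values.to_numpy(dtype=float)
    mean = np.nanmean(G, axis=1)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(mean, inds[0])
    Mr = residualize(M, X)
    Gr = residualize(G.T, X)  # n x snps
    cpg_ix = {c: i for i, c in enumerate(beta.cpg_ids)}
    snp_ix = {s: i for i, s in enumerate(genotypes.snp_ids)}
    ci = pairs["cpg_id"].map(cpg_ix).to_numpy()
    si = pairs["snp_id"].map(snp_ix).to_numpy()
    g = Gr[:, si]
    m = Mr[:, ci]
    gg = np.einsum("ij,ij->j", g, g)
    gm = np.einsum("ij,ij->j", g, m)
    mm = np.einsum("ij,ij->j", m, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(gg > 0, gm / gg, 0.0)
        rss_resid = np.maximum(mm - slope * gm, 0.0)
        se = np.sqrt(np.where(gg > 0, rss_resid / df / gg, np.inf))
        t = np.where(se > 0, slope / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), df)
    out = pairs.copy()
    out["beta"] = slope
    out["se"] = se
    out["p"] = pvals
    out["q"] = bh_adjust(pvals)
    out["significant"] = out["q"] < fdr_threshold
    return out


def distance_decay(results: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Fraction of tested pairs significant at FDR, per SNP-CpG distance bin.

    Empty bins report NaN (undefined), never zero.
    """
    if results.empty:
        raise ValueError("meQTL results are empty")
    edges = np.asarray(bin_edges)
    which = np.digitize(results["distance"], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        n_tested = int(mask.sum())
        frac = float(results.loc[mask, "significant"].mean()) if n_tested else np.nan
        rows.append(
            {
                "bin_start": int(edges[b]),
                "bin_end": int(edges[b + 1]),
                "n_tested": n_tested,
                "significant_fraction": frac,
            }
        )
    return pd.DataFrame(rows)
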