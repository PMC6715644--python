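"""Causal inference test (CIT) for genotype -> methylation -> cluster triplets.

Mediation of a SNP-cluster association by CpG methylation is declared when
all four component conditions hold: (1) G and Y are associated, (2) G is
associated with M given Y, (3) M is associated with Y given G, and (4) G is
independent of Y given M.  The CIT p-value is the maximum of the four
component p-values, so every condition must individually reject.

Conditions 1-3 are nested-model F-tests on covariate-adjusted linear models
with the cluster label encoded ordinally (M=0, S1=1, S2=2).  Condition 4 is
a permutation equivalence test: residual-permuted copies of G preserve the
G-M association while destroying any conditional G-Y dependence, giving the
F distribution under conditional independence; shifting it by the marginal
G-Y association strength turns it into the no-mediation (dependence) null,
and a small p4 then supports conditional independence, as the max-p
convention requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ClusterAssignment, CovariateTable, GenotypeMatrix
from .linalg import add_intercept, bh_adjust, nested_f_test, residualize
from .methylation import drop_collinear

log = logging.getLogger(__name__)

__all__ = ["CITResult", "MediationProfile", "cit_test", "screen_mediation",
           "mediation_effect_profile"]


@dataclass
class CITResult:
    snp_id: str
    cpg_id: str
    p1: float  # G ~ Y association
    p2: float  # G ~ M | Y
    p3: float  # M ~ Y | G
    p4: float  # equivalence: G independent of Y | M
    p_cit: float  # max of the four

    def components(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4])


@dataclass
class MediationProfile:
    beta_unadjusted: float
    ci_unadjusted: tuple
    beta_adjusted: float
    ci_adjusted: tuple


def _covariate_design(covariates: CovariateTable | None, n: int) -> np.ndarray:
    if covariates is None:
        return add_intercept(None, n)
    return add_intercept(drop_collinear(covariates.design()).to_numpy(), n)


def _f_stat_single(y: np.ndarray, x: np.ndarray, X_base: np.ndarray) -> tuple:
    """(F, p) for adding the single column x to the base design for y."""
    F, p, _, _, _ = nested_f_test(
        y[:, None], np.column_stack([X_base, x]), X_base
    )
    return float(F[0]), float(p[0])


def cit_test(
    G: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    covariates: CovariateTable | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    snp_id: str = "snp",
    cpg_id: str = "cpg",
) -> CITResult:
    """Four-condition causal inference test for one (G, M, Y) triplet."""
    G = np.asarray(G, dtype=float).ravel()
    M = np.asarray(M, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    n = len(Y)
    if not (len(G) == len(M) == n):
        raise ValueError("G, M, Y must be aligned")
    if np.std(G) == 0 or np.std(M) == 0:
        raise ValueError("constant G or M: CIT undefined")
    if n_perm < 100:
        log.warning("cit_test: n_perm=%d < 100 gives a coarse p4", n_perm)
    X = _covariate_design(covariates, n)
    # (1) G and Y associated
    _, p1 = _f_stat_single(Y, G, X)
    # (2) G associated with M after adjusting for Y
    _, p2 = _f_stat_single(M, G, np.column_stack([X, Y]))
    # (3) M associated with Y after adjusting for G
    _, p3 = _f_stat_single(Y, M, np.column_stack([X, G]))
    # (4) permutation equivalence test of G independent of Y given M
    p4 = _independence_p4(G, M, Y, X, n_perm, seed)
    p_cit = float(max(p1, p2, p3, p4))
    return CITResult(snp_id, cpg_id, float(p1), float(p2), float(p3), float(p4), p_cit)


def _independence_p4(
    G: np.ndarray, M: np.ndarray, Y: np.ndarray, X: np.ndarray, n_perm: int, seed: int
) -> float:
    """Equivalence-style test: small p supports G independent of Y given M.

    F* statistics from residual-permuted G (G-M association preserved) form
    the conditional-independence distribution; the margin
    delta = max(0, F_marginal - median(F*)) shifts it to represent the
    dependence (no-mediation) null; p4 is the add-one fraction of shifted
    F* at or below the observed conditional F.
    """
    n = len(Y)
    XM = np.column_stack([X, M])
    F_obs, _ = _f_stat_single(Y, G, XM)
    F_marg, _ = _f_stat_single(Y, G, X)
    # residualize G on (covariates, M); permuting these residuals keeps the
    # fitted G-M relationship intact
    e = residualize(G[:, None], XM).ravel()
    fitted = G - e
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    E = e[perms]  # n_perm x n
    # F for each permuted G* in Y ~ X + M + G*: via residual projection.
    # resid(G*|X,M) = resid(fitted + e_perm | X, M) = resid(e_perm | X, M)
    R = residualize(E.T, XM).T  # n_perm x n
    y_perp = residualize(Y[:, None], XM).ravel()
    df2 = n - np.linalg.matrix_rank(XM) - 1
    num = R @ y_perp
    denom_g = np.einsum("ij,ij->i", R, R)
    yy = float(y_perp @ y_perp)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom_g > 0, num**2 / (denom_g * yy), 0.0)
        F_star = r2 / (1 - r2) * df2
    delta = max(0.0, F_marg - float(np.median(F_star)))
    return float((1 + np.sum(F_star + delta <= F_obs)) / (n_perm + 1))


def screen_mediation(
    meqtl_results: pd.DataFrame,
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    assignment: ClusterAssignment,
    covariates: CovariateTable | None = None,
    fdr_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-stage mediation screen over significant meQTL pairs.

    Stage 1 tests every meQTL SNP for cluster association with the same
    covariate-adjusted model (BH FDR < ``fdr_threshold``); stage 2 runs the
    CIT on the surviving (SNP, CpG) pairs and BH-adjusts the CIT p-values
    across the screened triplets.
    """
    sig = meqtl_results.loc[meqtl_results.get("significant", False).astype(bool)]
    if sig.empty:
        log.info("screen_mediation: no significant meQTL pairs to screen")
        return _empty_cit_frame()
    Y = assignment.ordinal().to_numpy(dtype=float)
    n = len(Y)
    X = _covariate_design(covariates, n)
    snps = sig["snp_id"].unique().tolist()
    Gmat = genotypes.values.loc[snps].to_numpy(dtype=float)
    mean = np.nanmean(Gmat, axis=1)
    inds = np.where(np.isnan(Gmat))
    Gmat[inds] = np.take(mean, inds[0])
    p_stage1 = np.array(
        [_f_stat_single(Y, Gmat[i], X)[1] for i in range(len(snps))]
    )
    q_stage1 = bh_adjust(p_stage1)
    surviving = {s for s, q in zip(snps, q_stage1) if q < fdr_threshold}
    if not surviving:
        log.info("screen_mediation: no meQTL SNP is cluster-associated")
        return _empty_cit_frame()
    rng = np.random.default_rng(seed)
    rows = []
    for _, pair in sig.iterrows():
        if pair["snp_id"] not in surviving:
            continue
        g = Gmat[snps.index(pair["snp_id"])]
        m = beta.values.loc[pair["cpg_id"]].to_numpy(dtype=float)
        res = cit_test(
            g, m, Y, covariates, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
            snp_id=pair["snp_id"], cpg_id=pair["cpg_id"],
        )
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    out["q_cit"] = bh_adjust(out["p_cit"].to_numpy())
    out["mediation"] = out["q_cit"] < fdr_threshold
    return out


def _empty_cit_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["snp_id", "cpg_id", "p1", "p2", "p3", "p4", "p_cit", "q_cit",
                 "mediation"]
    )


def mediation_effect_profile(
    G: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    covariates: CovariateTable | None = None,
) -> MediationProfile:
    """Effect of G on Y with and without adjusting for M (95% intervals).

    Under mediation the adjusted coefficient shrinks toward zero.
    """
    from scipy import stats as sps

    from .linalg import ols_details

    G = np.asarray(G, dtype=float).ravel()
    M = np.asarray(M, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    n = len(Y)
    X = _covariate_design(covariates, n)
    if np.linalg.matrix_rank(np.column_stack([X, G, M])) < X.shape[1] + 2:
        raise ValueError("G and M are perfectly collinear with the design")

    def fit(design, col):
        beta, se, _, _, df = ols_details(Y, design)
        crit = sps.t.ppf(0.975, df)
        return float(beta[col]), (
            float(beta[col] - crit * se[col]),
            float(beta[col] + crit * se[col]),
        )

    X_un = np.column_stack([X, G])
    b_un, ci_un = fit(X_un, X_un.shape[1] - 1)
    X_adj = np.column_stack([X, M, G])
    b_adj, ci_adj = fit(X_adj, X_adj.shape[1] - 1)
    return MediationProfile(b_un, ci_un, b_adj, ci_adj)
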