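"""Differential methylation across clinical clusters.

Probe-level QC, a per-CpG covariate-adjusted ANOVA of methylation on the
cluster factor, a pairwise-contrast decomposition of significant CpGs (the
overall F gate at FDR < 0.1 followed by per-pair moderated contrasts is the
transparent analogue of limma's nestedF mode), BH FDR control, and the
genomic inflation factor as calibration diagnostic.

Ordinary (non-moderated) least squares is used throughout: with cohort-scale
residual degrees of freedom the empirical-Bayes moderation of limma changes
per-CpG variances negligibly, and OLS keeps every statistic reproducible by
the closed-form normal equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, ClusterAssignment, CovariateTable, check_aligned
from .linalg import add_intercept, bh_adjust, nested_f_test

log = logging.getLogger(__name__)

__all__ = [
    "filter_probes",
    "cluster_anova",
    "pairwise_contrasts",
    "inflation_lambda",
    "AssociationResult",
    "InflationReport",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class AssociationResult:
    """Per-CpG cluster-association table (F, p, BH q, partial R^2)."""

    table: pd.DataFrame  # index cpg_id; F, p, q, variance_explained
    fdr_threshold: float

    @property
    def significant(self) -> list:
        return list(self.table.index[self.table["q"] < self.fdr_threshold])


@dataclass
class InflationReport:
    lambda_gc: float
    n_tests: int


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def filter_probes(
    beta: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    crossreactive_ids=(),
    detection_alpha: float = 0.05,
    max_fail_fraction: float = 0.05,
):
    """Probe-level QC: poor-detection, cross-reactive and non-autosomal CpGs.

    A CpG is removed when its detection p-value exceeds ``detection_alpha``
    in strictly more than ``max_fail_fraction`` of samples, when it appears
    in the cross-reactive exclusion list, or when its manifest chromosome is
    not an autosome.  Returns the filtered matrix and per-class removal
    counts.
    """
    ids = pd.Index(beta.cpg_ids)
    removed = {}
    bad_detect = pd.Index([])
    if detection_p is not None:
        gap = ids.difference(detection_p.index)
        if len(gap):
            raise ValueError(f"detection p matrix missing CpGs: {list(gap[:5])}")
        fail_frac = (detection_p.loc[ids] > detection_alpha).mean(axis=1)
        bad_detect = ids[fail_frac > max_fail_fraction]
    removed["detection"] = len(bad_detect)
    bad_cross = ids.intersection(pd.Index(list(crossreactive_ids)))
    removed["cross_reactive"] = len(bad_cross)
    chroms = beta.manifest.loc[ids, "chrom"].map(_norm_chrom)
    bad_chrom = ids[~chroms.isin(AUTOSOMES)]
    removed["non_autosomal"] = len(bad_chrom)
    drop = bad_detect.union(bad_cross).union(bad_chrom)
    keep = ids.difference(drop, sort=False)
    log.info(
        "filter_probes: removed %d (detection %d, cross-reactive %d, "
        "non-autosomal %d), kept %d",
        len(drop),
        removed["detection"],
        removed["cross_reactive"],
        removed["non_autosomal"],
        len(keep),
    )
    return beta.subset(keep), removed


def drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedy left-to-right removal of columns that add no rank."""
    keep = []
    arr = np.empty((X.shape[0], 0))
    for col in X.columns:
        cand = np.column_stack([arr, X[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > arr.shape[1]:
            keep.append(col)
            arr = cand
        else:
            log.warning("dropping collinear covariate %r", col)
    return X[keep]


def _cluster_design(
    assignment: ClusterAssignment, covariates: CovariateTable | None, include_age=True
):
    """(X_full, X_reduced, dummy column order) for the cluster ANOVA model."""
    order = assignment.severity_order
    dummies = pd.get_dummies(
        pd.Categorical(assignment.labels, categories=order), drop_first=True
    ).astype(float)
    dummies.index = assignment.labels.index
    n = len(assignment.labels)
    if covariates is not None:
        cov = covariates.design()
        if not include_age and "age" in cov.columns:
            cov = cov.drop(columns="age")
        cov = drop_collinear(cov)
        X_red = add_intercept(cov.to_numpy(), n)
    else:
        X_red = add_intercept(None, n)
    X_full = np.column_stack([X_red, dummies.to_numpy()])
    return X_full, X_red, list(dummies.columns)


def cluster_anova(
    beta: BetaMatrix,
    assignment: ClusterAssignment,
    covariates: CovariateTable | None = None,
    fdr_threshold: float = 0.1,
    use_m_values: bool = False,
    include_age: bool = True,
) -> AssociationResult:
    """Per-CpG OLS of methylation on the cluster factor plus covariates.

    The cluster factor is tested by a (k-1)-df partial F-test; BH adjustment
    runs across all tested CpGs; variance_explained is the partial R^2 of
    the cluster factor.  Betas are modelled directly by default (the scale
    on which cluster differences are reported); M-values are available
    behind ``use_m_values``.
    """
    check_aligned(beta.sample_ids, assignment.sample_ids)
    if covariates is not None:
        check_aligned(beta.sample_ids, covariates.sample_ids)
    counts = assignment.labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 clusters each with >= 2 samples")
    Y = (beta.m_values() if use_m_values else beta.values).to_numpy().T  # n x m
    X_full, X_red, _ = _cluster_design(assignment, covariates, include_age)
    F, p, pr2, _, _ = nested_f_test(Y, X_full, X_red)
    zero_var = Y.std(axis=0) == 0
    if zero_var.any():
        log.warning("cluster_anova: %d zero-variance CpGs, p set to 1", zero_var.sum())
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"F": F, "p": p, "q": q, "variance_explained": pr2},
        index=pd.Index(beta.cpg_ids, name="cpg_id"),
    )
    return AssociationResult(table=table, fdr_threshold=fdr_threshold)


def pairwise_contrasts(
    anova_hits,
    beta: BetaMatrix,
    assignment: ClusterAssignment,
    covariates: CovariateTable | None = None,
    fdr_threshold: float = 0.1,
    include_age: bool = True,
) -> pd.DataFrame:
    """Pairwise cluster contrasts within the F-significant CpG set.

    For each cluster pair the contrast is a t-test from the same fitted
    model; delta_beta is the difference of covariate-adjusted cluster means
    (later-severity minus earlier); BH runs within each contrast across the
    gated CpGs.
    """
    hits = list(anova_hits)
    if not hits:
        return pd.DataFrame(columns=["cpg_id", "contrast", "delta_beta", "t", "p", "q"])
    sub = beta.subset(hits)
    check_aligned(sub.sample_ids, assignment.sample_ids)
    Y = sub.values.to_numpy().T  # n x m
    X_full, X_red, dummy_cols = _cluster_design(assignment, covariates, include_age)
    n, p_full = X_full.shape
    XtX_inv = np.linalg.inv(X_full.T @ X_full)
    B = XtX_inv @ X_full.T @ Y  # p_full x m
    resid = Y - X_full @ B
    df = n - np.linalg.matrix_rank(X_full)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    order = assignment.severity_order
    counts = assignment.labels.value_counts()
    frames = []
    n_base = p_full - len(dummy_cols)
    for a, b in combinations(order, 2):  # a earlier (milder) than b
        if counts.get(a, 0) == 0 or counts.get(b, 0) == 0:
            log.warning("contrast %s_vs_%s skipped: empty cluster", b, a)
            continue
        c = np.zeros(p_full)
        if b in dummy_cols:
            c[n_base + dummy_cols.index(b)] += 1.0
        if a in dummy_cols:
            c[n_base + dummy_cols.index(a)] -= 1.0
        est = c @ B
        var_c = float(c @ XtX_inv @ c)
        se = np.sqrt(np.maximum(sigma2 * var_c, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        pvals = 2 * stats.t.sf(np.abs(t), df)
        frames.append(
            pd.DataFrame(
                {
                    "cpg_id": hits,
                    "contrast": f"{b}_vs_{a}",
                    "delta_beta": est,
                    "t": t,
                    "p": pvals,
                    "q": bh_adjust(pvals),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["q"] < fdr_threshold
    return out


def inflation_lambda(p_values) -> InflationReport:
    """Genomic inflation factor: median association chi-square (1 df,
    quantile-transformed from p) over the null median chi-square."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    lam = float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
    return InflationReport(lambda_gc=lam, n_tests=int(p.size))
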