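"""Adjustment covariates for the association models.

Three blocks are constructed here and carried by every downstream linear
model: principal components of current-medication usage, reference-free
cell-composition surrogates (ReFACTor-style), and genetic ancestry principal
components from genome-wide dosages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CovariateTable, GenotypeMatrix
from .clustering import _cv_rank_error

log = logging.getLogger(__name__)

__all__ = [
    "medication_pca",
    "refactor_components",
    "ancestry_pcs",
    "assemble_covariates",
]


def _pca_scores(X: np.ndarray, n_components: int):
    """Centered PCA scores (n x k) and the explained-variance spectrum."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    return scores, s**2 / max(X.shape[0] - 1, 1)


def medication_pca(
    med_matrix: pd.DataFrame, n_folds: int = 3, seed: int = 0, max_components: int = 3
) -> pd.DataFrame:
    """Medication principal components, count chosen by cross-validation.

    Centered PCA on the dichotomized medication matrix; the number of
    retained components minimizes the fold-wise reconstruction error of
    held-out cells and is capped at ``max_components`` (three, following the
    study design).  A constant matrix yields zero components with a warning.
    """
    X = med_matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("medication matrix needs at least 2 medications")
    if not np.isin(X, [0.0, 1.0]).all():
        raise ValueError("medication matrix must be binary")
    if np.allclose(X.var(axis=0), 0.0):
        log.warning("medication_pca: constant matrix, returning zero components")
        return pd.DataFrame(index=med_matrix.index)
    upper = min(max_components, X.shape[1] - 1, X.shape[0] - 1)
    ranks = list(range(1, upper + 1))
    errors = _cv_rank_error(X, ranks, n_folds, seed)
    n_keep = ranks[int(np.argmin(errors))]
    scores, _ = _pca_scores(X, n_keep)
    cols = [f"medpc{i + 1}" for i in range(n_keep)]
    return pd.DataFrame(scores, index=med_matrix.index, columns=cols)


def refactor_components(
    beta: BetaMatrix, k: int = 6, t: int = 500
) -> pd.DataFrame:
    """Reference-free cell-composition surrogates (ReFACTor).

    Sites are standardized, a rank-k approximation is computed, sites are
    ranked by the distance between the observed and low-rank-reconstructed
    profiles, the ``t`` best-approximated sites are kept, and a PCA on those
    sites yields k per-sample component scores.  Defaults k=6, t=500 follow
    the published algorithm's defaults.
    """
    M = beta.values.to_numpy(dtype=float)  # CpGs x samples
    n_cpgs, n_samples = M.shape
    if k >= n_samples:
        raise ValueError("k (assumed cell types) must be < number of samples")
    t = min(t, n_cpgs)
    sd = M.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (M - M.mean(axis=1, keepdims=True)) / sd[:, None]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    low_rank = (U[:, :k] * s[:k]) @ Vt[:k]
    dist = np.linalg.norm(Z - low_rank, axis=1)
    ranked = np.argsort(dist, kind="mergesort")  # stable: row-order invariant ties
    selected = np.sort(ranked[:t])
    scores, spectrum = _pca_scores(Z[selected].T, k)
    if spectrum.size >= 2 and spectrum[0] < 1.5 * np.median(spectrum):
        log.warning(
            "refactor_components: flat variance spectrum; no clear latent "
            "cell-composition structure detected"
        )
    cols = [f"cellc{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=beta.sample_ids, columns=cols)


def ancestry_pcs(genotypes: GenotypeMatrix, n_components: int = 3) -> pd.DataFrame:
    """Genetic ancestry principal components from frequency-standardized,
    mean-imputed dosages (standardization by sqrt(2p(1-p)))."""
    G = genotypes.values.to_numpy(dtype=float)  # SNPs x samples
    if n_components == 0:
        return pd.DataFrame(index=genotypes.sample_ids)
    p = np.nanmean(G, axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; ancestry PCA undefined")
    G = G[poly]
    p = p[poly]
    mean = 2.0 * p
    G = np.where(np.isnan(G), mean[:, None], G)
    Z = (G - mean[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    scores, _ = _pca_scores(Z.T, min(n_components, Z.shape[0], Z.shape[1] - 1))
    cols = [f"ancpc{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=genotypes.sample_ids, columns=cols)


def assemble_covariates(
    base: pd.DataFrame,
    medication_scores: pd.DataFrame | None = None,
    cell_scores: pd.DataFrame | None = None,
    ancestry_scores: pd.DataFrame | None = None,
) -> CovariateTable:
    """Join the covariate blocks into one sample-aligned table.

    ``base`` supplies sex/age/smoke/alcohol (and optionally an ethnicity
    label column); the score blocks must be indexed by the same samples.
    """
    parts = [base]
    for block in (medication_scores, cell_scores, ancestry_scores):
        if block is not None and block.shape[1] > 0:
            if list(block.index) != list(base.index):
                raise ValueError("covariate blocks are not sample-aligned")
            parts.append(block)
    return CovariateTable(pd.concat(parts, axis=1))
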