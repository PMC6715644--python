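"""Patient subtyping from binary clinical criteria.

The discovery path is: dichotomize the criterion table, embed it with
multiple correspondence analysis (MCA, i.e. correspondence analysis of the
complete disjunctive indicator matrix), keep the top dimensions selected by
cell-wise cross-validation, K-means the retained coordinates, and choose the
number of clusters k by bootstrap Jaccard stability.  Cluster labels are
finally renamed M, S1, ..., S(k-1) in increasing order of severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ClusterAssignment, CriteriaMatrix

log = logging.getLogger(__name__)

__all__ = [
    "MCAResult",
    "StabilityProfile",
    "dichotomize_criteria",
    "mca",
    "select_dimensions",
    "kmeans_cluster",
    "bootstrap_stability",
    "order_clusters_by_severity",
]

#: stability threshold the study design requires every retained cluster to meet
JACCARD_STABILITY_THRESHOLD = 0.82


@dataclass
class MCAResult:
    """Principal row/category coordinates of the indicator-matrix CA."""

    coordinates: pd.DataFrame  # samples x dimensions, principal scale
    eigenvalues: np.ndarray  # per-dimension inertia, non-increasing
    total_inertia: float  # equals (J/Q) - 1 for complete binary data
    category_coordinates: pd.DataFrame  # categories x dimensions

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")


@dataclass
class StabilityProfile:
    """Bootstrap Jaccard stability of K-means solutions over candidate k."""

    k_values: list
    per_cluster_jaccard: dict  # k -> np.ndarray of per-cluster mean Jaccard
    selected_k: int
    n_bootstrap: int
    threshold: float = JACCARD_STABILITY_THRESHOLD

    def passes_threshold(self, k: int | None = None) -> bool:
        k = self.selected_k if k is None else k
        return bool(np.all(self.per_cluster_jaccard[k] > self.threshold))


def dichotomize_criteria(raw: pd.DataFrame, rules: dict) -> CriteriaMatrix:
    """Map a raw phenotype table to strict {0,1} criteria.

    ``rules`` maps each criterion name to a value->{0,1} dictionary.  Samples
    carrying any value without a mapping (including NaN) are excluded and
    logged; zero-variance columns are retained but flagged.
    """
    missing_rules = [c for c in raw.columns if c not in rules]
    if missing_rules:
        raise ValueError(f"no dichotomization rule for criteria: {missing_rules}")
    mapped = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        mapped[col] = raw[col].map(rules[col])
    bad = mapped.isna().any(axis=1)
    if bad.any():
        log.warning(
            "dichotomize_criteria: excluding %d samples with unmapped values: %s",
            int(bad.sum()),
            list(raw.index[bad][:10]),
        )
    out = CriteriaMatrix(mapped.loc[~bad].astype(int))
    zv = out.zero_variance_criteria()
    if zv:
        log.warning("dichotomize_criteria: zero-variance criteria retained: %s", zv)
    return out


def indicator_matrix(criteria: CriteriaMatrix) -> pd.DataFrame:
    """Complete disjunctive coding: each binary criterion -> two categories."""
    X = criteria.values
    blocks = {}
    for col in X.columns:
        blocks[f"{col}=1"] = X[col].astype(float)
        blocks[f"{col}=0"] = 1.0 - X[col]
    return pd.DataFrame(blocks, index=X.index)


def mca(criteria: CriteriaMatrix) -> MCAResult:
    """Correspondence analysis of the indicator matrix, principal row scale.

    Coordinates are reproducible up to per-dimension sign.  For Q complete
    binary variables the total inertia is (J/Q) - 1 = 1 with J = 2Q.
    """
    X = criteria.values
    if X.shape[0] < 2:
        raise ValueError("MCA needs at least 2 samples")
    nonconst = X.nunique() > 1
    if nonconst.sum() < 2:
        raise ValueError("MCA needs at least 2 non-constant criteria")
    Z = indicator_matrix(criteria).to_numpy()
    n, J = Z.shape
    Q = J // 2
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0  # categories never observed carry no mass
    S = (P[:, keep] - np.outer(r, c[keep])) / np.sqrt(np.outer(r, c[keep]))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-null dimensions
    ndim = int(np.sum(s > 1e-12 * max(1.0, s[0] if s.size else 1.0)))
    U, s, Vt = U[:, :ndim], s[:ndim], Vt[:ndim]
    row_coords = (U / np.sqrt(r)[:, None]) * s
    col_coords = (Vt.T / np.sqrt(c[keep])[:, None]) * s
    dims = [f"dim{i + 1}" for i in range(ndim)]
    cat_names = np.asarray(indicator_matrix(criteria).columns)[keep]
    return MCAResult(
        coordinates=pd.DataFrame(row_coords, index=X.index, columns=dims),
        eigenvalues=s**2,
        total_inertia=J / Q - 1.0,
        category_coordinates=pd.DataFrame(col_coords, index=cat_names, columns=dims),
    )


def _cv_rank_error(
    M: np.ndarray, ranks, n_folds: int, seed: int, n_iter: int = 25
) -> np.ndarray:
    """Cross-validated reconstruction error of held-out cells per rank.

    Cells are partitioned into folds; held-out cells are imputed by an
    iterative rank-d SVD scheme (column-mean start, impute, re-fit), and the
    squared error on the held-out cells is accumulated per candidate rank.
    """
    rng = np.random.default_rng(seed)
    n, m = M.shape
    fold_of = rng.integers(0, n_folds, size=(n, m))
    errors = np.zeros(len(ranks))
    for fold in range(n_folds):
        mask = fold_of == fold
        for ri, d in enumerate(ranks):
            W = M.copy()
            col_mean = np.where(
                (~mask).sum(axis=0) > 0,
                np.nansum(np.where(mask, np.nan, M), axis=0)
                / np.maximum((~mask).sum(axis=0), 1),
                0.0,
            )
            W[mask] = np.broadcast_to(col_mean, M.shape)[mask]
            for _ in range(n_iter):
                mu = W.mean(axis=0)
                U, s, Vt = np.linalg.svd(W - mu, full_matrices=False)
                # regularized reconstruction: shrink singular values by the
                # residual noise level so held-out cells are not overfit
                sigma2 = float(np.mean(s[d:] ** 2)) if d < s.size else 0.0
                s_shrunk = np.maximum(s[:d] - sigma2 / np.maximum(s[:d], 1e-12), 0.0)
                recon = (U[:, :d] * s_shrunk) @ Vt[:d] + mu
                W[mask] = recon[mask]
            errors[ri] += float(np.sum((M[mask] - W[mask]) ** 2))
    return errors


def select_dimensions(
    criteria: CriteriaMatrix, max_dim: int, n_folds: int = 5, seed: int = 0
) -> int:
    """Pick the MCA dimensionality by k-fold cross-validation of held-out
    indicator cells (impute-by-rank-d); ties break toward fewer dimensions."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    Q = criteria.values.shape[1]
    if max_dim >= Q:
        raise ValueError(
            f"max_dim must be < categories - variables = {Q} for binary data"
        )
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    # hold out criterion cells, not raw indicator cells: the two indicator
    # columns of a criterion are complements, so holding out only one of the
    # pair leaks the answer and inflates the selected rank
    Z = criteria.values.to_numpy(dtype=float)
    ranks = list(range(1, max_dim + 1))
    errors = _cv_rank_error(Z, ranks, n_folds, seed)
    return ranks[int(np.argmin(errors))]  # argmin returns first (fewest dims) on ties


def kmeans_cluster(
    coords: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> ClusterAssignment:
    """Best-of-restarts Lloyd K-means (k-means++ starts) on MCA coordinates."""
    n = coords.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        init="k-means++",
        tol=1e-6,
        random_state=int(seed) % (2**32),
    ).fit(coords.to_numpy())
    labels = pd.Series(
        [f"C{lab}" for lab in km.labels_], index=coords.index, name="cluster"
    )
    return ClusterAssignment(labels=labels, centroids=km.cluster_centers_)


def _bootstrap_jaccard(
    X: np.ndarray, base_labels: np.ndarray, k: int, n_bootstrap: int, rng, n_restarts: int
) -> np.ndarray:
    """clusterboot convention: mean, over resamples, of each original
    cluster's best Jaccard match among bootstrap clusters, computed over the
    intersection with the resampled points."""
    n = X.shape[0]
    sums = np.zeros(k)
    counts = np.zeros(k)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        seed_b = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=n_restarts, tol=1e-6, random_state=seed_b)
        boot_labels = km.fit(X[idx]).labels_
        present = np.unique(idx)
        in_boot_cluster = [set(idx[boot_labels == c].tolist()) for c in range(k)]
        present_set = set(present.tolist())
        for c in range(k):
            orig = set(np.flatnonzero(base_labels == c).tolist()) & present_set
            if not orig:
                continue
            best = 0.0
            for members in in_boot_cluster:
                inter = len(orig & members)
                union = len(orig | members)
                if union:
                    best = max(best, inter / union)
            sums[c] += best
            counts[c] += 1
    return sums / np.maximum(counts, 1)


def bootstrap_stability(
    coords: pd.DataFrame,
    k_candidates,
    n_bootstrap: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
) -> StabilityProfile:
    """Bootstrap Jaccard stability profile over candidate cluster counts.

    selected_k maximizes the minimum per-cluster mean Jaccard (a conservative
    reading of requiring every cluster to be stable); ties break toward the
    smaller k.
    """
    k_candidates = list(k_candidates)
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    if n_bootstrap < 20:
        raise ValueError("n_bootstrap must be >= 20 for stable Jaccard means")
    X = coords.to_numpy()
    rng = np.random.default_rng(seed)
    per_cluster = {}
    for k in sorted(k_candidates):
        base = KMeans(
            n_clusters=k, n_init=n_restarts, tol=1e-6, random_state=int(seed) % (2**32)
        ).fit(X)
        per_cluster[k] = _bootstrap_jaccard(
            X, base.labels_, k, n_bootstrap, rng, n_restarts
        )
    mins = {k: float(np.min(v)) for k, v in per_cluster.items()}
    selected = min(sorted(k_candidates), key=lambda k: (-mins[k], k))
    return StabilityProfile(
        k_values=sorted(k_candidates),
        per_cluster_jaccard=per_cluster,
        selected_k=selected,
        n_bootstrap=n_bootstrap,
    )


def order_clusters_by_severity(
    assignment: ClusterAssignment,
    criteria: CriteriaMatrix,
    severity_column: pd.Series | None = None,
) -> ClusterAssignment:
    """Rename clusters M, S1, ..., S(k-1) in increasing severity.

    Severity is the cluster mean of the per-sample criterion count, or of the
    supplied severity score when given.  Ties break by renal-criterion
    prevalence, then lexicographically by original label.
    """
    if list(assignment.sample_ids) != list(criteria.sample_ids):
        raise ValueError("assignment and criteria are not sample-aligned")
    if severity_column is not None:
        stat = severity_column.reindex(assignment.labels.index)
    else:
        stat = criteria.values.sum(axis=1)
    by_cluster = stat.groupby(assignment.labels).mean()
    renal_cols = [c for c in criteria.criterion_names if "renal" in str(c).lower()]
    if renal_cols:
        renal = criteria.values[renal_cols[0]].groupby(assignment.labels).mean()
    else:
        renal = pd.Series(0.0, index=by_cluster.index)
    order = sorted(
        by_cluster.index,
        key=lambda lab: (round(float(by_cluster[lab]), 12), float(renal[lab]), str(lab)),
    )
    if len({round(float(v), 12) for v in by_cluster.values}) < len(by_cluster):
        log.warning("order_clusters_by_severity: tie broken by renal prevalence")
    new_names = ["M"] + [f"S{i}" for i in range(1, len(order))]
    rename = dict(zip(order, new_names))
    labels = assignment.labels.map(rename)
    labels.name = "cluster"
    centroids = assignment.centroids
    return ClusterAssignment(
        labels=labels, centroids=centroids, severity_order=new_names
    )
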