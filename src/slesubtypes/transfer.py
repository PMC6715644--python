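"""Cluster label transfer to an external cohort and CpG validation there.

A random forest is trained on the discovered cluster labels with the binary
criteria as features (parameters chosen by out-of-bag error), applied to an
identically-dichotomized external criterion table, and the discovery CpG
associations are re-tested in the external cohort with its reduced
covariate set; per-contrast delta-beta values are correlated against the
discovery estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import BetaMatrix, ClusterAssignment, CovariateTable, CriteriaMatrix
from .methylation import cluster_anova, pairwise_contrasts

log = logging.getLogger(__name__)

__all__ = ["TransferModel", "train_cluster_model", "transfer_labels", "validate_cpgs"]

DEFAULT_PARAM_GRID = {
    "n_estimators": [250, 500, 1000],
    "max_features": ["sqrt", 0.3333, 1.0],
}


@dataclass
class TransferModel:
    forest: RandomForestClassifier
    feature_names: list
    classes: list
    oob_error_curve: pd.DataFrame  # one row per grid point
    selected_params: dict

    @property
    def oob_error(self) -> float:
        return float(1.0 - self.forest.oob_score_)


def train_cluster_model(
    criteria: CriteriaMatrix,
    labels: ClusterAssignment,
    param_grid: dict | None = None,
    seed: int = 0,
) -> TransferModel:
    """Random-forest classifier of cluster label from binary criteria.

    The grid over tree count and features-per-split is searched by
    minimizing the out-of-bag error; the full error curve is retained.
    """
    if list(criteria.sample_ids) != list(labels.sample_ids):
        raise ValueError("criteria and labels are not sample-aligned")
    y = labels.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = criteria.values.to_numpy(dtype=float)
    grid = param_grid or DEFAULT_PARAM_GRID
    rows = []
    best = None
    for n_est in grid["n_estimators"]:
        for mf in grid["max_features"]:
            rf = RandomForestClassifier(
                n_estimators=int(n_est),
                max_features=mf,
                oob_score=True,
                random_state=int(seed) % (2**32),
                n_jobs=1,
            ).fit(X, y)
            err = 1.0 - rf.oob_score_
            rows.append({"n_estimators": n_est, "max_features": mf, "oob_error": err})
            if best is None or err < best[0] - 1e-12:
                best = (err, rf, {"n_estimators": n_est, "max_features": mf})
    curve = pd.DataFrame(rows)
    err, rf, params = best
    log.info("train_cluster_model: selected %s (OOB error %.3f)", params, err)
    return TransferModel(
        forest=rf,
        feature_names=list(criteria.criterion_names),
        classes=list(rf.classes_),
        oob_error_curve=curve,
        selected_params=params,
    )


def transfer_labels(
    model: TransferModel, external_criteria: CriteriaMatrix
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Predict cluster labels for an external cohort (columns matched by name)."""
    missing = [c for c in model.feature_names if c not in external_criteria.criterion_names]
    if missing:
        raise ValueError(f"external criteria missing columns: {missing}")
    X = external_criteria.values[model.feature_names].to_numpy(dtype=float)
    votes = model.forest.predict_proba(X)
    pred = np.asarray(model.classes)[votes.argmax(axis=1)]
    labels = pd.Series(pred, index=external_criteria.sample_ids, name="cluster")
    assignment = ClusterAssignment(labels=labels, severity_order=sorted(model.classes, key=_severity_key))
    vote_df = pd.DataFrame(votes, index=external_criteria.sample_ids, columns=model.classes)
    return assignment, vote_df


def _severity_key(label: str):
    # "M" sorts before "S1" < "S2" < ...
    return (0, 0) if label == "M" else (1, int(str(label).lstrip("S") or 0))


def validate_cpgs(
    external_beta: BetaMatrix,
    transferred: ClusterAssignment,
    external_covariates: CovariateTable | None,
    cpg_list,
    discovery_contrasts: pd.DataFrame,
    fdr_threshold: float = 0.1,
) -> dict:
    """Re-test discovery CpGs in the external cohort; correlate delta-betas.

    ``cpg_list`` must already be restricted to probes present on the
    external platform.  The external model uses the cohort's reduced
    covariates (cell composition, ancestry, sex, age: whatever the supplied
    table carries).  Returns the validation ANOVA table, the external
    pairwise contrasts, the validated fraction at the FDR threshold, and
    the per-contrast Pearson correlation of delta-beta values.
    """
    cpgs = [c for c in cpg_list if c in set(external_beta.cpg_ids)]
    if not cpgs:
        raise ValueError("no overlapping CpGs between discovery list and platform")
    sub = external_beta.subset(cpgs)
    assoc = cluster_anova(
        sub, transferred, external_covariates, fdr_threshold=fdr_threshold
    )
    validated = assoc.table["q"] < fdr_threshold
    contrasts = pairwise_contrasts(
        cpgs, sub, transferred, external_covariates, fdr_threshold=fdr_threshold
    )
    corr = {}
    disc = discovery_contrasts.set_index(["cpg_id", "contrast"])["delta_beta"]
    ext = contrasts.set_index(["cpg_id", "contrast"])["delta_beta"]
    for contrast in contrasts["contrast"].unique():
        d = disc.xs(contrast, level="contrast").reindex(cpgs)
        e = ext.xs(contrast, level="contrast").reindex(cpgs)
        ok = d.notna() & e.notna()
        corr[contrast] = float(np.corrcoef(d[ok], e[ok])[0, 1]) if ok.sum() > 2 else np.nan
    return {
        "association": assoc.table.assign(validated=validated),
        "contrasts": contrasts,
        "validated_fraction": float(validated.mean()),
        "delta_beta_correlation": corr,
    }
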