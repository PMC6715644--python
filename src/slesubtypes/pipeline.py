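"""End-to-end pipeline runner: simulate (optional) -> cluster -> covariates
-> differential methylation -> meQTL -> CIT -> enrichment -> transfer.

Every stage writes TSV/JSON artifacts into the output directory plus a run
manifest of seeds, thresholds and input hashes; a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, covariates as cov_mod, enrichment, meqtl, mediation
from . import methylation, simulate, transfer
from .containers import check_aligned, CovariateTable

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # thresholds (study defaults)
    dm_fdr: float = 0.1
    meqtl_fdr: float = 0.05
    cit_fdr: float = 0.05
    cis_window: int = 1_000_000
    maf_min: float = 0.05
    hwe_alpha: float = 1e-4
    r2_max: float = 0.8
    n_perm: int = 1000
    cit_n_perm: int = 200
    k_candidates: tuple = (2, 3, 4)
    n_bootstrap: int = 50
    refactor_k: int = 6
    refactor_t: int = 500
    ancestry_components: int = 3
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "cluster": True,
            "covariates": True,
            "dm": True,
            "meqtl": True,
            "cit": True,
            "enrich": True,
            "transfer": True,
        }
    )
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        return cfg

    def validate(self) -> None:
        for name in ("dm_fdr", "meqtl_fdr", "cit_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if self.cis_window <= 0 or not 0 <= self.maf_min < 0.5:
            raise ValueError("invalid cis_window or maf_min")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order and write all artifacts.

    A stage failure halts the run with the stage name; stages whose inputs
    were toggled off refuse to run with a clear error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "hashes": {}}
    stages = config.stages
    state: dict = {}

    def run_stage(name, fn):
        if not stages.get(name, False):
            return
        t0 = time.time()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {"wall_time_s": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", name, time.time() - t0)

    def need(key, producer):
        if key not in state:
            raise RuntimeError(
                f"stage requires '{key}' but stage '{producer}' is toggled off"
            )
        return state[key]

    # ---- simulate --------------------------------------------------------
    def stage_simulate():
        sim_cfg = simulate.SimulationConfig(**{**config.simulation, "seed": config.seed})
        cohort = simulate.simulate_cohort(sim_cfg)
        paths = simulate.write_cohort(cohort, out / "cohort")
        manifest["hashes"].update({k: _hash_file(p) for k, p in paths.items()})
        state["cohort"] = cohort

    run_stage("simulate", stage_simulate)

    # ---- clustering ------------------------------------------------------
    def stage_cluster():
        cohort = need("cohort", "simulate")
        res = clustering.mca(cohort.criteria)
        coords = res.coordinates.iloc[:, :2]
        profile = clustering.bootstrap_stability(
            coords, config.k_candidates, n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        assign = clustering.kmeans_cluster(coords, profile.selected_k, seed=config.seed)
        assign = clustering.order_clusters_by_severity(assign, cohort.criteria)
        assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t", index_label="sample_id")
        with open(out / "stability.json", "w") as fh:
            json.dump(
                {
                    "selected_k": profile.selected_k,
                    "per_cluster_jaccard": {
                        str(k): [round(float(x), 6) for x in v]
                        for k, v in profile.per_cluster_jaccard.items()
                    },
                    "passes_threshold": profile.passes_threshold(),
                },
                fh,
                indent=1,
            )
        state["assignment"] = assign
        state["mca"] = res

    run_stage("cluster", stage_cluster)

    # ---- covariates ------------------------------------------------------
    def stage_covariates():
        cohort = need("cohort", "simulate")
        medpcs = cov_mod.medication_pca(cohort.medications, seed=config.seed)
        cells = cov_mod.refactor_components(
            cohort.beta, k=config.refactor_k, t=config.refactor_t
        )
        ancs = cov_mod.ancestry_pcs(cohort.genotypes, config.ancestry_components)
        table = cov_mod.assemble_covariates(cohort.covariates, medpcs, cells, ancs)
        table.values.to_csv(out / "covariates_full.tsv", sep="\t", index_label="sample_id")
        state["covariates"] = table

    run_stage("covariates", stage_covariates)

    # ---- differential methylation ---------------------------------------
    def stage_dm():
        cohort = need("cohort", "simulate")
        assign = need("assignment", "cluster")
        covs = need("covariates", "covariates")
        check_aligned(cohort.beta.sample_ids, covs.sample_ids)
        assoc = methylation.cluster_anova(
            cohort.beta, assign, covs, fdr_threshold=config.dm_fdr
        )
        contrasts = methylation.pairwise_contrasts(
            assoc.significant, cohort.beta, assign, covs, fdr_threshold=config.dm_fdr
        )
        lam = methylation.inflation_lambda(assoc.table["p"])
        assoc.table.to_csv(out / "dm_association.tsv", sep="\t")
        contrasts.to_csv(out / "dm_contrasts.tsv", sep="\t", index=False)
        with open(out / "dm_inflation.json", "w") as fh:
            json.dump({"lambda": lam.lambda_gc, "n_tests": lam.n_tests}, fh)
        state["dm"] = assoc
        state["contrasts"] = contrasts

    run_stage("dm", stage_dm)

    # ---- meQTL -----------------------------------------------------------
    def stage_meqtl():
        cohort = need("cohort", "simulate")
        covs = need("covariates", "covariates")
        dm = need("dm", "dm")
        geno, qc_report = meqtl.genotype_qc(
            cohort.genotypes, maf_min=config.maf_min, hwe_alpha=config.hwe_alpha
        )
        pos_sorted = geno.positions.sort_values(["chrom", "pos"])
        geno = geno.subset(pos_sorted.index)
        kept = meqtl.ld_prune(geno, r2_max=config.r2_max)
        geno = geno.subset(kept)
        hit_cpgs = dm.significant
        pairs = meqtl.map_cis_pairs(
            geno.positions,
            cohort.beta.manifest.loc[hit_cpgs],
            window_bp=config.cis_window,
        )
        results = meqtl.fit_meqtl(
            cohort.beta, geno, covs, pairs, fdr_threshold=config.meqtl_fdr
        )
        results.to_csv(out / "meqtl.tsv", sep="\t", index=False)
        state["meqtl"] = results
        state["genotypes_qc"] = geno

    run_stage("meqtl", stage_meqtl)

    # ---- CIT -------------------------------------------------------------
    def stage_cit():
        cohort = need("cohort", "simulate")
        covs = need("covariates", "covariates")
        results = need("meqtl", "meqtl")
        assign = need("assignment", "cluster")
        geno = need("genotypes_qc", "meqtl")
        cit = mediation.screen_mediation(
            results, cohort.beta, geno, assign, covs,
            fdr_threshold=config.cit_fdr, n_perm=config.cit_n_perm, seed=config.seed,
        )
        cit.to_csv(out / "cit.tsv", sep="\t", index=False)
        state["cit"] = cit

    run_stage("cit", stage_cit)

    # ---- enrichment ------------------------------------------------------
    def stage_enrich():
        cohort = need("cohort", "simulate")
        covs = need("covariates", "covariates")
        dm = need("dm", "dm")
        if not dm.significant:
            log.warning("enrichment skipped: no significant CpGs")
            return
        res = enrichment.ethnicity_permutation_enrichment(
            cohort.beta,
            cohort.covariates["ethnicity"],
            covs,
            dm.significant,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        with open(out / "ethnicity_enrichment.json", "w") as fh:
            json.dump(
                {
                    "n_cluster": res.n_cluster,
                    "n_race_observed": res.n_race_observed,
                    "null_mean": res.null_mean,
                    "enrichment_statistic": res.enrichment_statistic,
                    "p_perm": res.p_perm,
                    "n_perm": res.n_perm,
                    "null_counts": res.null_counts.tolist(),
                },
                fh,
            )
        state["enrichment"] = res

    run_stage("enrich", stage_enrich)

    # ---- transfer --------------------------------------------------------
    def stage_transfer():
        cohort = need("cohort", "simulate")
        assign = need("assignment", "cluster")
        contrasts = need("contrasts", "dm")
        dm = need("dm", "dm")
        model = transfer.train_cluster_model(
            cohort.criteria, assign,
            param_grid={"n_estimators": [250, 500], "max_features": ["sqrt", 1.0]},
            seed=config.seed,
        )
        ext_cfg = simulate.SimulationConfig(
            **{**config.simulation, "seed": config.seed + 101}
        )
        external = simulate.simulate_cohort(ext_cfg)
        pred, votes = transfer.transfer_labels(model, external.criteria)
        pred.labels.to_frame().to_csv(out / "transfer_labels.tsv", sep="\t",
                                      index_label="sample_id")
        votes.to_csv(out / "transfer_votes.tsv", sep="\t", index_label="sample_id")
        if dm.significant:
            ext_cov = CovariateTable(
                external.covariates[["sex", "age"]].astype(float)
            )
            val = transfer.validate_cpgs(
                external.beta, pred, ext_cov, dm.significant, contrasts,
                fdr_threshold=config.dm_fdr,
            )
            val["association"].to_csv(out / "validation.tsv", sep="\t")
            with open(out / "validation_summary.json", "w") as fh:
                json.dump(
                    {
                        "oob_error": model.oob_error,
                        "validated_fraction": val["validated_fraction"],
                        "delta_beta_correlation": val["delta_beta_correlation"],
                    },
                    fh,
                )
            state["validation"] = val
        state["transfer_model"] = model

    run_stage("transfer", stage_transfer)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest_stable(manifest), fh, indent=1, sort_keys=True)
    return out


def manifest_stable(manifest: dict) -> dict:
    # wall times vary between runs; keep them out of the determinism contract
    out = {k: v for k, v in manifest.items() if k != "stages"}
    out["stages_run"] = sorted(manifest["stages"])
    return out
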