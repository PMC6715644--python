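"""Synthetic multi-omic lupus cohorts with known ground truth.

The generator emulates the statistical structure every downstream stage
assumes: latent clinical clusters with cluster-specific binary-criterion
prevalences (defaults follow the published cohort's criterion table), CpGs
whose mean beta shifts with cluster, cis SNPs controlling a subset of those
CpGs, genotype-methylation-cluster triplets generated under causal, reactive
and independent graphs, ethnicity labels correlated with cluster and with a
subset of CpGs independently of genotype, and nuisance structure
(cell-composition-like latent factors and medication usage correlated with
cluster).

Beta values are generated on the logit scale and inverse-transformed, which
guarantees (0,1) support without boundary pile-up; the logit noise scale is
chosen by the delta method so that the residual SD on the beta scale matches
``noise_sd``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import BetaMatrix, CriteriaMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_mediation_triplets",
    "synthesize_detection_p",
    "write_cohort",
]

#: Cluster-specific prevalence (fraction) of each ACR criterion/sub-criterion,
#: rows = clusters ordered mild -> severe, from the published cohort summary.
DEFAULT_CRITERIA = [
    "malar_rash", "discoid_rash", "oral_ulcers", "arthritis", "pleuritis",
    "pericarditis", "seizure", "psychosis", "anti_dsdna", "anti_smith",
    "ana", "hemolytic_anemia", "leukopenia", "lymphopenia",
    "thrombocytopenia", "renal", "photosensitivity", "apla",
]

DEFAULT_PREVALENCE = np.array([
    # M      S1     S2
    [.683, .208, .628],
    [.149, .052, .205],
    [.703, .266, .487],
    [.931, .662, .885],
    [.480, .175, .385],
    [.130, .136, .359],
    [.080, .045, .090],
    [.050, .006, .090],
    [.356, .760, .923],
    [.099, .279, .577],
    [.891, .987, .987],
    [.010, .085, .154],
    [.040, .117, .654],
    [.198, .169, .769],
    [.089, .130, .346],
    [.158, .623, .577],
    [.733, .182, .410],
    [.257, .325, .423],
]).T  # clusters x criteria

DEFAULT_PROPORTIONS = np.array([101, 154, 78]) / 333.0

#: ethnicity composition within each cluster (columns M, S1, S2)
DEFAULT_ETHNICITY = {
    "White": [0.480, 0.227, 0.167],
    "Hispanic": [0.180, 0.221, 0.308],
    "AfricanAmerican": [0.110, 0.097, 0.128],
    "Asian": [0.200, 0.448, 0.372],
    "Other": [0.030, 0.007, 0.025],
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    n_samples: int = 333
    n_criteria: int = 18
    n_clusters: int = 3
    criterion_prevalence: np.ndarray = field(
        default_factory=lambda: DEFAULT_PREVALENCE.copy()
    )
    cluster_proportions: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROPORTIONS.copy()
    )
    n_cpgs: int = 2000
    n_cluster_cpgs: int = 50
    delta_beta: float = 0.05
    n_snps: int = 300
    maf_range: tuple = (0.05, 0.5)
    n_meqtl: int = 50
    meqtl_effect: float = 0.05
    meqtl_maf: float = 0.3
    mediation_scenarios: dict = field(
        default_factory=lambda: {"causal": 5, "reactive": 5, "independent": 5}
    )
    mediation_y_weight: float = 1.0  # causal: standardized M -> severity score
    mediation_direct_weight: float = 0.4  # reactive/independent: std G -> score
    n_cell_factors: int = 6  # major leukocyte fractions in whole blood
    cell_effect: float = 0.05  # beta-scale loading SD on affected CpGs
    cell_cluster_shift: float = 0.3  # confounding of first factor with severity
    ethnicity_groups: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY))
    n_ethnic_cpgs: int = 30
    ethnic_effect: float = 0.05
    n_medications: int = 16
    n_med_cpgs: int = 5
    med_effect: float = 0.05
    noise_sd: float = 0.03
    genotype_missing_rate: float = 0.0
    seed: int = 0
    biology_seed: int = 2020  # shared effect structure across replication cohorts

    def validate(self) -> None:
        prev = np.asarray(self.criterion_prevalence, dtype=float)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if prev.shape != (self.n_clusters, self.n_criteria):
            raise ConfigurationError(
                "criterion_prevalence must be n_clusters x n_criteria "
                f"({self.n_clusters} x {self.n_criteria}), got {prev.shape}"
            )
        if np.any((prev < 0) | (prev > 1)):
            raise ConfigurationError("criterion_prevalence entries must lie in [0,1]")
        if props.shape != (self.n_clusters,) or abs(props.sum() - 1) > 1e-12:
            raise ConfigurationError("cluster_proportions must sum to 1 within 1e-12")
        if self.n_cluster_cpgs > self.n_cpgs:
            raise ConfigurationError("n_cluster_cpgs exceeds n_cpgs")
        n_med_trip = sum(self.mediation_scenarios.values())
        if self.n_meqtl < n_med_trip:
            raise ConfigurationError("n_meqtl smaller than mediation triplet count")
        if self.n_snps < self.n_meqtl:
            raise ConfigurationError("n_snps smaller than n_meqtl")
        if self.n_cluster_cpgs + n_med_trip + self.n_med_cpgs > self.n_cpgs:
            raise ConfigurationError("n_cpgs too small for planted CpG classes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be within (0, 0.5]")
        bad = {k for k in self.mediation_scenarios} - {"causal", "reactive", "independent"}
        if bad:
            raise ConfigurationError(f"mediation_scenarios has unknown keys {bad}")
        # betas must survive the additive shifts without clipping
        if self.delta_beta + 2 * self.meqtl_effect + self.ethnic_effect > 0.45:
            raise ConfigurationError(
                "delta_beta/meqtl_effect/ethnic_effect too large: betas would clip"
            )


@dataclass
class GroundTruth:
    true_cluster: pd.Series
    causal_cpg_ids: set
    meqtl_pairs: list  # (snp_id, cpg_id, per-allele effect)
    mediation_triplets: list  # (snp_id, cpg_id, scenario)
    ethnic_cpg_ids: set
    med_cpg_ids: set
    cell_factor_loadings: pd.DataFrame
    cell_factors: pd.DataFrame


@dataclass
class SyntheticCohort:
    criteria: CriteriaMatrix
    beta: BetaMatrix
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # sex, age, smoke, alcohol, ethnicity
    medications: pd.DataFrame  # samples x binary medications
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Global seed fanned out to per-component child streams by fixed offsets."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _beta_from_logit(mu: np.ndarray, eps: np.ndarray, noise_sd: float) -> np.ndarray:
    """Inverse-logit generation with delta-method-matched beta-scale noise."""
    mu = np.clip(mu, 0.02, 0.98)
    scale = noise_sd / (mu * (1.0 - mu))
    return expit(logit(mu) + eps * scale)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully labelled synthetic cohort (deterministic given seed)."""
    config.validate()
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    scen = config.mediation_scenarios
    scenarios = (
        ["causal"] * scen.get("causal", 0)
        + ["reactive"] * scen.get("reactive", 0)
        + ["independent"] * scen.get("independent", 0)
    )
    n_trip = len(scenarios)

    # ---- genomic layout -------------------------------------------------
    rng_pos = _rng(config.biology_seed, 11)
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    chroms = rng_pos.integers(1, 23, size=config.n_cpgs).astype(str)
    positions = rng_pos.integers(1_000_000, 120_000_000, size=config.n_cpgs)
    regions = rng_pos.choice(
        ["TSS200", "TSS1500", "5UTR", "Body", "3UTR"],
        size=config.n_cpgs,
        p=[0.15, 0.15, 0.1, 0.5, 0.1],
    )
    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "gene": [f"GENE{i // 4}" for i in range(config.n_cpgs)],
            "region": regions,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )

    # planted CpG classes occupy the front of the index space
    cluster_cpgs = cpg_ids[: config.n_cluster_cpgs]
    trip_cpgs = cpg_ids[config.n_cluster_cpgs : config.n_cluster_cpgs + n_trip]
    med_cpgs = cpg_ids[
        config.n_cluster_cpgs + n_trip : config.n_cluster_cpgs + n_trip + config.n_med_cpgs
    ]
    rng_eth_bio = _rng(config.biology_seed, 8)
    rng_eth = _rng(config.seed, 8)
    n_from_cluster = min(config.n_ethnic_cpgs // 2, len(cluster_cpgs))
    eth_from_cluster = list(
        rng_eth_bio.choice(cluster_cpgs, size=n_from_cluster, replace=False)
    )
    background = cpg_ids[config.n_cluster_cpgs + n_trip + config.n_med_cpgs :]
    eth_background = list(
        rng_eth_bio.choice(background, size=config.n_ethnic_cpgs - n_from_cluster, replace=False)
    )
    ethnic_cpgs = eth_from_cluster + eth_background

    # ---- genotypes ------------------------------------------------------
    rng_bio_geno = _rng(config.biology_seed, 3)
    rng_geno = _rng(config.seed, 3)
    snp_ids = [f"rs{i:06d}" for i in range(config.n_snps)]
    lo, hi = config.maf_range
    mafs = rng_bio_geno.uniform(lo, hi, size=config.n_snps)
    mafs[: config.n_meqtl] = config.meqtl_maf  # planted cis SNPs
    G = rng_geno.binomial(2, mafs[:, None], size=(config.n_snps, n)).astype(float)

    # cis SNPs sit near their target CpG; targets: mediation CpGs first,
    # then cluster CpGs cycled for the remaining pure meQTLs
    targets = list(trip_cpgs)
    pool = list(cluster_cpgs) if cluster_cpgs else list(background)
    i = 0
    while len(targets) < config.n_meqtl:
        targets.append(pool[i % len(pool)])
        i += 1
    snp_chrom = np.array([f"c" for _ in range(config.n_snps)], dtype=object)
    snp_pos = np.zeros(config.n_snps, dtype=int)
    for j, cpg in enumerate(targets):
        row = manifest.loc[cpg]
        snp_chrom[j] = row["chrom"]
        offset = int(rng_pos.integers(1_000, 100_000)) * int(rng_pos.choice([-1, 1]))
        snp_pos[j] = max(1, int(row["pos"]) + offset)
    for j in range(config.n_meqtl, config.n_snps):
        snp_chrom[j] = str(rng_pos.integers(1, 23))
        snp_pos[j] = int(rng_pos.integers(1_000_000, 120_000_000))
    snp_positions = pd.DataFrame(
        {"chrom": snp_chrom, "pos": snp_pos, "ref": "A", "alt": "G"},
        index=pd.Index(snp_ids, name="snp_id"),
    )

    # ---- mediation CpGs generated before the cluster label --------------
    rng_med = _rng(config.seed, 10)
    rng_noise = _rng(config.seed, 5)
    eps = rng_noise.standard_normal((config.n_cpgs, n))
    base = _rng(config.biology_seed, 4).uniform(0.15, 0.85, size=config.n_cpgs)
    cpg_index = {c: i for i, c in enumerate(cpg_ids)}
    beta_vals = np.empty((config.n_cpgs, n))
    trip_snp_ids = snp_ids[:n_trip]
    m_for_score = {}
    for t, (scenario, cpg) in enumerate(zip(scenarios, trip_cpgs)):
        gi = G[t]
        ci = cpg_index[cpg]
        if scenario in ("causal", "independent"):
            mu = base[ci] + config.meqtl_effect * gi
            beta_vals[ci] = _beta_from_logit(mu, eps[ci], config.noise_sd)
            if scenario == "causal":
                m = beta_vals[ci]
                m_for_score[t] = (m - m.mean()) / m.std()

    # ---- severity score and cluster assignment --------------------------
    rng_clu = _rng(config.seed, 1)
    score = rng_clu.standard_normal(n)
    for t, scenario in enumerate(scenarios):
        g_std = (G[t] - G[t].mean()) / max(G[t].std(), 1e-12)
        if scenario == "causal":
            score = score + config.mediation_y_weight * m_for_score[t]
        else:  # reactive and independent: direct G -> severity edge
            score = score + config.mediation_direct_weight * g_std
    order = np.argsort(np.argsort(score))  # ranks
    cuts = np.cumsum(config.cluster_proportions)[:-1]
    ycode = np.digitize(order / n, cuts)  # 0 = mildest ... k-1 = most severe
    cluster_names = ["M"] + [f"S{i}" for i in range(1, config.n_clusters)]
    true_cluster = pd.Series(
        [cluster_names[c] for c in ycode], index=sample_ids, name="true_cluster"
    )

    # ---- criteria -------------------------------------------------------
    rng_crit = _rng(config.seed, 2)
    prev = np.asarray(config.criterion_prevalence, dtype=float)
    crit = (rng_crit.random((n, config.n_criteria)) < prev[ycode]).astype(int)
    crit_cols = (
        DEFAULT_CRITERIA
        if config.n_criteria == len(DEFAULT_CRITERIA)
        else [f"crit{i}" for i in range(config.n_criteria)]
    )
    criteria = CriteriaMatrix(
        pd.DataFrame(crit, index=sample_ids, columns=crit_cols)
    )

    # ---- ethnicity ------------------------------------------------------
    groups = list(config.ethnicity_groups)
    comp = np.array([config.ethnicity_groups[g] for g in groups], dtype=float)
    comp = comp / comp.sum(axis=0)
    eth_idx = np.array(
        [rng_eth.choice(len(groups), p=comp[:, c]) for c in ycode]
    )
    ethnicity = pd.Series([groups[i] for i in eth_idx], index=sample_ids, name="ethnicity")

    # ---- nuisance structure ---------------------------------------------
    rng_cell_bio = _rng(config.biology_seed, 6)
    rng_cell = _rng(config.seed, 6)
    cell = rng_cell.standard_normal((n, config.n_cell_factors))
    if config.n_cell_factors > 0:
        cell[:, 0] += config.cell_cluster_shift * (ycode - ycode.mean())
    n_cell_cpgs = max(config.n_cpgs // 2, 1)
    cell_rows = rng_cell_bio.choice(config.n_cpgs, size=n_cell_cpgs, replace=False)
    loadings = np.zeros((config.n_cpgs, config.n_cell_factors))
    loadings[cell_rows] = rng_cell_bio.normal(
        0.0, config.cell_effect, size=(n_cell_cpgs, config.n_cell_factors)
    )

    # medication usage: three latent co-prescription axes, the first tied to
    # disease severity (immunosuppressant-like usage rises with cluster)
    rng_medi_bio = _rng(config.biology_seed, 7)
    rng_medi = _rng(config.seed, 7)
    med_base = rng_medi_bio.uniform(0.1, 0.4, size=config.n_medications)
    sev_std = (ycode - ycode.mean()) / max(ycode.std(), 1e-12)
    latent = np.column_stack(
        [0.4 * sev_std + rng_medi.standard_normal(n), rng_medi.standard_normal((n, 2))]
    )
    W = rng_medi_bio.normal(0.0, 1.2, size=(3, config.n_medications))
    med_logit = logit(med_base)[None, :] + latent @ W
    meds = (rng_medi.random((n, config.n_medications)) < expit(med_logit)).astype(int)
    medications = pd.DataFrame(
        meds, index=sample_ids, columns=[f"med{i}" for i in range(config.n_medications)]
    )

    # ---- methylation means ----------------------------------------------
    mu = np.repeat(base[:, None], n, axis=1)
    rng_pat = _rng(config.biology_seed, 12)
    patterns = np.array([[0, 0, 1.0], [0, 1.0, 1.0], [0, 0.5, 1.0]])
    for cpg in cluster_cpgs:
        ci = cpg_index[cpg]
        pat = patterns[rng_pat.integers(0, len(patterns))][:config.n_clusters]
        sign = rng_pat.choice([-1.0, 1.0])
        mu[ci] += sign * config.delta_beta * pat[ycode]
    meqtl_pairs = []
    for j in range(config.n_meqtl):
        ci = cpg_index[targets[j]]
        if j >= n_trip:  # pure meQTLs; mediation rows already carry their G term
            mu[ci] = mu[ci] + config.meqtl_effect * G[j]
        meqtl_pairs.append((snp_ids[j], targets[j], config.meqtl_effect))
    for t, (scenario, cpg) in enumerate(zip(scenarios, trip_cpgs)):
        if scenario == "reactive":  # M responds to the cluster, not to G
            ci = cpg_index[cpg]
            mu[ci] = base[ci] + config.delta_beta * (ycode - 1)
    eth_offsets = {}
    for cpg in ethnic_cpgs:
        ci = cpg_index[cpg]
        offs = rng_eth_bio.normal(0.0, config.ethnic_effect, size=len(groups))
        offs -= offs.mean()
        eth_offsets[cpg] = offs
        mu[ci] = mu[ci] + offs[eth_idx]
    if med_cpgs:
        # medication-driven CpGs respond to the most severity-linked drug so
        # the confounding path (cluster -> usage -> methylation) is real
        usage_corr = [
            abs(np.corrcoef(meds[:, m], ycode)[0, 1]) if meds[:, m].std() > 0 else 0.0
            for m in range(config.n_medications)
        ]
        driver = int(np.argmax(usage_corr))
        for cpg in med_cpgs:
            ci = cpg_index[cpg]
            mu[ci] = mu[ci] + config.med_effect * meds[:, driver]
    mu = mu + loadings @ cell.T  # cell factors act on the beta scale

    keep_rows = np.ones(config.n_cpgs, dtype=bool)
    for t, scenario in enumerate(scenarios):
        if scenario in ("causal", "independent"):
            keep_rows[cpg_index[trip_cpgs[t]]] = False  # generated earlier
    beta_vals[keep_rows] = _beta_from_logit(
        mu[keep_rows], eps[keep_rows], config.noise_sd
    )
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=cpg_ids, columns=sample_ids), manifest
    )

    # ---- genotype missingness -------------------------------------------
    if config.genotype_missing_rate > 0:
        mask = rng_geno.random(G.shape) < config.genotype_missing_rate
        G = np.where(mask, np.nan, G)
    genotypes = GenotypeMatrix(
        pd.DataFrame(G, index=snp_ids, columns=sample_ids), snp_positions
    )

    # ---- base covariates -------------------------------------------------
    rng_cov = _rng(config.seed, 9)
    covariates = pd.DataFrame(
        {
            "sex": rng_cov.binomial(1, 0.9, n),  # 1 = female; SLE is ~9:1
            "age": np.clip(rng_cov.normal(45, 12, n).round(), 18, 80),
            "smoke": rng_cov.binomial(1, 0.15, n),
            "alcohol": rng_cov.binomial(1, 0.4, n),
        },
        index=sample_ids,
    ).astype(float)
    covariates["ethnicity"] = ethnicity

    truth = GroundTruth(
        true_cluster=true_cluster,
        causal_cpg_ids=set(cluster_cpgs),
        meqtl_pairs=meqtl_pairs,
        mediation_triplets=[
            (trip_snp_ids[t], trip_cpgs[t], scenarios[t]) for t in range(n_trip)
        ],
        ethnic_cpg_ids=set(ethnic_cpgs),
        med_cpg_ids=set(med_cpgs),
        cell_factor_loadings=pd.DataFrame(
            loadings, index=cpg_ids,
            columns=[f"factor{i + 1}" for i in range(config.n_cell_factors)],
        ),
        cell_factors=pd.DataFrame(
            cell, index=sample_ids,
            columns=[f"factor{i + 1}" for i in range(config.n_cell_factors)],
        ),
    )
    return SyntheticCohort(criteria, beta, genotypes, covariates, medications, truth)


def simulate_mediation_triplets(
    n_per_scenario: int,
    effects: dict | None = None,
    n_samples: int = 500,
    seed: int = 0,
):
    """Standalone (G, M, Y) triplets under the three generative graphs.

    causal: G -> M -> Y; reactive: G -> Y -> M; independent: G -> M and
    G -> Y with M independent of Y given G.  M is continuous (unit residual
    SD), Y is the ordinal cluster code obtained by thresholding the latent
    outcome at its empirical tertiles, G is a Binomial(2, maf) dosage.
    Returns (list of {'G','M','Y'} dicts, list of scenario labels).
    """
    if n_per_scenario <= 0 or n_samples <= 0:
        raise ConfigurationError("n_per_scenario and n_samples must be positive")
    eff = {"g_on_m": 0.7, "m_on_y": 0.7, "g_on_y": 0.7, "y_on_m": 0.7, "maf": 0.3}
    if effects:
        eff.update(effects)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    data, labels = [], []

    def ordinalize(latent):
        qs = np.quantile(latent, [1 / 3, 2 / 3])
        return np.digitize(latent, qs).astype(float)

    for scenario in ("causal", "reactive", "independent"):
        for _ in range(n_per_scenario):
            G = rng.binomial(2, eff["maf"], n_samples).astype(float)
            if scenario == "causal":
                M = eff["g_on_m"] * G + rng.standard_normal(n_samples)
                Y = ordinalize(eff["m_on_y"] * M + rng.standard_normal(n_samples))
            elif scenario == "reactive":
                Y = ordinalize(eff["g_on_y"] * G + rng.standard_normal(n_samples))
                M = eff["y_on_m"] * Y + rng.standard_normal(n_samples)
            else:
                M = eff["g_on_m"] * G + rng.standard_normal(n_samples)
                Y = ordinalize(eff["g_on_y"] * G + rng.standard_normal(n_samples))
            data.append({"G": G, "M": M, "Y": Y})
            labels.append(scenario)
    return data, labels


def synthesize_detection_p(
    beta: BetaMatrix, n_failing_cpgs: int = 0, fail_fraction: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Uniform detection p-values with planted high-p failures.

    The first ``n_failing_cpgs`` CpGs fail detection (p > 0.05) in
    ``fail_fraction`` of samples; all other cells are Uniform(0, 0.05).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 14]))
    n_cpg, n_s = beta.values.shape
    det = rng.uniform(0.0, 0.05, size=(n_cpg, n_s))
    for i in range(min(n_failing_cpgs, n_cpg)):
        n_fail = int(np.ceil(fail_fraction * n_s))
        cols = rng.choice(n_s, size=n_fail, replace=False)
        det[i, cols] = rng.uniform(0.06, 1.0, size=n_fail)
    return pd.DataFrame(det, index=beta.cpg_ids, columns=beta.sample_ids)


def _write_vcf(genotypes: GenotypeMatrix, path: Path) -> None:
    """Minimal VCF v4.2 with GT genotypes (dosage = count of ALT allele)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    pos = genotypes.positions
    order = pos.sort_values(["chrom", "pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(pos["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for snp in order:
            row = pos.loc[snp]
            calls = [
                gt_map.get(v, "./.")
                for v in genotypes.values.loc[snp].to_numpy(dtype=float)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the standard plain-text fixture set; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "criteria": outdir / "criteria.tsv",
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "manifest.tsv",
        "vcf": outdir / "genotypes.vcf",
        "dosages": outdir / "dosages.tsv",
        "covariates": outdir / "covariates.tsv",
        "medications": outdir / "medications.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.criteria.values.to_csv(paths["criteria"], sep="\t", index_label="sample_id")
    cohort.beta.values.to_csv(paths["beta"], sep="\t", index_label="cpg_id")
    man = cohort.beta.manifest.rename(columns={"pos": "pos_1based"})
    man.to_csv(paths["manifest"], sep="\t", index_label="cpg_id")
    _write_vcf(cohort.genotypes, paths["vcf"])
    cohort.genotypes.values.to_csv(paths["dosages"], sep="\t", index_label="snp_id")
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index_label="sample_id")
    cohort.medications.to_csv(paths["medications"], sep="\t", index_label="sample_id")
    truth = cohort.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "true_cluster": truth.true_cluster.to_dict(),
                "causal_cpg_ids": sorted(truth.causal_cpg_ids),
                "meqtl_pairs": [list(p) for p in truth.meqtl_pairs],
                "mediation_triplets": [list(t) for t in truth.mediation_triplets],
                "ethnic_cpg_ids": sorted(truth.ethnic_cpg_ids),
                "med_cpg_ids": sorted(truth.med_cpg_ids),
            },
            fh,
            indent=1,
        )
    return paths
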