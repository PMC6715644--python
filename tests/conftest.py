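"""Shared fixtures: one default synthetic cohort and its derived stages.

Session scope keeps the expensive objects (cohort, covariates, association
scan, meQTL results) computed once and reused across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from slesubtypes import covariates as cov
from slesubtypes import meqtl as meqtl_mod
from slesubtypes import methylation
from slesubtypes.containers import ClusterAssignment, CovariateTable
from slesubtypes.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def true_assignment(cohort):
    return ClusterAssignment(
        labels=cohort.truth.true_cluster.rename("cluster"),
        severity_order=["M", "S1", "S2"],
    )


@pytest.fixture(scope="session")
def covariate_table(cohort):
    return cov.assemble_covariates(
        cohort.covariates,
        cov.medication_pca(cohort.medications, seed=1),
        cov.refactor_components(cohort.beta, k=6, t=500),
        cov.ancestry_pcs(cohort.genotypes, 3),
    )


@pytest.fixture(scope="session")
def dm_assoc(cohort, true_assignment, covariate_table):
    return methylation.cluster_anova(
        cohort.beta, true_assignment, covariate_table, fdr_threshold=0.1
    )


@pytest.fixture(scope="session")
def qc_genotypes(cohort):
    geno, _ = meqtl_mod.genotype_qc(cohort.genotypes)
    geno = geno.subset(geno.positions.sort_values(["chrom", "pos"]).index)
    return geno.subset(meqtl_mod.ld_prune(geno))


@pytest.fixture(scope="session")
def meqtl_results(cohort, qc_genotypes, covariate_table, dm_assoc):
    pairs = meqtl_mod.map_cis_pairs(
        qc_genotypes.positions, cohort.beta.manifest.loc[dm_assoc.significant]
    )
    return meqtl_mod.fit_meqtl(
        cohort.beta, qc_genotypes, covariate_table, pairs, fdr_threshold=0.05
    )


@pytest.fixture()
def small_beta():
    """Tiny deterministic beta matrix for exact-value tests."""
    rng = np.random.default_rng(0)
    n_cpg, n_s = 8, 12
    ids = [f"cg{i:03d}" for i in range(n_cpg)]
    samples = [f"s{i}" for i in range(n_s)]
    manifest = pd.DataFrame(
        {
            "chrom": ["1", "2", "3", "X", "4", "5", "6", "chr7"],
            "pos": rng.integers(1_000, 9_000_000, n_cpg),
            "gene": [f"G{i}" for i in range(n_cpg)],
            "region": "Body",
        },
        index=pd.Index(ids, name="cpg_id"),
    )
    values = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n_cpg, n_s)), index=ids, columns=samples
    )
    from slesubtypes.containers import BetaMatrix

    return BetaMatrix(values, manifest)


@pytest.fixture()
def small_covariates():
    rng = np.random.default_rng(1)
    n = 12
    return CovariateTable(
        pd.DataFrame(
            {
                "sex": rng.integers(0, 2, n).astype(float),
                "age": rng.uniform(20, 70, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
    )
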