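"""Genotype QC, HWE exact test, LD pruning, cis pairing, meQTL fits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slesubtypes import meqtl
from slesubtypes.containers import BetaMatrix, CovariateTable, GenotypeMatrix


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration of all heterozygote configurations
    with the observed allele counts (rational arithmetic via math.comb)."""
    from math import comb

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_b = n - het - hom_a
        if hom_a < 0 or hom_b < 0:
            continue
        # multinomial genotype count / binomial allele count, times 2^het
        num = comb(n, hom_a) * comb(n - hom_a, het) * 2**het
        den = comb(2 * n, n_a)
        probs[het] = num / den
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


def _geno(G, chrom="1", pos=None):
    n_snp = G.shape[0]
    ids = [f"rs{i}" for i in range(n_snp)]
    pos = np.arange(1, n_snp + 1) * 100 if pos is None else pos
    meta = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}, index=ids)
    cols = [f"s{i}" for i in range(G.shape[1])]
    return GenotypeMatrix(pd.DataFrame(G.astype(float), index=ids, columns=cols), meta)


class TestHWE:
    def test_specific_counts_vs_enumeration(self):
        assert meqtl.hwe_exact_test(5, 4, 1) == pytest.approx(
            hwe_enumeration_oracle(5, 4, 1), abs=1e-12
        )

    def test_all_totals_up_to_50(self):
        """Exhaustive agreement with the enumeration oracle for all
        genotype-count triples with total <= 50 (coarse grid)."""
        for n in range(1, 51, 7):
            for n_aa in range(0, n + 1, 5):
                for n_ab in range(0, n - n_aa + 1, 3):
                    n_bb = n - n_aa - n_ab
                    got = meqtl.hwe_exact_test(n_aa, n_ab, n_bb)
                    exp = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(exp, abs=1e-10)

    def test_single_configuration_p_one(self):
        assert meqtl.hwe_exact_test(10, 0, 0) == 1.0

    def test_hwe_consistent_counts_large(self):
        # 0.4/0.6 allele freqs at HWE proportions, n=1000
        p = meqtl.hwe_exact_test(360, 480, 160)
        assert 0.5 < p <= 1.0 and np.isfinite(p)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            meqtl.hwe_exact_test(-1, 2, 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_property_matches_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert meqtl.hwe_exact_test(a, b, c) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), abs=1e-10
        )


class TestGenotypeQC:
    def test_maf_exactly_5_percent_removed(self):
        rng = np.random.default_rng(0)
        n = 100
        # SNP0: MAF exactly 0.05 (10 minor alleles in 200)
        row0 = np.zeros(n)
        row0[:10] = 1
        row1 = rng.binomial(2, 0.3, n)
        geno = _geno(np.vstack([row0, row1]))
        kept, report = meqtl.genotype_qc(geno)
        assert "rs0" not in kept.snp_ids and "rs1" in kept.snp_ids
        assert report.removed_maf == 1

    def test_six_percent_missing_removed(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.3, (2, 100)).astype(float)
        G[0, :6] = np.nan
        kept, report = meqtl.genotype_qc(_geno(G))
        assert "rs0" not in kept.snp_ids
        assert report.removed_call_rate == 1

    def test_monomorphic_removed_at_maf_step(self):
        rng = np.random.default_rng(2)
        G = np.vstack([np.zeros(50), rng.binomial(2, 0.4, 50)])
        kept, report = meqtl.genotype_qc(_geno(G))
        assert report.removed_maf == 1 and "rs1" in kept.snp_ids

    def test_hwe_violation_removed(self):
        # all heterozygotes: extreme HWE deviation
        G = np.vstack([np.ones(100), np.random.default_rng(3).binomial(2, 0.4, 100)])
        kept, report = meqtl.genotype_qc(_geno(G))
        assert report.removed_hwe == 1

    def test_idempotent(self, cohort):
        once, _ = meqtl.genotype_qc(cohort.genotypes)
        twice, rep = meqtl.genotype_qc(once)
        assert rep.removed_call_rate == rep.removed_maf == rep.removed_hwe == 0
        assert once.snp_ids == twice.snp_ids

    def test_all_removed_errors(self):
        G = np.zeros((3, 40))
        with pytest.raises(ValueError):
            meqtl.genotype_qc(_geno(G))


class TestLDPrune:
    def test_identical_snps_keep_one(self):
        rng = np.random.default_rng(4)
        row = rng.binomial(2, 0.4, 80)
        G = np.vstack([row, row, rng.binomial(2, 0.4, 80)])
        kept = meqtl.ld_prune(_geno(G))
        assert kept.count("rs0") + kept.count("rs1") == 1
        assert "rs0" in kept  # earlier position wins
        assert "rs2" in kept

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.4, (20, 300))
        assert len(meqtl.ld_prune(_geno(G))) == 20

    def test_postcondition_bruteforce_200_snps(self):
        """After pruning, no within-window retained pair exceeds r^2 = 0.8."""
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.4, (40, 120)).astype(float)
        # blocks of correlated SNPs: children copy a parent with small flips
        rows = []
        for b in range(40):
            rows.append(base[b])
            for _ in range(4):
                child = base[b].copy()
                flip = rng.random(120) < 0.05
                child[flip] = rng.binomial(2, 0.4, flip.sum())
                rows.append(child)
        G = np.vstack(rows)  # 200 SNPs
        geno = _geno(G)
        kept = meqtl.ld_prune(geno, r2_max=0.8, window=50, step=5)
        kept_geno = geno.values.loc[kept].to_numpy()
        order = {s: i for i, s in enumerate(kept)}
        for i, j in itertools.combinations(range(len(kept)), 2):
            if j - i < 50:  # same window reach
                r = np.corrcoef(kept_geno[i], kept_geno[j])[0, 1]
                assert r**2 <= 0.8 + 1e-9

    def test_unsorted_positions_error(self):
        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.4, (3, 40))
        geno = _geno(G, pos=[300, 100, 200])
        with pytest.raises(ValueError):
            meqtl.ld_prune(geno)


class TestCisPairs:
    def _pos(self, rows, what="snp"):
        return pd.DataFrame(rows, columns=["chrom", "pos"],
                            index=[f"{what}{i}" for i in range(len(rows))])

    def test_strict_window(self):
        snp = self._pos([["1", 1_000_000]])
        cpg = self._pos([["1", 1_999_999], ["1", 2_000_000]], what="cg")
        pairs = meqtl.map_cis_pairs(snp, cpg)
        assert len(pairs) == 1
        assert pairs.iloc[0]["cpg_id"] == "cg0"
        assert pairs.iloc[0]["distance"] == 999_999

    def test_different_chromosomes_unpaired(self):
        pairs = meqtl.map_cis_pairs(
            self._pos([["2", 500]]), self._pos([["1", 600]], what="cg")
        )
        assert pairs.empty

    def test_chr_prefix_normalized(self):
        pairs = meqtl.map_cis_pairs(
            self._pos([["chr1", 500]]), self._pos([["1", 600]], what="cg")
        )
        assert len(pairs) == 1 and pairs.iloc[0]["distance"] == 100


class TestFitMeqtl:
    def test_matches_statsmodels_oracle_12_samples(self, small_beta, small_covariates):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.4, (3, 12)).astype(float)
        geno = _geno(G)
        geno.values.columns = small_beta.sample_ids
        pairs = pd.DataFrame(
            {"snp_id": ["rs0", "rs1", "rs2"], "cpg_id": small_beta.cpg_ids[:3],
             "distance": [10, 20, 30]}
        )
        res = meqtl.fit_meqtl(small_beta, geno, small_covariates, pairs)
        X_cov = sm.add_constant(small_covariates.values[["sex", "age"]].astype(float))
        for _, row in res.iterrows():
            y = small_beta.values.loc[row["cpg_id"]].to_numpy()
            g = geno.values.loc[row["snp_id"]].to_numpy()
            X = np.column_stack([X_cov.to_numpy(), g])
            fit = sm.OLS(y, X).fit()
            assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-8)
            assert row["se"] == pytest.approx(fit.bse[-1], abs=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_permuted_genotypes_null_rate(self, cohort, covariate_table, qc_genotypes, dm_assoc):
        """Shuffling sample labels of the genotypes kills the signal."""
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(cohort.beta.sample_ids))
        shuffled = GenotypeMatrix(
            pd.DataFrame(
                qc_genotypes.values.to_numpy()[:, perm],
                index=qc_genotypes.snp_ids, columns=qc_genotypes.sample_ids,
            ),
            qc_genotypes.positions,
        )
        pairs = meqtl.map_cis_pairs(
            shuffled.positions, cohort.beta.manifest.loc[dm_assoc.significant]
        )
        res = meqtl.fit_meqtl(cohort.beta, shuffled, covariate_table, pairs)
        assert res["significant"].mean() < 0.1

    def test_pairs_referencing_filtered_features_skipped(self, small_beta, small_covariates):
        rng = np.random.default_rng(10)
        geno = _geno(rng.binomial(2, 0.4, (2, 12)))
        geno.values.columns = small_beta.sample_ids
        pairs = pd.DataFrame(
            {"snp_id": ["rs0", "rs_gone"], "cpg_id": [small_beta.cpg_ids[0], "cg_gone"],
             "distance": [5, 5]}
        )
        res = meqtl.fit_meqtl(small_beta, geno, small_covariates, pairs)
        assert len(res) == 1


class TestDistanceDecay:
    def test_constructed_monotone_profile(self, meqtl_results):
        """Planted effects sit < 100 kb, so the significant fraction decays
        with distance."""
        prof = meqtl.distance_decay(
            meqtl_results, bin_edges=[0, 100_000, 1_000_000]
        )
        frac = prof["significant_fraction"].to_numpy()
        assert frac[0] > frac[1]

    def test_null_flat_profile(self):
        rng = np.random.default_rng(11)
        res = pd.DataFrame(
            {"distance": rng.integers(0, 1_000_000, 4000),
             "significant": rng.random(4000) < 0.05}
        )
        prof = meqtl.distance_decay(res, bin_edges=[0, 250_000, 500_000, 750_000, 1_000_000])
        assert prof["significant_fraction"].max() - prof["significant_fraction"].min() < 0.04

    def test_single_bin_and_empty_bin(self):
        res = pd.DataFrame({"distance": [10, 20], "significant": [True, False]})
        prof = meqtl.distance_decay(res, bin_edges=[0, 100])
        assert prof.iloc[0]["significant_fraction"] == 0.5
        prof2 = meqtl.distance_decay(res, bin_edges=[0, 100, 200])
        assert np.isnan(prof2.iloc[1]["significant_fraction"])
        with pytest.raises(ValueError):
            meqtl.distance_decay(res.iloc[:0], bin_edges=[0, 100])
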