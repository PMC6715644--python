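"""MCA, dimension selection, K-means, bootstrap stability, severity order."""

import numpy as np
import pandas as pd
import pytest

from slesubtypes import clustering
from slesubtypes.containers import ClusterAssignment, CriteriaMatrix
from slesubtypes.simulate import SimulationConfig, simulate_cohort


def _criteria(X):
    return CriteriaMatrix(
        pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(X.shape[0])],
            columns=[f"c{j}" for j in range(X.shape[1])],
        )
    )


def mca_oracle(X):
    """Brute-force correspondence analysis of the indicator table: explicit
    standardized-residual matrix and eigendecomposition, element by element."""
    n, Q = X.shape
    Z = np.zeros((n, 2 * Q))
    for i in range(n):
        for j in range(Q):
            Z[i, 2 * j] = X[i, j]
            Z[i, 2 * j + 1] = 1 - X[i, j]
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.zeros_like(P)
    for i in range(n):
        for j in range(2 * Q):
            S[i, j] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    F = np.diag(1 / np.sqrt(r)) @ U @ np.diag(s)
    return F, s**2


class TestMCA:
    def test_matches_bruteforce_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (25, 6))
        X[:, 0] = np.concatenate([np.ones(13), np.zeros(12)])  # ensure variation
        res = clustering.mca(_criteria(X))
        F_o, ev_o = mca_oracle(X.astype(float))
        k = res.coordinates.shape[1]
        np.testing.assert_allclose(res.eigenvalues, ev_o[:k], atol=1e-8)
        for d in range(k):
            got = res.coordinates.iloc[:, d].to_numpy()
            exp = F_o[:, d]
            assert np.allclose(got, exp, atol=1e-8) or np.allclose(got, -exp, atol=1e-8)

    def test_total_inertia_closed_form(self, cohort):
        """For Q complete binary variables total inertia = (2Q/Q) - 1 = 1."""
        res = clustering.mca(cohort.criteria)
        assert res.total_inertia == pytest.approx(1.0, abs=1e-12)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, (30, 5))
        res = clustering.mca(_criteria(X))
        perm = rng.permutation(30)
        res_p = clustering.mca(_criteria(X[perm]))
        a = res.coordinates.to_numpy()[perm]
        b = res_p.coordinates.to_numpy()
        for d in range(a.shape[1]):
            assert np.allclose(a[:, d], b[:, d], atol=1e-10) or np.allclose(
                a[:, d], -b[:, d], atol=1e-10
            )

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            clustering.mca(_criteria(np.ones((10, 4), dtype=int)))
        with pytest.raises(ValueError):
            clustering.mca(_criteria(np.zeros((1, 4), dtype=int)))


class TestDichotomize:
    def test_mapping_and_exclusion(self):
        raw = pd.DataFrame(
            {"rash": ["present", "absent", "weird"], "renal": ["yes", "no", "yes"]},
            index=["a", "b", "c"],
        )
        rules = {"rash": {"present": 1, "absent": 0}, "renal": {"yes": 1, "no": 0}}
        out = clustering.dichotomize_criteria(raw, rules)
        assert list(out.sample_ids) == ["a", "b"]  # 'weird' unmapped -> excluded
        assert out.values.loc["a", "rash"] == 1

    def test_missing_rule_errors(self):
        raw = pd.DataFrame({"rash": ["present"]})
        with pytest.raises(ValueError, match="rash"):
            clustering.dichotomize_criteria(raw, {})

    def test_zero_variance_column_retained_flagged(self):
        raw = pd.DataFrame({"a": ["y", "y"], "b": ["y", "n"]})
        rules = {"a": {"y": 1, "n": 0}, "b": {"y": 1, "n": 0}}
        out = clustering.dichotomize_criteria(raw, rules)
        assert "a" in out.criterion_names
        assert out.zero_variance_criteria() == ["a"]


class TestSelectDimensions:
    def test_recovers_two_latent_dimensions(self):
        rng = np.random.default_rng(0)
        n, Q = 300, 12
        A = rng.normal(0, 1.6, (n, 2))
        B = rng.normal(0, 1, (2, Q))
        X = (rng.random((n, Q)) < 1 / (1 + np.exp(-(A @ B)))).astype(int)
        assert clustering.select_dimensions(_criteria(X), max_dim=5, seed=0) == 2

    def test_pure_noise_returns_minimum(self):
        rng = np.random.default_rng(1)
        X = (rng.random((300, 12)) < 0.5).astype(int)
        assert clustering.select_dimensions(_criteria(X), max_dim=5, seed=0) == 1

    def test_invalid_folds_error(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (30, 6))
        with pytest.raises(ValueError):
            clustering.select_dimensions(_criteria(X), max_dim=3, n_folds=1)


class TestKMeans:
    def test_two_point_masses_exact(self):
        pts = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 5])
        coords = pd.DataFrame(pts, index=[f"s{i}" for i in range(20)])
        a = clustering.kmeans_cluster(coords, k=2, seed=0)
        lab = a.labels.to_numpy()
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
        assert lab[0] != lab[-1]

    def test_k_equals_n(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.normal(size=(6, 2)), index=[f"s{i}" for i in range(6)])
        a = clustering.kmeans_cluster(coords, k=6, seed=0)
        assert a.labels.nunique() == 6

    def test_k_too_large_errors(self):
        coords = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            clustering.kmeans_cluster(coords, k=4)


class TestBootstrapStability:
    @pytest.fixture(scope="class")
    @staticmethod
    def separated():
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        pts = np.vstack([c + rng.normal(0, 0.3, (40, 2)) for c in centers])
        return pd.DataFrame(pts, index=[f"s{i}" for i in range(120)])

    def test_selects_k3_with_high_jaccard(self, separated):
        prof = clustering.bootstrap_stability(separated, [2, 3, 4], n_bootstrap=100, seed=0)
        assert prof.selected_k == 3
        assert np.all(prof.per_cluster_jaccard[3] >= 0.95)
        assert prof.passes_threshold(3)  # the > 0.82 retention rule

    def test_label_noise_decreases_stability(self, separated):
        """Monotonicity: blurring well-separated data lowers mean Jaccard."""
        rng = np.random.default_rng(7)
        base = clustering.bootstrap_stability(separated, [3], n_bootstrap=40, seed=1)
        noisy1 = separated + rng.normal(0, 2.0, separated.shape)
        noisy2 = separated + rng.normal(0, 4.0, separated.shape)
        p1 = clustering.bootstrap_stability(noisy1, [3], n_bootstrap=40, seed=1)
        p2 = clustering.bootstrap_stability(noisy2, [3], n_bootstrap=40, seed=1)
        m0, m1, m2 = (
            p.per_cluster_jaccard[3].mean() for p in (base, p1, p2)
        )
        assert m0 > m1 > m2

    def test_invalid_inputs(self, separated):
        with pytest.raises(ValueError):
            clustering.bootstrap_stability(separated, [], n_bootstrap=50)
        with pytest.raises(ValueError):
            clustering.bootstrap_stability(separated, [2], n_bootstrap=5)


class TestSeverityOrder:
    def test_lowest_count_is_m_and_reported_severity_order(self, cohort):
        res = clustering.mca(cohort.criteria)
        a = clustering.kmeans_cluster(res.coordinates.iloc[:, :2], 3, seed=0)
        ordered = clustering.order_clusters_by_severity(a, cohort.criteria)
        assert ordered.severity_order == ["M", "S1", "S2"]
        counts = cohort.criteria.values.sum(axis=1).groupby(ordered.labels).mean()
        assert counts["M"] == counts.min() and counts["S2"] == counts.max()

    def test_supplied_severity_column(self, cohort):
        """Severity-index means ordered as in the study (5.6 < 7.39 <= 7.41)."""
        res = clustering.mca(cohort.criteria)
        a = clustering.kmeans_cluster(res.coordinates.iloc[:, :2], 3, seed=0)
        index_map = {"M": 5.6, "S1": 7.39, "S2": 7.41}
        first = clustering.order_clusters_by_severity(a, cohort.criteria)
        sev = first.labels.map(index_map)
        again = clustering.order_clusters_by_severity(a, cohort.criteria, severity_column=sev)
        assert (first.labels == again.labels).all()

    def test_k1_identity(self):
        crit = _criteria(np.array([[0, 1], [1, 0], [1, 1]]))
        a = ClusterAssignment(
            labels=pd.Series(["C0"] * 3, index=crit.sample_ids, name="cluster")
        )
        out = clustering.order_clusters_by_severity(a, crit)
        assert set(out.labels) == {"M"}


def test_cluster_recovery_on_separable_world():
    """The full MCA + K-means path recovers truth (ARI > 0.9) when cluster
    prevalences are separable (criterion log-odds doubled)."""
    from sklearn.metrics import adjusted_rand_score
    from scipy.special import expit, logit

    from slesubtypes.simulate import DEFAULT_PREVALENCE

    sharp = expit(2.0 * logit(DEFAULT_PREVALENCE))
    cfg = SimulationConfig(seed=4, criterion_prevalence=sharp, n_cpgs=60,
                           n_cluster_cpgs=5, n_snps=60, n_meqtl=20, n_ethnic_cpgs=5)
    c = simulate_cohort(cfg)
    res = clustering.mca(c.criteria)
    a = clustering.kmeans_cluster(res.coordinates.iloc[:, :2], 3, seed=4)
    assert adjusted_rand_score(c.truth.true_cluster, a.labels) > 0.9
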