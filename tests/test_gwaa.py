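import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pleiolink.gwaa import (
    GenotypeSample,
    ScanResult,
    compute_grm,
    discovery_metrics,
    fit_null_mvlmm,
    multivariate_scan,
    storey_qvalues,
    univariate_scan,
)


def _random_sample(rng, n=120, M=60, beta=None, causal_col=0, rho_e=0.0):
    """Synthetic unstructured sample: binomial genotypes, Gaussian traits."""
    p = rng.uniform(0.1, 0.5, M)
    G = rng.binomial(2, p, size=(n, M)).astype(np.int8)
    cov = np.array([[1.0, rho_e], [rho_e, 1.0]])
    Y = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    if beta is not None:
        Y += np.outer(G[:, causal_col], beta)
    marker_map = pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(M)],
            "chrom": np.zeros(M, dtype=int),
            "cM": np.linspace(0, 0.1, M),
            "role": "neutral",
        }
    )
    truth = pd.DataFrame(
        {"id": ["Q0"], "chrom": [0], "cM": [marker_map["cM"][causal_col]],
         "role": ["qtl_pleio"], "segregating": [True]}
    )
    return GenotypeSample(G, Y, marker_map, truth)


class TestGRM:
    def test_constant_genotypes_zero_matrix(self):
        G = np.full((5, 10), 1)
        G[:, 0] = [0, 1, 2, 1, 0]  # one informative marker to pass MAF
        K = compute_grm(G)
        assert K.shape == (5, 5)
        assert np.allclose(K, K.T)

    def test_two_individual_hand_case(self):
        K = compute_grm(np.array([[0], [2]]))
        assert np.allclose(K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_brute_force_equivalence(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 500)).astype(float)
        K = compute_grm(G, maf=0.001)
        f = G.mean(axis=0) / 2
        use = np.minimum(f, 1 - f) >= 0.001
        Xc = G[:, use] - G[:, use].mean(axis=0)
        K_direct = sum(np.outer(Xc[:, j], Xc[:, j]) for j in range(Xc.shape[1]))
        K_direct /= use.sum()
        assert np.allclose(K, K_direct)
        assert np.mean(np.diag(K)) == pytest.approx(Xc.var(axis=0).sum() / use.sum(), rel=0.05)

    def test_all_filtered_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(np.zeros((10, 5)))


class TestUnivariateScan:
    def test_pvalues_match_pearson_t_oracle(self, rng):
        sample = _random_sample(rng)
        res = univariate_scan(sample, 1)
        y = sample.phenotypes[:, 0]
        for j in [0, 7, 33]:
            g = sample.genotypes[:, j].astype(float)
            _, p_oracle = stats.pearsonr(g, y)
            row = res.table.iloc[j]
            assert row["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_perfect_signal_significant(self, rng):
        sample = _random_sample(rng)
        sample.phenotypes[:, 0] = sample.genotypes[:, 3].astype(float)
        res = univariate_scan(sample, 1)
        assert bool(res.table.iloc[3]["significant"])
        assert res.table.iloc[3]["p"] < 1e-50

    def test_bh_hand_computation(self):
        p = np.array([0.001, 0.02, 0.04, 0.05])
        _, adj, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        assert np.allclose(adj, [0.004, 0.04, 0.05, 0.05])

    def test_null_fdr_control(self, rng):
        """Permuted phenotypes: false-discovery proportion is controlled."""
        fdps = []
        for _ in range(40):
            sample = _random_sample(rng, n=80, M=100)
            res = univariate_scan(sample, 2, fdr=0.1)
            nsig = int(res.table["significant"].sum())
            fdps.append(nsig / max(nsig, 1) if nsig else 0.0)
        assert np.mean(fdps) <= 0.1 + 0.05

    def test_monomorphic_marker_skipped_with_reason(self, rng):
        sample = _random_sample(rng, M=10)
        sample.genotypes[:, 4] = 0
        res = univariate_scan(sample, 1)
        row = res.table.iloc[4]
        assert not row["significant"]
        assert row["reason"] == "maf_below_threshold"
        assert np.isnan(row["p"])


class TestStoreyQvalues:
    def test_all_ones(self):
        assert np.all(storey_qvalues(np.ones(50)) == 1.0)

    def test_pi0_one_equals_bh(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh, atol=1e-12)

    def test_uniform_null_pi0_near_one(self, rng):
        p = rng.uniform(size=10_000)
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
        pi0 = np.polyval(np.polyfit(lam, pi0_lam, 3), lam.max())
        assert 0.9 <= min(pi0, 1.0) <= 1.0
        q = storey_qvalues(p)
        assert np.all(q <= 1.0)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            storey_qvalues([])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestMultivariateScan:
    def test_matches_fixed_covariance_ols_oracle(self, rng):
        """With K = 0 the mixed model collapses onto bivariate GLS.

        Oracle: per-marker stacked weighted least squares with the same
        null residual covariance, built without the eigen-rotation path.
        """
        sample = _random_sample(rng, n=80, M=30, beta=(0.4, 0.3), rho_e=0.3)
        K = np.zeros((80, 80))
        res = multivariate_scan(sample, K, fdr=0.1)
        Vg, Ve = res.vg, res.ve
        W = np.linalg.inv(Ve)
        Y = sample.phenotypes
        n = Y.shape[0]
        for j in [0, 5, 17]:
            g = sample.genotypes[:, j].astype(float)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([np.ones(n), g])

            def gls_rss(X):
                XtWX = np.kron(X.T @ X, W)
                XtWy = (X.T @ Y @ W).reshape(-1)
                beta = np.linalg.solve(XtWX, XtWy)
                R = Y - X @ beta.reshape(X.shape[1], 2)
                return np.einsum("ia,ab,ib->", R, W, R)

            lrt_oracle = gls_rss(X0) - gls_rss(X1)
            assert res.table.iloc[j]["stat"] == pytest.approx(lrt_oracle, abs=1e-6)

    def test_null_pvalues_uniform(self, rng):
        sample = _random_sample(rng, n=150, M=400, rho_e=0.5)
        K = compute_grm(sample.genotypes)
        res = multivariate_scan(sample, K)
        p = res.table["p"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_joint_test_beats_univariate_on_shared_effect(self, rng):
        """A marker moving both traits: joint LRT outranks each 1-df scan."""
        hits_multi, hits_uni = 0, 0
        for _ in range(10):
            sample = _random_sample(rng, n=100, M=50, beta=(0.25, 0.25))
            K = np.zeros((100, 100))
            multi = multivariate_scan(sample, K)
            u1 = univariate_scan(sample, 1)
            chi2_multi = multi.table.iloc[0]["stat"]
            t = u1.table.iloc[0]["stat"]
            hits_multi += chi2_multi
            hits_uni += t**2
        assert hits_multi > hits_uni  # 2-trait signal accumulates

    def test_non_psd_kinship_rejected(self, rng):
        sample = _random_sample(rng, n=20, M=10)
        K = -np.eye(20)
        with pytest.raises(ValueError):
            multivariate_scan(sample, K)

    def test_reml_recovers_residual_covariance(self, rng):
        """K=0: REML Ve should approximate the true trait covariance."""
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        Y = rng.multivariate_normal([0, 0], cov, size=400)
        Vg, Ve, _, _, _ = fit_null_mvlmm(Y, np.zeros((400, 400)))
        # with K = 0 only the residual component is identified
        assert np.allclose(Ve, np.cov(Y.T), atol=0.35)


class TestDiscoveryMetrics:
    def _scan(self, sig_markers, trait=None, kind="multivariate", extra=()):
        rows = []
        for name, chrom, cM in list(sig_markers) + list(extra):
            rows.append((name, chrom, cM, "neutral", True))
        tab = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "role", "significant"])
        if not len(tab):
            tab = pd.DataFrame(columns=["marker", "chrom", "cM", "role", "significant"])
        return ScanResult(tab, kind, 0.1, trait=trait)

    def _truth(self, rows):
        return pd.DataFrame(rows, columns=["id", "chrom", "cM", "role", "segregating"])

    def test_no_significant_markers(self):
        truth = self._truth([("Q1", 0, 0.05, "qtn_pleio", True)])
        s1 = self._scan([], trait=1, kind="univariate")
        s2 = self._scan([], trait=2, kind="univariate")
        rep = discovery_metrics((s1, s2), truth)
        assert rep.dr_pleio == 0.0
        assert rep.fnr == 1.0

    def test_window_arithmetic_half_discovered(self):
        truth = self._truth(
            [("Q1", 0, 0.5, "qtl_pleio", True), ("Q2", 1, 0.5, "qtl_pleio", True)]
        )
        scan = self._scan([("M1", 0, 0.54)])  # 0.04 cM from Q1 only
        rep = discovery_metrics(scan, truth, window_cM=0.05)
        assert rep.dr == 0.5

    def test_window_boundary_excluded(self):
        truth = self._truth([("Q1", 0, 0.5, "qtl_pleio", True)])
        scan = self._scan([("M1", 0, 0.56)])  # 0.06 cM away
        rep = discovery_metrics(scan, truth, window_cM=0.05)
        assert rep.dr == 0.0

    def test_same_chromosome_required(self):
        truth = self._truth([("Q1", 2, 0.5, "qtl_pleio", True)])
        scan = self._scan([("M1", 0, 0.5)])
        assert discovery_metrics(scan, truth).dr == 0.0

    def test_univariate_pair_requires_both(self):
        truth = self._truth([("Q1", 0, 0.5, "qtl_pleio", True)])
        s1 = self._scan([("M1", 0, 0.5)], trait=1, kind="univariate")
        s2 = self._scan([], trait=2, kind="univariate")
        rep = discovery_metrics((s1, s2), truth)
        assert rep.dr_pleio == 0.0
        assert rep.dr_single == 0.5
        assert rep.snp_sig == 0.5
        assert rep.snp_pleio == 0.0

    def test_qtn_fpr_fnr(self):
        truth = self._truth(
            [
                ("Q1", 0, 0.0, "qtn_trait1", True),
                ("Q2", 1, 0.0, "qtn_trait2", True),
                ("Q3", 2, 0.0, "qtn_pleio", True),
                ("Q4", 3, 0.0, "qtn_pleio", False),  # not segregating: excluded
            ]
        )
        # Q1 significant in both scans (spurious pleiotropy), Q3 missed in scan 2
        s1 = self._scan([("Q1", 0, 0.0), ("Q3", 2, 0.0)], trait=1, kind="univariate")
        s2 = self._scan([("Q1", 0, 0.0)], trait=2, kind="univariate")
        rep = discovery_metrics((s1, s2), truth)
        assert rep.fpr == 0.5  # Q1 of {Q1, Q2}
        assert rep.fnr == 1.0  # Q3 (only segregating pleiotropic QTN) missed

    def test_trait_relabeling_symmetry(self):
        truth = self._truth([("Q1", 0, 0.5, "qtl_pleio", True)])
        s1 = self._scan([("M1", 0, 0.5)], trait=1, kind="univariate")
        s2 = self._scan([("M2", 0, 0.52)], trait=2, kind="univariate")
        r12 = discovery_metrics((s1, s2), truth)
        s1b = self._scan([("M2", 0, 0.52)], trait=1, kind="univariate")
        s2b = self._scan([("M1", 0, 0.5)], trait=2, kind="univariate")
        r21 = discovery_metrics((s1b, s2b), truth)
        assert r12.dr_pleio == r21.dr_pleio
        assert r12.dr_single == r21.dr_single
        assert r12.snp_sig == r21.snp_sig

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            discovery_metrics(self._scan([]), pd.DataFrame())
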