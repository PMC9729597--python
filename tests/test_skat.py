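"""Kinship estimation, PCA, mixed-model null, and the kernel score test."""

import math

import numpy as np
import pytest
from scipy import stats

from pedseg.skat import (
    beta_weights,
    compute_kinship,
    davies_pvalue,
    fit_null_emmax,
    liu_pvalue,
    run_association,
    run_pca,
    skat_test,
)
from pedseg.simulate import simulate_null_family_cohort


class TestComputeKinship:
    def test_unrelated_offdiagonal_near_zero(self):
        rng = np.random.default_rng(0)
        n, m = 60, 1000
        p = rng.uniform(0.1, 0.9, m)
        G = rng.binomial(2, p[None, :].repeat(n, axis=0))
        K = compute_kinship(G).values
        off = K[np.triu_indices(n, 1)]
        assert abs(off.mean()) < 3 / math.sqrt(m)
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)

    def test_parent_offspring_relatedness_half(self):
        rng = np.random.default_rng(1)
        n_pairs, m = 150, 2000
        p = rng.uniform(0.1, 0.9, m)
        parent = rng.binomial(2, p[None].repeat(n_pairs, 0))
        transmitted = np.where(
            parent == 2, 1, np.where(parent == 0, 0, rng.integers(0, 2, parent.shape))
        )
        child = transmitted + rng.binomial(1, p[None].repeat(n_pairs, 0))
        G = np.empty((2 * n_pairs, m))
        G[0::2], G[1::2] = parent, child
        K = compute_kinship(G).values
        rel = np.array([K[2 * i, 2 * i + 1] for i in range(n_pairs)])
        assert rel.mean() == pytest.approx(0.5, abs=0.05)

    def test_duplicate_columns_give_diagonal_entry(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.3, size=(30, 500))
        G2 = np.vstack([G, G[:1]])  # sample 30 duplicates sample 0
        K = compute_kinship(G2).values
        assert K[0, 30] == pytest.approx(K[0, 0], rel=1e-9)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            compute_kinship(np.zeros((10, 5)))

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.4, size=(50, 400)).astype(float)
        G_miss = G.copy()
        G_miss[rng.random(G.shape) < 0.05] = -1
        K = compute_kinship(G_miss, min_maf=0.05).values
        assert np.isfinite(K).all()


class TestRunPca:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        m = 500
        p1, p2 = rng.uniform(0.2, 0.8, m), None
        p2 = np.clip(p1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
        G = np.vstack(
            [rng.binomial(2, p1[None].repeat(40, 0)), rng.binomial(2, p2[None].repeat(40, 0))]
        )
        scores, _ = run_pca(G, k=2, n_clusters=2, seed=0)
        labels_true = np.array([0] * 40 + [1] * 40)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(scores[:, :1], labels_true) > 0.5

    def test_three_planted_clusters_recovered(self):
        rng = np.random.default_rng(1)
        m = 600
        base = rng.uniform(0.2, 0.8, m)
        G = []
        truth = []
        for pop, shift in enumerate((-0.25, 0.0, 0.25)):
            p = np.clip(base + shift, 0.05, 0.95)
            G.append(rng.binomial(2, p[None].repeat(30, 0)))
            truth += [pop] * 30
        G = np.vstack(G)
        _, labels = run_pca(G, k=3, n_clusters=3, seed=0)
        # recovery up to relabeling: every true cluster maps to one label
        truth = np.array(truth)
        for pop in range(3):
            vals, counts = np.unique(labels[truth == pop], return_counts=True)
            assert counts.max() / counts.sum() > 0.9

    def test_rank_zero_raises(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((20, 50)), k=3)


class TestFitNullEmmax:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
        nm = fit_null_emmax(y, X, np.eye(n))
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r_ols = y - X @ beta
        # decorrelated residuals proportional to OLS residuals
        r_model = nm.eigvecs @ (nm.residuals / nm.scale)
        assert np.corrcoef(r_model, r_ols)[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_variance_ratio_recovery_block_families(self):
        """Planted sg2/se2 = 1 on block-family kinship, n=500: the REML
        estimate recovers it within +/-0.3 in the median."""
        n_fam, size = 100, 5
        n = n_fam * size
        block = np.full((size, size), 0.5) + 0.5 * np.eye(size)
        K = np.kron(np.eye(n_fam), block)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        rng = np.random.default_rng(5)
        X = np.ones((n, 1))
        estimates = []
        for _ in range(15):
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)
            estimates.append(fit_null_emmax(y, X, K).ratio)
        assert abs(np.median(estimates) - 1.0) < 0.3

    def test_constant_phenotype_degenerate(self):
        n = 30
        nm = fit_null_emmax(np.ones(n), np.ones((n, 1)), np.eye(n))
        assert nm.degenerate
        assert np.allclose(nm.residuals, 0)

    def test_rank_deficient_covariates_raise(self):
        n = 30
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError):
            fit_null_emmax(np.arange(n, dtype=float), X, np.eye(n))

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        d = simulate_null_family_cohort(n_families=30, m_common=1500, rng=rng)
        K = compute_kinship(d["common"]).values
        X = np.column_stack([np.ones(d["y"].size), rng.normal(size=d["y"].size)])
        nm = fit_null_emmax(d["y"], X, K)
        assert np.abs(nm.Xhat.T @ nm.residuals).max() < 1e-8


class TestDaviesPvalue:
    def test_single_eigenvalue_is_chi2(self):
        for q in (0.5, 3.84, 10.0, 30.0):
            assert davies_pvalue(q, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(q, 1), rel=1e-5
            )

    def test_equal_eigenvalues_are_scaled_chi2(self):
        q = 2.5 * stats.chi2.ppf(0.95, 3)
        assert davies_pvalue(q, np.array([2.5, 2.5, 2.5])) == pytest.approx(
            0.05, rel=1e-4
        )

    def test_scale_invariance(self):
        lam = np.array([5.0, 2.0, 0.7])
        p1 = davies_pvalue(10.0, lam)
        p2 = davies_pvalue(10.0 * 1e4, lam * 1e4)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_all_zero_eigenvalues(self):
        assert davies_pvalue(1.0, np.zeros(3)) == 1.0

    def test_liu_close_to_davies_in_bulk(self):
        lam = np.array([3.0, 1.0, 0.5, 0.5])
        for frac in (0.5, 1.0, 2.0):
            q = frac * lam.sum()
            assert liu_pvalue(q, lam) == pytest.approx(
                davies_pvalue(q, lam), abs=0.05
            )

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            k = int(rng.integers(1, 10))
            lam = rng.uniform(0.1, 20.0, k)
            p_target = rng.uniform(0.02, 0.5)
            # independent q location, then fresh draws for the MC estimate
            q = _invert_davies(lam, p_target)
            draws = (rng.standard_normal((400_000, k)) ** 2 * lam).sum(axis=1)
            mc = (draws > q).mean()
            se = math.sqrt(mc * (1 - mc) / draws.size)
            assert abs(davies_pvalue(q, lam) - mc) < 4 * se


def _invert_davies(lam, p_target):
    from scipy.optimize import brentq

    hi = lam.sum() + 20 * math.sqrt(2 * (lam**2).sum())
    return brentq(lambda q: davies_pvalue(q, lam) - p_target, 1e-9, hi, xtol=1e-8)


class TestSkatTest:
    def _null(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        return fit_null_emmax(y, X, np.eye(n)), rng

    def test_all_zero_genotypes(self):
        nm, _ = self._null()
        res = skat_test(nm, np.zeros((60, 3)))
        assert res.q_stat == 0.0 and res.p_asymptotic == 1.0

    def test_single_variant_matches_score_test(self):
        nm, rng = self._null()
        g = rng.binomial(1, 0.2, size=(60, 1)).astype(float)
        res = skat_test(nm, g, B=0)
        z = nm.project_out_covariates(nm.decorrelate(g))
        lam = float((z.T @ z).item())
        assert res.p_asymptotic == pytest.approx(
            stats.chi2.sf(res.q_stat / lam, 1), rel=1e-6
        )

    def test_matches_independent_dense_oracle(self):
        """With K = identity and no extra covariates the test must agree
        with a direct textbook computation (dense n x n route) on small
        instances."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            n, m = 40, 4
            y = rng.normal(size=n)
            X = np.ones((n, 1))
            G = rng.binomial(2, 0.15, size=(n, m)).astype(float)
            w = rng.uniform(0.5, 2.0, m)
            nm = fit_null_emmax(y, X, np.eye(n))
            res = skat_test(nm, G, weights=w, B=0)
            # oracle: OLS residuals, dense n x n projection, with both the
            # residuals and the weighted genotypes whitened by the REML
            # error scale sigma (= OLS sigma-hat under identity kinship)
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            r = y - X @ beta
            sigma2 = (r @ r) / (n - 1)
            P = np.eye(n) - X @ np.linalg.inv(X.T @ X) @ X.T
            A = P @ (G * w) / math.sqrt(sigma2)
            score = A.T @ (r / math.sqrt(sigma2))
            q_oracle = float(score @ score)
            lam_oracle = np.linalg.eigvalsh(A.T @ A)
            p_oracle = davies_pvalue(q_oracle, np.clip(lam_oracle, 0, None))
            assert res.q_stat == pytest.approx(q_oracle, rel=1e-8)
            assert res.p_asymptotic == pytest.approx(p_oracle, abs=1e-4)

    def test_resampling_deterministic_under_seed(self):
        nm, rng = self._null()
        G = np.random.default_rng(9).binomial(1, 0.1, size=(60, 5)).astype(float)
        p1 = skat_test(nm, G, B=2000, rng=np.random.default_rng(7)).p_resampling
        p2 = skat_test(nm, G, B=2000, rng=np.random.default_rng(7)).p_resampling
        assert p1 == p2

    def test_invariant_to_column_order_and_relabeling(self):
        rng = np.random.default_rng(11)
        n, m = 50, 6
        y = rng.binomial(1, 0.4, n).astype(float)
        X = np.ones((n, 1))
        K = np.eye(n)
        G = rng.binomial(1, 0.15, size=(n, m)).astype(float)
        w = np.ones(m)
        nm = fit_null_emmax(y, X, K)
        base = skat_test(nm, G, weights=w, B=0).p_asymptotic
        perm_cols = rng.permutation(m)
        assert skat_test(nm, G[:, perm_cols], weights=w[perm_cols], B=0).p_asymptotic == pytest.approx(base)
        relab = rng.permutation(n)
        nm2 = fit_null_emmax(y[relab], X[relab], K[np.ix_(relab, relab)])
        assert skat_test(nm2, G[relab], weights=w, B=0).p_asymptotic == pytest.approx(
            base, rel=1e-6
        )

    def test_davies_and_resampling_agree_in_resolvable_range(self):
        """On null family cohorts the two p-value routes agree within the
        resampling error at the adaptive stopping defaults."""
        rng = np.random.default_rng(21)
        within = 0
        total = 0
        for _ in range(12):
            d = simulate_null_family_cohort(rng=rng)
            nm = fit_null_emmax(
                d["y"], np.ones((d["y"].size, 1)), compute_kinship(d["common"]).values
            )
            res = skat_test(
                nm,
                d["rare"].astype(float),
                weights=beta_weights(d["rare"].mean(0) / 2),
                B=10_000,
                rng=rng,
            )
            if res.p_reported <= 1e-3:
                continue
            se = math.sqrt(
                res.p_resampling * (1 - res.p_resampling) / res.n_permutations
            )
            total += 1
            within += abs(res.p_asymptotic - res.p_resampling) <= 3 * se
        assert total > 0 and within / total >= 0.75


class TestRunAssociation:
    def test_planted_burden_gene_ranks_first(self):
        """A gene whose rare alleles are strongly enriched in cases gets
        the smallest p among all genes tested."""
        rng = np.random.default_rng(2)
        from pedseg.datamodel import Cohort, Role, Sample
        from pedseg.prioritize import classify_variant
        from conftest import make_variant

        n_case, n_uc = 60, 60
        samples = [
            Sample(f"C{i}", f"F{i}", affected=True, role=Role.CASE)
            for i in range(n_case)
        ] + [Sample(f"U{i}", "", role=Role.UNRELATED_CONTROL) for i in range(n_uc)]
        cohort = Cohort(samples=samples)
        n = len(cohort)
        common = rng.binomial(2, rng.uniform(0.2, 0.8, 600)[None].repeat(n, 0))
        calls = []
        pos = 0
        for gene in [f"G{i}" for i in range(8)]:
            for _ in range(4):
                pos += 1
                p_case = 0.25 if gene == "G0" else 0.02
                g = np.concatenate(
                    [rng.binomial(1, p_case, n_case), rng.binomial(1, 0.02, n_uc)]
                ).astype(np.int8)
                calls.append(
                    classify_variant(
                        make_variant(g, gene=gene, pos=pos, maf_sas=None, maf_global=None)
                    )
                )
        units = {f"G{i}": [f"G{i}"] for i in range(8)}
        results = run_association(
            cohort, calls, units, common_genotypes=common, B=0, seed=1
        )
        best = min(results, key=lambda r: r.p_asymptotic)
        assert best.unit == "G0"

    def test_two_sets_bonferroni(self):
        rng = np.random.default_rng(4)
        from pedseg.datamodel import Cohort, Role, Sample
        from pedseg.prioritize import classify_variant
        from conftest import make_variant

        samples = [
            Sample(f"C{i}", f"F{i}", affected=True, role=Role.CASE) for i in range(40)
        ] + [Sample(f"U{i}", "", role=Role.UNRELATED_CONTROL) for i in range(40)]
        cohort = Cohort(samples=samples)
        n = len(cohort)
        common = rng.binomial(2, rng.uniform(0.2, 0.8, 500)[None].repeat(n, 0))
        calls = [
            classify_variant(
                make_variant(
                    rng.binomial(1, 0.05, n).astype(np.int8),
                    gene=g,
                    pos=i + 1,
                    maf_sas=None,
                    maf_global=None,
                )
            )
            for i, g in enumerate(["A"] * 5 + ["B"] * 5)
        ]
        results = run_association(
            cohort,
            calls,
            {"setA": ["A"], "setB": ["B"]},
            common_genotypes=common,
            B=0,
            seed=0,
        )
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, 2 * r.p_reported))

    def test_seeded_determinism(self, mini_sim):
        from pedseg.prioritize import filter_rpd

        rpd = filter_rpd(mini_sim.variants)
        units = {"CNS": sorted(set(mini_sim.config.cns_genes))}
        r1 = run_association(
            mini_sim.cohort, rpd, units, mini_sim.common_genotypes, B=2000, seed=5
        )
        r2 = run_association(
            mini_sim.cohort, rpd, units, mini_sim.common_genotypes, B=2000, seed=5
        )
        assert r1[0].p_resampling == r2[0].p_resampling
        assert r1[0].q_stat == r2[0].q_stat


def test_beta_weights_upweight_rarer_variants():
    w = beta_weights(np.array([0.001, 0.01, 0.05]))
    assert w[0] > w[1] > w[2]
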