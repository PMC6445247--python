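"""PCA, admixture EM, cross-validation over K, label alignment."""

import numpy as np
import pytest

from aimpanel import (
    AdmixtureModel,
    GenotypeMatrix,
    GenotypePCA,
    SimulationSpec,
    align_cluster_labels,
    cv_error,
    pca_fit_project,
    simulate_genotypes,
    table2_fixture,
)
from aimpanel.structure import AdmixtureResults
from conftest import make_loci


class TestPCA:
    def test_opposite_fixation_separates_on_pc1(self):
        # two groups monomorphic for opposite alleles: PC1 splits them with
        # zero within-group variance
        geno = np.vstack([np.full((5, 10), 2), np.zeros((5, 10), dtype=int)])
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(10)], ["A"] * 5 + ["B"] * 5, make_loci(10), geno
        )
        res = pca_fit_project(gm, n_components=2)
        pc1 = res.scores_ref["PC1"].to_numpy()
        assert np.std(pc1[:5]) < 1e-8 and np.std(pc1[5:]) < 1e-8
        assert abs(pc1[:5].mean() - pc1[5:].mean()) > 1.0

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(20, 30))
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(20)], ["p"] * 20, make_loci(30), geno
        )
        res = pca_fit_project(gm, n_components=5)
        # independent path: standardize, eigendecompose the covariance
        pbar = geno.mean(axis=0) / 2
        X = (geno - 2 * pbar) / np.sqrt(pbar * (1 - pbar))
        evals, evecs = np.linalg.eigh(X.T @ X / (20 - 1))
        order = np.argsort(evals)[::-1][:5]
        np.testing.assert_allclose(res.eigenvalues, evals[order], atol=1e-8)
        want = X @ evecs[:, order]
        for c in range(5):
            got = res.scores_ref.iloc[:, c].to_numpy()
            sign = np.sign(np.dot(got, want[:, c]))
            np.testing.assert_allclose(got, sign * want[:, c], atol=1e-6)

    def test_reference_scores_zero_mean_eigvals_sorted(self, three_group_panel):
        gm, _, _ = three_group_panel
        res = pca_fit_project(gm, n_components=4)
        assert np.all(np.abs(res.scores_ref.mean(axis=0)) < 1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)

    def test_projection_of_reference_equals_fit(self, three_group_panel):
        gm, _, _ = three_group_panel
        res = pca_fit_project(gm, test=gm, n_components=3)
        np.testing.assert_allclose(
            res.scores_test.to_numpy(), res.scores_ref.to_numpy(), atol=1e-8
        )

    def test_group_separation_on_divergent_data(self, three_group_panel):
        from sklearn.metrics import silhouette_score

        gm, _, _ = three_group_panel
        res = pca_fit_project(gm, n_components=2)
        s = silhouette_score(res.scores_ref.to_numpy(), gm.population_labels)
        assert s >= 0.0

    def test_mismatched_projection_loci_is_error(self, three_group_panel):
        gm, _, _ = three_group_panel
        res = pca_fit_project(gm, n_components=2)
        other = gm.subset_loci(gm.rs_ids[:10])
        with pytest.raises(ValueError, match="lacks"):
            GenotypePCA(gm).project(other, res)


class TestAdmixtureEM:
    def test_k1_closed_form(self, two_group_panel):
        gm, _, _ = two_group_panel
        fit = AdmixtureModel(gm, 1).fit()
        np.testing.assert_array_equal(fit.Q, np.ones((gm.n_individuals, 1)))
        d = gm.dosage_float()
        np.testing.assert_allclose(
            fit.F[:, 0], np.nanmean(d, axis=0) / 2, atol=1e-6
        )
        assert fit.converged

    def test_loglik_trace_nondecreasing(self, two_group_panel):
        gm, _, _ = two_group_panel
        fit = AdmixtureModel(gm, 2).fit(seed=5, n_starts=1, max_iter=300)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_q_rows_on_simplex_f_clamped(self, two_group_panel):
        gm, _, _ = two_group_panel
        fit = AdmixtureModel(gm, 3).fit(seed=2, n_starts=1, max_iter=200)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
        assert fit.F.min() >= 1e-6 and fit.F.max() <= 1 - 1e-6

    def test_unsupervised_recovery_after_alignment(self, two_group_panel):
        gm, ft, q = two_group_panel
        fit = AdmixtureModel(gm, 2).fit(seed=1)
        truth = AdmixtureResults(K=2, Q=q.to_numpy(), F=ft.freq, loglik=0.0)
        perm = align_cluster_labels(truth, fit)
        mae = np.mean(np.abs(fit.Q[:, perm] - q.to_numpy()))
        assert mae < 0.05

    def test_supervised_equals_direct_mle(self):
        # per-individual likelihood is concave in q given fixed F, so EM
        # must reach the same optimum as a generic optimizer
        from scipy.optimize import minimize

        t2 = table2_fixture()
        spec = SimulationSpec(
            groups=[(g, 5) for g in t2.group_names], loci=list(t2.loci),
            freq_model=t2, seed=17,
        )
        gm, _, _ = simulate_genotypes(spec)
        fit = AdmixtureModel(gm, 4, supervised_F=t2).fit(seed=3, n_starts=1, tol=1e-10, max_iter=10000)
        F = np.clip(t2.freq, 1e-6, 1 - 1e-6)
        g = gm.geno.astype(float)

        def negll(z, gi):
            q = np.exp(z - z.max())
            q /= q.sum()
            mu = np.clip(F @ q, 1e-9, 1 - 1e-9)
            return -(gi * np.log(mu) + (2 - gi) * np.log(1 - mu)).sum()

        for i in range(0, gm.n_individuals, 5):
            best = None
            for s in range(3):
                z0 = np.random.default_rng(s).normal(size=4)
                r = minimize(negll, z0, args=(g[i],), method="Nelder-Mead",
                             options=dict(maxiter=5000, fatol=1e-12, xatol=1e-10))
                if best is None or r.fun < best.fun:
                    best = r
            q_ref = np.exp(best.x - best.x.max())
            q_ref /= q_ref.sum()
            np.testing.assert_allclose(fit.Q[i], q_ref, atol=5e-3)

    def test_individual_permutation_equivariance(self):
        t2 = table2_fixture()
        spec = SimulationSpec(
            groups=[(g, 5) for g in t2.group_names], loci=list(t2.loci),
            freq_model=t2, seed=19,
        )
        gm, _, _ = simulate_genotypes(spec)
        rng = np.random.default_rng(2)
        perm = rng.permutation(gm.n_individuals)
        fit_a = AdmixtureModel(gm, 4, supervised_F=t2).fit(seed=1, n_starts=1, tol=1e-9, max_iter=5000)
        fit_b = AdmixtureModel(gm.subset_individuals(perm), 4, supervised_F=t2).fit(
            seed=1, n_starts=1, tol=1e-9, max_iter=5000
        )
        np.testing.assert_allclose(fit_b.Q, fit_a.Q[perm], atol=1e-4)

    def test_k_exceeding_individuals_is_error(self, two_group_panel):
        gm, _, _ = two_group_panel
        with pytest.raises(ValueError, match="exceeds"):
            AdmixtureModel(gm, gm.n_individuals + 1)

    def test_all_missing_individual_is_error(self):
        geno = np.array([[1, 1], [-1, -1]])
        gm = GenotypeMatrix(["a", "b"], ["p", "p"], make_loci(2), geno)
        with pytest.raises(ValueError, match="no non-missing"):
            AdmixtureModel(gm, 1)


class TestCrossValidation:
    def test_errors_finite_and_nonnegative(self, two_group_panel):
        gm, _, _ = two_group_panel
        errs = cv_error(gm, [1, 2], folds=3, seed=0, n_starts=1, max_iter=150)
        assert np.all(np.isfinite(errs)) and np.all(errs >= 0)

    def test_panmictic_data_does_not_prefer_k2(self):
        rng = np.random.default_rng(14)
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, size=40), size=(60, 40))
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(60)], ["p"] * 60, make_loci(40), geno
        )
        errs = cv_error(gm, [1, 2], folds=3, seed=3, n_starts=1, max_iter=200)
        assert errs[2] >= errs[1] - 0.02  # K=2 no better than K=1 beyond noise

    def test_recovers_generating_k(self, three_group_panel):
        gm, _, _ = three_group_panel
        errs = cv_error(gm, range(1, 5), folds=3, seed=7, n_starts=2, max_iter=300)
        assert errs.idxmin() == 3


class TestLabelAlignment:
    def _fit(self, Q):
        return AdmixtureResults(K=Q.shape[1], Q=Q, F=np.zeros((1, Q.shape[1])), loglik=0.0)

    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(3), size=20)
        fit = self._fit(Q)
        np.testing.assert_array_equal(align_cluster_labels(fit, fit), [0, 1, 2])

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(1)
        Q = rng.dirichlet(np.ones(3), size=20)
        swapped = self._fit(Q[:, [2, 0, 1]])
        perm = align_cluster_labels(self._fit(Q), swapped)
        np.testing.assert_allclose(swapped.Q[:, perm], Q, atol=1e-12)

    def test_two_seeded_runs_agree_after_alignment(self, two_group_panel):
        gm, _, _ = two_group_panel
        a = AdmixtureModel(gm, 2).fit(seed=1, n_starts=1)
        b = AdmixtureModel(gm, 2).fit(seed=99, n_starts=1)
        perm = align_cluster_labels(a, b)
        assert np.max(np.abs(b.Q[:, perm] - a.Q)) < 0.05

    def test_k_mismatch_is_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="K mismatch"):
            align_cluster_labels(
                self._fit(rng.dirichlet(np.ones(2), size=5)),
                self._fit(rng.dirichlet(np.ones(3), size=5)),
            )
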