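import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

import mrdflow as m
from mrdflow.clustering import model_from_dict, model_to_dict

from conftest import toy_two_cluster_model


def gls_oracle(cohort, basis, Gamma, sigma2):
    """Direct generalized-least-squares spline fit of the pooled mixed model
    at fixed variance components."""
    p = basis.dimension
    A = np.zeros((p, p))
    b = np.zeros(p)
    for t in cohort.trajectories:
        S = basis.evaluate(t.times)
        Sigma = S @ Gamma @ S.T + sigma2 * np.eye(len(t))
        Si = np.linalg.inv(Sigma)
        A += S.T @ Si @ S
        b += S.T @ Si @ t.values
    return np.linalg.solve(A, b)


class TestEmFit:
    def test_loglik_nondecreasing(self, fitted_four_cluster):
        fit, _, _ = fitted_four_cluster
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_memberships_are_probabilities(self, fitted_four_cluster):
        fit, _, _ = fitted_four_cluster
        np.testing.assert_allclose(fit.memberships.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(fit.memberships >= 0)
        np.testing.assert_array_equal(fit.assignments, fit.memberships.argmax(axis=1))

    def test_g1_equals_gls_oracle(self, small_cohort):
        """With one cluster the EM mean must solve the GLS normal equations
        at the fitted variance components."""
        cohort, _ = small_cohort
        fit = m.fit_fcm(cohort, G=1, p=4, n_starts=1, seed=0)
        model = fit.model
        eta_hat = model.cluster_coefficients[0]
        eta_gls = gls_oracle(cohort, model.basis, model.Gamma, model.sigma2)
        np.testing.assert_allclose(eta_hat, eta_gls, atol=1e-6)

    def test_two_separated_archetypes_recovered_exactly(self):
        """Mean gap >> noise: the fitted labels must match truth (ARI 1)."""
        specs = m.scale_to_separation(m.default_archetypes()[:2], 8.0)
        specs = [
            s.__class__(**{**s.__dict__, "proportion": 0.5}) for s in specs
        ]
        config = m.default_config(n_subjects=50, seed=5)
        cohort, labels = m.generate_cohort(specs, config)
        cohort = m.filter_cohort(cohort, 3)
        keep = [int(t.patient_id[1:]) - 1 for t in cohort.trajectories]
        fit = m.fit_fcm(cohort, G=2, p=4, n_starts=3, seed=5)
        assert adjusted_rand_score(labels[keep], fit.assignments) == 1.0

    def test_label_permutation_invariance(self, fitted_four_cluster):
        """Relabeling clusters must leave likelihood-derived quantities and
        the survival stratification unchanged."""
        fit, cohort, _ = fitted_four_cluster
        model = fit.model
        perm = np.array([2, 0, 3, 1])
        permuted = m.FcmModel(
            basis=model.basis, G=model.G, h=model.h, lambda0=model.lambda0,
            Lambda=model.Lambda, alpha=model.alpha[perm], Gamma=model.Gamma,
            sigma2=model.sigma2, priors=model.priors[perm],
        )
        traj = cohort.trajectories[0]
        w0 = m.posterior_membership(model, traj)
        w1 = m.posterior_membership(permuted, traj)
        np.testing.assert_allclose(w1, w0[perm], atol=1e-10)
        assert m.shannon_entropy(w1) == pytest.approx(m.shannon_entropy(w0))
        np.testing.assert_allclose(
            m.predict_curve(permuted, traj, [0.0, 12.0, 30.0]),
            m.predict_curve(model, traj, [0.0, 12.0, 30.0]),
            atol=1e-9,
        )


class TestPosterior:
    def test_sums_to_one(self, fitted_four_cluster):
        fit, cohort, _ = fitted_four_cluster
        for traj in cohort.trajectories[:10]:
            w = m.posterior_membership(fit.model, traj)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)

    def test_closed_form_bayes_oracle(self):
        """2-cluster toy with scalar covariances: the posterior must match
        the closed-form Gaussian Bayes rule."""
        model = toy_two_cluster_model(sigma2=0.25, priors=(0.3, 0.7))
        times = np.array([1.0, 4.0, 9.0])
        y = np.array([-5.1, -4.0, -3.2])
        traj = m.MrdTrajectory("X", m.Tissue.BM, times, y)
        w = m.posterior_membership(model, traj)

        S = model.basis.evaluate(times)
        sd = np.sqrt(model.sigma2)
        lik = np.array([
            np.prod(norm.pdf(y, loc=S @ eta, scale=sd))
            for eta in model.cluster_coefficients
        ])
        expected = model.priors * lik
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-10)

    def test_noiseless_cluster_mean_is_assigned_to_it(self, fitted_four_cluster):
        fit, _, _ = fitted_four_cluster
        model = fit.model
        times = np.array([0.0, 3.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0])
        for k in range(model.G):
            y = model.mean_curves(times)[k]
            traj = m.MrdTrajectory("mean", m.Tissue.BM, times, y)
            assert m.posterior_membership(model, traj).argmax() == k


class TestPredictCurve:
    def test_empty_query(self, fitted_four_cluster):
        fit, cohort, _ = fitted_four_cluster
        assert m.predict_curve(fit.model, cohort.trajectories[0], []).size == 0

    def test_degenerate_weights_use_single_cluster(self):
        model = toy_two_cluster_model(sigma2=0.5)
        traj = m.MrdTrajectory(
            "X", m.Tissue.BM, np.array([2.0, 8.0]), np.array([-6.0, -6.0])
        )
        # Gamma = 0: the conditional coefficient mean is the cluster mean
        pred = m.predict_curve(model, traj, [0.0, 5.0], memberships=np.array([1.0, 0.0]))
        expected = model.basis.evaluate([0.0, 5.0]) @ model.cluster_coefficients[0]
        np.testing.assert_allclose(pred, expected, atol=1e-12)

    def test_g1_no_random_effect_gives_gls_curve(self, small_cohort):
        """With G=1 and Gamma=0 the reconstruction is the population GLS
        spline, identical for every subject."""
        cohort, _ = small_cohort
        fit = m.fit_fcm(cohort, G=1, p=4, n_starts=1, seed=0)
        model = fit.model
        frozen = m.FcmModel(
            basis=model.basis, G=1, h=1, lambda0=model.lambda0,
            Lambda=model.Lambda, alpha=model.alpha,
            Gamma=np.zeros_like(model.Gamma), sigma2=model.sigma2,
            priors=model.priors,
        )
        grid = np.linspace(0, 42, 10)
        expected = frozen.mean_curves(grid)[0]
        for traj in cohort.trajectories[:5]:
            np.testing.assert_allclose(
                m.predict_curve(frozen, traj, grid), expected, atol=1e-9
            )

    def test_near_interpolation_when_noise_vanishes(self):
        """As sigma2 -> 0 with a free random effect, the reconstruction
        passes through the observed points."""
        basis = m.NaturalCubicBasis(np.array([0.0, 6.0, 12.0, 24.0]))
        model = m.FcmModel(
            basis=basis, G=1, h=1, lambda0=np.array([-4.0, 0.0, 0.0, 0.0]),
            Lambda=np.zeros((4, 1)), alpha=np.zeros((1, 1)),
            Gamma=np.eye(4), sigma2=1e-10, priors=np.array([1.0]),
        )
        times = np.array([0.0, 6.0, 12.0, 24.0])
        y = np.array([-3.0, -5.0, -6.5, -4.0])
        traj = m.MrdTrajectory("X", m.Tissue.BM, times, y)
        np.testing.assert_allclose(
            m.predict_curve(model, traj, times), y, atol=1e-5
        )


class TestFdbIndex:
    def test_matches_brute_force_formula(self, fitted_four_cluster):
        """Recompute the index from tabulated curves with explicit loops."""
        fit, cohort, _ = fitted_four_cluster
        model = fit.model
        value = m.fdb_index(fit, cohort, n_grid=100)

        t_max = max(float(t.times.max()) for t in cohort.trajectories)
        grid = np.linspace(0.0, t_max, 100)
        means = model.mean_curves(grid)
        l2 = lambda f, g: np.sqrt(np.trapezoid((f - g) ** 2, grid))
        G = model.G
        S_k = []
        for k in range(G):
            dists = [
                l2(m.predict_curve(model, traj, grid,
                                   memberships=fit.memberships[i]), means[k])
                for i, traj in enumerate(cohort.trajectories)
                if fit.assignments[i] == k
            ]
            S_k.append(np.mean(dists) if dists else 0.0)
        expected = np.mean([
            max((S_k[k] + S_k[j]) / l2(means[k], means[j])
                for j in range(G) if j != k)
            for k in range(G)
        ])
        assert value == pytest.approx(expected, rel=1e-10)

    def test_identical_clusters_give_infinity(self, small_cohort):
        cohort, _ = small_cohort
        fit = m.fit_fcm(cohort, G=1, p=4, n_starts=1, seed=0)
        model = fit.model
        dup = m.FcmModel(
            basis=model.basis, G=2, h=1,
            lambda0=model.lambda0, Lambda=np.zeros((model.p, 1)),
            alpha=np.zeros((2, 1)), Gamma=model.Gamma, sigma2=model.sigma2,
            priors=np.array([0.5, 0.5]),
        )
        fake = m.FitResult(
            model=dup,
            memberships=np.full((len(cohort), 2), 0.5),
            assignments=np.zeros(len(cohort), dtype=int),
            patient_ids=cohort.patient_ids(),
            loglik_trace=np.array([0.0]), converged=True, n_iter=1,
        )
        with pytest.warns(UserWarning):
            assert m.fdb_index(fake, cohort) == np.inf

    def test_requires_two_clusters(self, small_cohort):
        cohort, _ = small_cohort
        fit = m.fit_fcm(cohort, G=1, p=4, n_starts=1, seed=0)
        with pytest.raises(ValueError):
            m.fdb_index(fit, cohort)


class TestDiscriminants:
    def test_g1_empty(self):
        basis = m.NaturalCubicBasis(np.array([0.0, 10.0]))
        model = m.FcmModel(
            basis=basis, G=1, h=1, lambda0=np.zeros(2),
            Lambda=np.zeros((2, 1)), alpha=np.zeros((1, 1)),
            Gamma=np.zeros((2, 2)), sigma2=0.1, priors=np.array([1.0]),
        )
        assert m.discriminant_functions(model, np.linspace(0, 10, 5)).shape == (5, 0)

    def test_curve_count(self, fitted_four_cluster):
        fit, _, _ = fitted_four_cluster
        model = fit.model
        D = m.discriminant_functions(model, np.linspace(0, 42, 50))
        assert D.shape == (50, min(model.h, model.G - 1))

    def test_peak_in_informative_window(self):
        """Two clusters whose means differ only on [20, 30] months: the
        discriminant magnitude must peak inside that window, where a
        per-timepoint Fisher ratio oracle also peaks."""
        knots = np.array([0.0, 10.0, 20.0, 25.0, 30.0, 42.0])
        basis = m.NaturalCubicBasis(knots)
        grid = np.linspace(0, 42, 400)
        S = basis.evaluate(grid)
        bump = np.where((grid >= 20) & (grid <= 30),
                        np.sin(np.pi * (grid - 20) / 10) ** 2, 0.0)
        delta, *_ = np.linalg.lstsq(S, bump, rcond=None)
        eta = np.stack([-4.0 + 0.0 * delta, -4.0 + delta])
        priors = np.array([0.5, 0.5])
        lambda0 = priors @ eta
        B = eta - lambda0
        _, _, Vt = np.linalg.svd(np.sqrt(priors)[:, None] * B, full_matrices=False)
        Lambda = Vt[:1].T
        model = m.FcmModel(
            basis=basis, G=2, h=1, lambda0=lambda0, Lambda=Lambda,
            alpha=B @ Lambda, Gamma=1e-4 * np.eye(len(knots)), sigma2=0.2,
            priors=priors,
        )
        D = np.abs(m.discriminant_functions(model, grid))[:, 0]
        assert 20.0 <= grid[np.argmax(D)] <= 30.0
        # independent oracle: homoscedastic per-timepoint Fisher ratio
        fisher = (eta[1] - eta[0]) @ S.T
        fisher = fisher**2 / model.sigma2
        assert 20.0 <= grid[np.argmax(fisher)] <= 30.0


class TestSelectModel:
    def test_single_archetype_selects_one_cluster(self):
        specs = [m.default_archetypes()[1].__class__(
            **{**m.default_archetypes()[1].__dict__, "proportion": 1.0})]
        cohort, _ = m.generate_cohort(specs, m.default_config(n_subjects=30, seed=2))
        cohort = m.filter_cohort(cohort, 3)
        _, G_star, h_star, diag = m.select_model(
            cohort, p_grid=[4], G_grid=[1, 2, 3], seed=2, n_starts=2, n_folds=3
        )
        assert G_star == 1 and h_star == 1

    def test_two_separated_archetypes_select_two(self):
        specs = m.scale_to_separation(m.default_archetypes()[1:3], 8.0)
        specs = [s.__class__(**{**s.__dict__, "proportion": 0.5}) for s in specs]
        cohort, _ = m.generate_cohort(specs, m.default_config(n_subjects=40, seed=4))
        cohort = m.filter_cohort(cohort, 3)
        _, G_star, _, diag = m.select_model(
            cohort, p_grid=[4], G_grid=[1, 2, 3], seed=4, n_starts=2, n_folds=3
        )
        assert G_star == 2


class TestSerialization:
    def test_roundtrip_reproduces_memberships_exactly(
        self, fitted_four_cluster, tmp_path
    ):
        fit, cohort, _ = fitted_four_cluster
        path = tmp_path / "model.json"
        m.save_model(fit.model, path, meta={"seed": 11})
        loaded = m.load_model(path)
        for traj in cohort.trajectories[:8]:
            w0 = m.posterior_membership(fit.model, traj)
            w1 = m.posterior_membership(loaded, traj)
            np.testing.assert_array_equal(w0, w1)  # bit-for-bit

    def test_version_gate(self):
        d = model_to_dict(toy_two_cluster_model())
        d["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            model_from_dict(d)
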