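"""CSP engine: covariance estimation, generalized eigendecomposition, features."""

import numpy as np
import pytest

from mlcsp.csp import (
    CovariancePair,
    apply_filters,
    csp_features,
    features_from_covariances,
    fit_csp,
    mean_class_covariance,
    normalized_covariance,
    patterns,
    select_filters,
    trial_covariances,
)


def random_trial(rng, channels=4, samples=50):
    return rng.standard_normal((channels, samples))


def random_spd(rng, c):
    x = rng.standard_normal((c, 3 * c))
    s = x @ x.T
    return s / np.trace(s)


class TestNormalizedCovariance:
    def test_single_channel_normalizes_to_one(self, rng):
        trial = rng.standard_normal((1, 30))
        np.testing.assert_allclose(normalized_covariance(trial), [[1.0]])

    def test_orthogonal_equal_power_rows_give_half_diagonal(self):
        trial = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        np.testing.assert_allclose(normalized_covariance(trial), np.diag([0.5, 0.5]))

    def test_matches_direct_oracle(self, rng):
        trial = random_trial(rng, 3)
        oracle = trial @ trial.T / np.trace(trial @ trial.T)
        np.testing.assert_allclose(normalized_covariance(trial), oracle)
        got = normalized_covariance(trial)
        assert np.trace(got) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(got, got.T)

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError):
            normalized_covariance(np.zeros((3, 10)))

    def test_batched_equals_per_trial(self, rng):
        data = rng.standard_normal((5, 3, 40))
        batched = trial_covariances(data)
        for i in range(5):
            np.testing.assert_allclose(batched[i], normalized_covariance(data[i]))


class TestMeanClassCovariance:
    def test_single_and_duplicated_trials(self, rng):
        trial = random_trial(rng)
        np.testing.assert_allclose(
            mean_class_covariance([trial]), normalized_covariance(trial)
        )
        np.testing.assert_allclose(
            mean_class_covariance([trial, trial]), normalized_covariance(trial)
        )

    def test_matches_elementwise_oracle(self, rng):
        trials = [random_trial(rng) for _ in range(5)]
        oracle = sum(normalized_covariance(t) for t in trials) / 5
        got = mean_class_covariance(trials)
        np.testing.assert_allclose(got, oracle)
        assert np.trace(got) == pytest.approx(1.0, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_class_covariance([])


class TestFitCSP:
    def test_identical_isotropic_classes_give_unit_eigenvalues(self):
        sigma = np.eye(3) / 3
        model = fit_csp(CovariancePair(sigma, sigma, 10, 10))
        np.testing.assert_allclose(model.eigenvalues, 1.0, rtol=1e-6)

    def test_hand_solved_2x2_diagonal_problem(self):
        # sigma1 w = lambda sigma2 w with diagonal matrices: lambda = 0.8/0.2 = 4
        # along the first axis and 0.2/0.8 = 0.25 along the second.
        pair = CovariancePair(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]), 5, 5)
        model = fit_csp(pair, m=1)
        np.testing.assert_allclose(model.eigenvalues, [4.0, 0.25], rtol=1e-6)
        W = np.abs(model.W / np.abs(model.W).max(axis=0))
        np.testing.assert_allclose(W, np.eye(2), atol=1e-9)

    def test_simultaneous_diagonalization_and_eigen_residual(self, rng):
        c = 6
        pair = CovariancePair(random_spd(rng, c), random_spd(rng, c), 20, 20)
        model = fit_csp(pair)
        for sigma in (pair.sigma1, pair.sigma2):
            d = model.W.T @ sigma @ model.W
            off = d - np.diag(np.diag(d))
            assert np.abs(off).max() / np.abs(np.diag(d)).max() < 1e-6
        for j in range(c):
            w = model.W[:, j]
            resid = pair.sigma1 @ w - model.eigenvalues[j] * (pair.sigma2 @ w)
            assert np.linalg.norm(resid) < 1e-6
        # scaling convention
        np.testing.assert_allclose(
            np.diag(model.W.T @ (pair.sigma1 + pair.sigma2) @ model.W), 1.0, atol=1e-9
        )
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_swapping_classes_inverts_eigenvalue_spectrum(self, rng):
        pair = CovariancePair(random_spd(rng, 5), random_spd(rng, 5), 10, 10)
        fwd = fit_csp(pair)
        rev = fit_csp(CovariancePair(pair.sigma2, pair.sigma1, 10, 10))
        np.testing.assert_allclose(rev.eigenvalues, 1 / fwd.eigenvalues[::-1], rtol=1e-6)

    def test_extreme_filters_match_rayleigh_grid_search(self, rng):
        """Top/bottom filters maximize/minimize w'S1w / w'S2w (3-D grid oracle)."""
        pair = CovariancePair(random_spd(rng, 3), random_spd(rng, 3), 10, 10)
        model = fit_csp(pair, m=1)
        theta = np.linspace(0, np.pi, 181)
        phi = np.linspace(0, 2 * np.pi, 361)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        ).reshape(-1, 3)
        quotient = np.einsum("ni,ij,nj->n", dirs, pair.sigma1, dirs) / np.einsum(
            "ni,ij,nj->n", dirs, pair.sigma2, dirs
        )
        for col, grid_w in ((0, dirs[quotient.argmax()]), (-1, dirs[quotient.argmin()])):
            w = model.W[:, col]
            cos = np.abs(grid_w @ w) / np.linalg.norm(w)
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 2.0

    def test_non_symmetric_input_rejected(self, rng):
        bad = rng.standard_normal((3, 3))
        with pytest.raises(ValueError):
            CovariancePair(bad, np.eye(3) / 3, 5, 5)

    def test_variance_contrast_recovers_planted_direction(self, rng):
        """Class-1 variance inflated along u: the top filter's pattern aligns with u."""
        c, n, t = 6, 60, 200
        u = rng.standard_normal(c)
        u /= np.linalg.norm(u)
        base = [rng.standard_normal((c, t)) for _ in range(2 * n)]
        class1 = [b + 4.0 * np.outer(u, rng.standard_normal(t)) for b in base[:n]]
        pair = CovariancePair(
            mean_class_covariance(class1), mean_class_covariance(base[n:]), n, n
        )
        model = fit_csp(pair, m=1)
        pattern = model.pattern(0)
        cos = np.abs(pattern @ u) / np.linalg.norm(pattern)
        assert cos >= 0.95


class TestSelectionProjectionFeatures:
    def test_select_filters_counts(self, rng):
        pair = CovariancePair(random_spd(rng, 26), random_spd(rng, 26), 10, 10)
        model = fit_csp(pair, m=3)
        assert select_filters(model).shape == (26, 6)
        full = select_filters(fit_csp(pair, m=13))
        assert full.shape == (26, 26)
        with pytest.raises(ValueError):
            select_filters(model, m=14)

    def test_select_m1_on_diagonal_case_returns_axis_filters(self):
        pair = CovariancePair(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]), 5, 5)
        W_sel = select_filters(fit_csp(pair, m=1))
        assert W_sel.shape == (2, 2)
        np.testing.assert_allclose(
            np.abs(W_sel) / np.abs(W_sel).max(axis=0), np.eye(2), atol=1e-9
        )

    def test_apply_filters_is_matrix_product(self, rng):
        trial = random_trial(rng, 4, 20)
        W_sel = np.eye(4)[:, [1, 3]]
        np.testing.assert_array_equal(apply_filters(W_sel, trial), trial[[1, 3]])
        np.testing.assert_allclose(apply_filters(W_sel, np.zeros((4, 20))), 0.0)
        W = rng.standard_normal((4, 2))
        np.testing.assert_allclose(apply_filters(W, trial), W.T @ trial)
        with pytest.raises(ValueError):
            apply_filters(W, random_trial(rng, 5))

    def test_features_normalization_identity(self, rng):
        trial = random_trial(rng, 4, 100)
        W_sel = rng.standard_normal((4, 2))
        v = csp_features(W_sel, trial)
        assert (v < 0).all()
        assert np.exp(v).sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_projected_power_gives_uniform_features(self):
        trial = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        v = csp_features(np.eye(2), trial)
        np.testing.assert_allclose(v, np.log(0.5), atol=1e-12)

    def test_features_match_direct_oracle(self, rng):
        trial = random_trial(rng, 4, 60)
        W_sel = rng.standard_normal((4, 2))
        proj = W_sel.T @ trial @ trial.T @ W_sel
        oracle = np.log(np.diag(proj) / np.trace(proj))
        np.testing.assert_allclose(csp_features(W_sel, trial), oracle)
        # batched path agrees
        batched = features_from_covariances(W_sel, trial_covariances(trial[None]))
        np.testing.assert_allclose(batched[0], oracle)

    def test_zero_trial_features_rejected(self):
        with pytest.raises(ValueError):
            csp_features(np.eye(2), np.zeros((2, 10)))


class TestPatterns:
    def test_inverse_relationship(self, rng):
        pair = CovariancePair(random_spd(rng, 5), random_spd(rng, 5), 10, 10)
        model = fit_csp(pair)
        A = patterns(model)
        np.testing.assert_allclose(model.W @ A, np.eye(5), atol=1e-6)
        np.testing.assert_allclose(A, np.linalg.inv(model.W), atol=1e-9)
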