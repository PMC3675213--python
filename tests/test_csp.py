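"""CSP: hand-worked examples, algebraic identities, and agreement with a
brute-force generalized-eigendecomposition oracle."""

import numpy as np
import pytest
from scipy import linalg

from sensebci import (apply_csp, class_mean_covariance,
                      features_from_covariances, fit_csp,
                      fit_csp_from_session, logvar_features,
                      normalized_covariance)

from conftest import make_session


def random_spd_pair(dim, rng):
    """Two random normalized SPD matrices of the given dimension."""
    out = []
    for _ in range(2):
        A = rng.standard_normal((dim, dim + 4))
        C = A @ A.T
        out.append(C / np.trace(C))
    return out


def oracle_generalized_eig(C1, C2):
    """Brute-force oracle: solve C1 v = lambda (C1 + C2) v directly."""
    lam, V = linalg.eigh(C1, C1 + C2)
    order = np.argsort(lam)[::-1]
    return lam[order], V[:, order]


class TestNormalizedCovariance:
    def test_hand_example(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0]])
        C = normalized_covariance(X)
        assert np.allclose(C, [[0.5, 0.0], [0.0, 0.5]])

    @pytest.mark.parametrize("seed", range(5))
    def test_unit_trace_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        C = normalized_covariance(rng.standard_normal((6, 100)))
        assert np.trace(C) == pytest.approx(1.0)
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-12)

    def test_white_trial_is_isotropic(self):
        rng = np.random.default_rng(0)
        C = normalized_covariance(rng.standard_normal((4, 200_000)))
        assert np.allclose(C, np.eye(4) / 4, atol=5e-3)

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            normalized_covariance(np.zeros((3, 50)))

    def test_short_trial_warns(self):
        with pytest.warns(UserWarning, match="rank deficient"):
            normalized_covariance(np.random.default_rng(0).standard_normal((5, 4)))


class TestClassMeanCovariance:
    def test_two_trial_average_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 4, 80))
        s = make_session(data, labels=["left", "left"])
        expected = (normalized_covariance(data[0]) + normalized_covariance(data[1])) / 2
        assert np.allclose(class_mean_covariance(s, "left"), expected)

    def test_identical_trials_collapse(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 80))
        s = make_session(np.tile(X, (3, 1, 1)), labels=["right"] * 3)
        assert np.allclose(class_mean_covariance(s, "right"), normalized_covariance(X))

    def test_balanced_pooling_linearity(self, session_small_strong):
        C1 = class_mean_covariance(session_small_strong, "left")
        C2 = class_mean_covariance(session_small_strong, "right")
        pooled = sum(normalized_covariance(x) for x in session_small_strong.data)
        pooled /= session_small_strong.n_trials
        assert np.allclose(pooled, 0.5 * (C1 + C2))

    def test_empty_class_rejected(self):
        s = make_session(np.random.default_rng(0).standard_normal((2, 3, 50)),
                         labels=["left", "left"])
        with pytest.raises(ValueError, match="right"):
            class_mean_covariance(s, "right")


class TestFitCSP:
    def test_axis_aligned_closed_form(self):
        C1 = np.diag([0.8, 0.2])
        C2 = np.diag([0.2, 0.8])
        model = fit_csp(C1, C2, n_pairs=1)
        assert np.allclose(model.eigvals_class1, [0.8, 0.2])
        # filters recover the coordinate axes up to scale
        for row in model.filters:
            assert np.min(np.abs(row)) < 1e-10 * np.max(np.abs(row)) + 1e-12

    def test_identical_classes_are_indiscriminable(self):
        rng = np.random.default_rng(3)
        C, _ = random_spd_pair(5, rng)
        model = fit_csp(C, C)
        assert np.allclose(model.eigvals_class1, 0.5, atol=1e-10)

    @pytest.mark.parametrize("dim,seed", [(d, s) for d in range(2, 11) for s in (0, 1)])
    def test_identities_and_oracle_agreement(self, dim, seed):
        rng = np.random.default_rng(100 * dim + seed)
        C1, C2 = random_spd_pair(dim, rng)
        model = fit_csp(C1, C2)
        W = model.filters
        # eigenvalue complementarity: projected class covariances are diagonal
        # and their diagonals sum to one
        D1 = W @ C1 @ W.T
        D2 = W @ C2 @ W.T
        assert np.allclose(D1 - np.diag(np.diag(D1)), 0, atol=1e-10)
        assert np.allclose(D2 - np.diag(np.diag(D2)), 0, atol=1e-10)
        assert np.allclose(np.diag(D1) + np.diag(D2), 1.0, atol=1e-10)
        # whitening identity
        assert np.allclose(W @ (C1 + C2) @ W.T, np.eye(dim), atol=1e-8)
        # oracle agreement: eigenvalues and one-dimensional eigenspaces
        lam, V = oracle_generalized_eig(C1, C2)
        assert np.allclose(model.eigvals_class1, lam, atol=1e-8)
        for i in range(dim):
            w = W[i] / np.linalg.norm(W[i])
            v = V[:, i] / np.linalg.norm(V[:, i])
            assert abs(w @ v) == pytest.approx(1.0, abs=1e-6)

    def test_class_swap_reverses_spectrum(self):
        rng = np.random.default_rng(4)
        C1, C2 = random_spd_pair(6, rng)
        fwd = fit_csp(C1, C2)
        rev = fit_csp(C2, C1)
        assert np.allclose(rev.eigvals_class1, (1 - fwd.eigvals_class1)[::-1], atol=1e-10)
        assert np.allclose(np.abs(rev.filters), np.abs(fwd.filters[::-1]), atol=1e-8)

    def test_patterns_invert_filters(self):
        rng = np.random.default_rng(5)
        C1, C2 = random_spd_pair(5, rng)
        model = fit_csp(C1, C2)
        assert np.allclose(model.filters @ model.patterns, np.eye(5), atol=1e-8)

    def test_rank_deficient_composite_rejected(self):
        C = np.zeros((3, 3))
        C[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_csp(C, C)


class TestProjectionAndFeatures:
    def test_projected_training_covariance_is_diagonal(self, session_small_strong):
        """Projecting the pooled training covariance (mean of the per-trial
        normalized covariances over both classes) diagonalizes it."""
        from sensebci import bandpass, extract_window
        win = extract_window(bandpass(session_small_strong, "broad"), 4, 7)
        model = fit_csp_from_session(win)
        pooled = sum(normalized_covariance(x) for x in win.data) / win.n_trials
        proj = model.filters @ pooled @ model.filters.T
        off = proj - np.diag(np.diag(proj))
        assert np.max(np.abs(off)) < 1e-10
        assert np.allclose(np.diag(proj), 0.5, atol=1e-10)  # W (C1+C2) W' = I

    def test_identity_model_is_identity(self, session_small_strong):
        from sensebci import CSPModel
        n = session_small_strong.n_channels
        model = CSPModel(filters=np.eye(n), patterns=np.eye(n),
                         eigvals_class1=np.full(n, 0.5))
        Z = apply_csp(model, session_small_strong)
        assert np.array_equal(Z.data, session_small_strong.data)

    def test_channel_mismatch_rejected(self, session_small_strong):
        from sensebci import CSPModel
        model = CSPModel(filters=np.eye(4), patterns=np.eye(4),
                         eigvals_class1=np.full(4, 0.5))
        with pytest.raises(ValueError, match="channels"):
            apply_csp(model, session_small_strong)

    def test_six_features_and_scaling_shift(self, session_small_strong):
        from sensebci import bandpass, extract_window
        win = extract_window(bandpass(session_small_strong, "broad"), 4, 7)
        model = fit_csp_from_session(win, n_pairs=3)
        Z = apply_csp(model, win)
        F = logvar_features(Z, n_pairs=3)
        assert F.shape == (win.n_trials, 6)
        scaled = Z.with_data(Z.data.copy())
        k = 3.0
        scaled.data[:, 0, :] *= k  # first selected component
        F2 = logvar_features(scaled, n_pairs=3)
        assert np.allclose(F2[:, 0] - F[:, 0], 2 * np.log(k))
        assert np.allclose(F2[:, 1:], F[:, 1:])

    def test_unit_variance_white_rows_give_zero_features(self):
        rng = np.random.default_rng(6)
        n_samples = 50_000
        s = make_session(rng.standard_normal((4, 6, n_samples)))
        F = logvar_features(s, n_pairs=3)
        # sample log-variance of N(0,1) concentrates at 0 with sd ~ sqrt(2/n)
        assert np.all(np.abs(F) < 5 * np.sqrt(2.0 / n_samples))

    def test_covariance_fast_path_matches_projection_path(self, session_small_strong):
        from sensebci import bandpass, extract_window
        win = extract_window(bandpass(session_small_strong, "broad"), 4, 7)
        model = fit_csp_from_session(win)
        slow = logvar_features(apply_csp(model, win), n_pairs=3)
        covs = np.stack([(x - x.mean(axis=1, keepdims=True))
                         @ (x - x.mean(axis=1, keepdims=True)).T / win.n_samples
                         for x in win.data])
        fast = features_from_covariances(model, covs)
        assert np.allclose(fast, slow, atol=1e-10)

    def test_zero_variance_component_rejected(self):
        data = np.concatenate(
            [np.random.default_rng(0).standard_normal((2, 5, 100)),
             np.zeros((2, 1, 100))], axis=1)
        s = make_session(data)
        with pytest.raises(ValueError, match="[Zz]ero-variance"):
            logvar_features(s, n_pairs=3)
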