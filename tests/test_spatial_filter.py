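"""CSP / RCSP: covariance estimation, factorization, projection."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmi.containers import Trial, TrialSet
from crossmi.spatial_filter import (
    BETA_GRID,
    GAMMA_GRID,
    fit_csp,
    fit_filters,
    fit_rcsp,
    mean_class_covariance,
    project_and_retain,
    regularized_class_covariance,
    trial_covariance,
)


def _spd(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


def _trials(rng, n, q=4, p=50, label=1):
    return [
        Trial(rng.normal(size=(q, p)), label, "S1", np.zeros((q, 8)), 100.0)
        for _ in range(n)
    ]


class TestTrialCovariance:
    def test_identity_trial(self):
        S = trial_covariance(np.eye(5))
        np.testing.assert_allclose(S, np.eye(5) / 5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(4, 50))
        np.testing.assert_allclose(
            trial_covariance(E), trial_covariance(-3.7 * E), atol=1e-12
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(4, 50))
        C = E @ E.T
        np.testing.assert_allclose(trial_covariance(E), C / np.trace(C))

    def test_unit_trace(self):
        rng = np.random.default_rng(2)
        S = trial_covariance(rng.normal(size=(6, 30)))
        assert abs(np.trace(S) - 1.0) < 1e-10

    def test_zero_trial_errors(self):
        with pytest.raises(ValueError):
            trial_covariance(np.zeros((3, 10)))


class TestRegularizedCovariance:
    def test_beta_gamma_zero_is_plain_mean(self):
        rng = np.random.default_rng(3)
        trials = _trials(rng, 6)
        S = regularized_class_covariance(trials, None, 0.0, 0.0)
        np.testing.assert_array_equal(S, mean_class_covariance(trials))

    def test_gamma_one_scaled_identity(self):
        rng = np.random.default_rng(4)
        trials = _trials(rng, 5)
        S = regularized_class_covariance(trials, None, 0.0, 1.0)
        omega = mean_class_covariance(trials)
        np.testing.assert_allclose(
            S, np.trace(omega) / 4 * np.eye(4), atol=1e-12
        )

    def test_beta_one_uses_generic_only(self):
        rng = np.random.default_rng(5)
        cls, gen = _trials(rng, 4), _trials(rng, 7)
        S = regularized_class_covariance(cls, gen, 1.0, 0.0)
        np.testing.assert_allclose(S, mean_class_covariance(gen), atol=1e-12)

    def test_beta_without_generic_errors(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            regularized_class_covariance(_trials(rng, 3), None, 0.5, 0.0)

    def test_parameter_range(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            regularized_class_covariance(_trials(rng, 3), None, -0.1, 0.0)

    def test_printed_grids(self):
        assert len(BETA_GRID) == 12 and len(GAMMA_GRID) == 11
        assert BETA_GRID[:4] == (0.0, 0.001, 0.01, 0.1)
        assert GAMMA_GRID[:3] == (0.0, 0.01, 0.1)


class TestFitFilters:
    def test_diagonalization_and_sum_to_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            S1, S2 = _spd(rng, 6), _spd(rng, 6)
            bank = fit_filters(S1, S2)
            W = bank.W
            D1 = W @ S1 @ W.T
            D2 = W @ S2 @ W.T
            assert np.abs(D1 - np.diag(np.diag(D1))).max() < 1e-8
            assert np.abs(D2 - np.diag(np.diag(D2))).max() < 1e-8
            assert np.abs(D1 + D2 - np.eye(6)).max() < 1e-8
            # eigenvalues sorted descending
            assert np.all(np.diff(bank.class1_eigenvalues) <= 1e-12)

    def test_generalized_eigenvector_oracle(self):
        """Rows of W match eig(S1, S1+S2) up to sign/scale (brute force)."""
        rng = np.random.default_rng(9)
        S1, S2 = _spd(rng, 3), _spd(rng, 3)
        bank = fit_filters(S1, S2)
        mu, V = sla.eigh(S1, S1 + S2)  # ascending
        V = V[:, ::-1]
        mu = mu[::-1]
        np.testing.assert_allclose(bank.class1_eigenvalues, mu, atol=1e-10)
        for i in range(3):
            w = bank.W[i]
            v = V[:, i]
            cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
            assert cos > 1 - 1e-8

    def test_equal_covariances_degenerate_case(self):
        bank = fit_filters(0.5 * np.eye(4), 0.5 * np.eye(4))
        np.testing.assert_allclose(bank.class1_eigenvalues, 0.5, atol=1e-12)
        np.testing.assert_allclose(
            bank.W @ np.eye(4) @ bank.W.T, np.eye(4), atol=1e-8
        )

    def test_singular_composite_errors(self):
        with pytest.raises(ValueError):
            fit_filters(np.zeros((3, 3)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 8))
    def test_sum_to_identity_property(self, seed, n):
        rng = np.random.default_rng(seed)
        S1, S2 = _spd(rng, n), _spd(rng, n)
        W = fit_filters(S1, S2).W
        assert np.abs(W @ (S1 + S2) @ W.T - np.eye(n)).max() < 1e-8


class TestCSPvsRCSP:
    def test_rcsp_zero_equals_csp_bitwise(self):
        rng = np.random.default_rng(10)
        c1 = TrialSet(_trials(rng, 6, label=1))
        c2 = TrialSet(_trials(rng, 6, label=2))
        a = fit_csp(c1, c2)
        b = fit_rcsp(c1, c2, beta=0.0, gamma=0.0)
        np.testing.assert_array_equal(a.W, b.W)

    def test_scale_invariance_of_filters(self):
        rng = np.random.default_rng(11)
        t1, t2 = _trials(rng, 5, label=1), _trials(rng, 5, label=2)
        s1 = [Trial(9.3 * t.data, t.label, "S1", t.baseline, 100.0) for t in t1]
        s2 = [Trial(9.3 * t.data, t.label, "S1", t.baseline, 100.0) for t in t2]
        a = fit_csp(TrialSet(t1), TrialSet(t2))
        b = fit_csp(TrialSet(s1), TrialSet(s2))
        np.testing.assert_allclose(a.W, b.W, atol=1e-10)


class TestProjectAndRetain:
    def test_four_channels_identity_retention(self):
        rng = np.random.default_rng(12)
        S1, S2 = _spd(rng, 4), _spd(rng, 4)
        bank = fit_filters(S1, S2)
        E = rng.normal(size=(4, 30))
        X = project_and_retain(E, bank)
        np.testing.assert_array_equal(X, bank.W @ E)  # all rows retained

    def test_identity_bank_returns_rows(self):
        from crossmi.spatial_filter import SpatialFilterBank

        bank = SpatialFilterBank(
            np.eye(6), np.ones(6), np.linspace(1, 0, 6), 0.0, 0.0
        )
        E = np.random.default_rng(13).normal(size=(6, 20))
        X = project_and_retain(E, bank)
        np.testing.assert_array_equal(X, E[[0, 1, 4, 5]])

    def test_class_variance_ordering(self):
        """First retained row captures class-1 variance, last row class-2."""
        rng = np.random.default_rng(14)
        # class 1 strong on channel 0, class 2 strong on channel 3
        def make(label, strong):
            scale = np.ones(4)
            scale[strong] = 6.0
            return TrialSet(
                [
                    Trial(scale[:, None] * rng.normal(size=(4, 100)), label,
                          "S1", np.zeros((4, 8)), 100.0)
                    for _ in range(12)
                ]
            )

        c1, c2 = make(1, 0), make(2, 3)
        bank = fit_csp(c1, c2)
        X1 = project_and_retain(c1[0].data, bank)
        X2 = project_and_retain(c2[0].data, bank)
        assert X1[0].var() > X1[-1].var()
        assert X2[-1].var() > X2[0].var()

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(15)
        bank = fit_filters(_spd(rng, 4), _spd(rng, 4))
        with pytest.raises(ValueError):
            project_and_retain(rng.normal(size=(5, 10)), bank)
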