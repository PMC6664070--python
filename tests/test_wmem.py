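"""Maximum-entropy-on-the-mean inverse solution: solver and pipeline."""

import numpy as np
import pytest
import scipy.linalg as sla

from crossmi.containers import Trial, TrialSet
from crossmi.preprocess import bandpass, window_trials
from crossmi.synth import SynthConfig, default_active_sets, simulate_subject_pair
from crossmi.wmem import (
    MEMReference,
    average_trials,
    build_reference,
    dual_value,
    estimate_noise_model,
    localize,
    mem_solve,
    parcellate,
    prelocalize,
    soft_shrink,
)


def _trial(data, label=1, fs=100.0):
    q = data.shape[0]
    return Trial(data, label, "S1", np.zeros((q, 8)), fs)


class TestAverage:
    def test_identical_trials(self):
        d = np.random.default_rng(0).normal(size=(3, 20))
        ts = TrialSet([_trial(d), _trial(d)])
        np.testing.assert_allclose(average_trials(ts, 1).data, d)

    def test_symmetric_cancellation(self):
        d = np.random.default_rng(1).normal(size=(3, 20))
        ts = TrialSet([_trial(d), _trial(-d)])
        assert np.abs(average_trials(ts, 1).data).max() < 1e-12

    def test_noise_shrinks_like_sqrt_n(self):
        """RMS error of a 140-trial average vs. a single noisy trial ~ sqrt(140)."""
        rng = np.random.default_rng(2)
        template = rng.normal(size=(4, 50))
        trials = TrialSet(
            [_trial(template + rng.normal(size=(4, 50))) for _ in range(140)]
        )
        err_avg = np.std(average_trials(trials, 1).data - template)
        err_one = np.std(trials[0].data - template)
        ratio = err_one / err_avg
        assert np.sqrt(140) / 1.5 < ratio < np.sqrt(140) * 1.5

    def test_empty_class_errors(self):
        ts = TrialSet([_trial(np.ones((2, 10)), label=1)])
        with pytest.raises(ValueError):
            average_trials(ts, 2)


class TestSoftShrink:
    @pytest.mark.parametrize(
        "w,tau,expected", [(2.0, 1.0, 1.0), (0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)]
    )
    def test_formula_cases(self, w, tau, expected):
        assert soft_shrink(w, tau) == expected

    def test_vectorized_and_properties(self):
        w = np.linspace(-5, 5, 101)
        out = soft_shrink(w, 1.5)
        assert np.all(np.sign(out) * np.sign(w) >= 0)
        assert np.all(np.abs(out) <= np.abs(w))
        assert np.all(out[np.abs(w) <= 1.5] == 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_shrink(1.0, -0.1)


class TestNoiseModel:
    def test_universal_threshold_white_noise(self):
        """tau_ch averages to sigma*sqrt(2 ln N) within 15% (Monte Carlo)."""
        sigma, N = 2.0, 256
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(100):
            data = sigma * rng.standard_normal((2, N))
            nm = estimate_noise_model([sigma * rng.standard_normal((2, 64))], data)
            taus.append(nm.tau)
        expected = sigma * np.sqrt(2 * np.log(N))
        assert abs(np.mean(taus) - expected) / expected < 0.15

    def test_whitener_identity_for_white_noise(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((4, 4000))
        nm = estimate_noise_model([base])
        assert np.abs(nm.whitener - np.eye(4)).max() < 0.1
        # W Sigma W' ~ I on the retained subspace
        assert np.abs(nm.whitener @ nm.covariance @ nm.whitener.T - np.eye(4)).max() < 1e-8

    def test_degenerate_correlated_channels(self):
        rng = np.random.default_rng(5)
        row = rng.standard_normal(500)
        nm = estimate_noise_model([np.vstack([row, row])])  # rank 1
        assert np.all(np.isfinite(nm.whitener))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            estimate_noise_model([np.zeros((2, 8))])


class TestPrelocalize:
    def test_single_source_peaks_at_truth(self, head16):
        s0 = 17
        M = np.outer(head16.lead_field[:, s0], np.sin(np.linspace(0, 9, 40)))
        m = prelocalize(M, head16)
        assert int(np.argmax(m)) == s0

    def test_orthogonal_column_scores_zero(self, head16):
        g0 = head16.lead_field[:, 0]
        v = np.random.default_rng(0).normal(size=16)
        v -= (v @ g0) / (g0 @ g0) * g0  # data orthogonal to source 0's column
        m = prelocalize(np.outer(v, np.ones(20)), head16)
        assert m[0] < 1e-12

    def test_bounded_scores(self, head16):
        M = np.random.default_rng(1).normal(size=(16, 30))
        m = prelocalize(M, head16)
        assert np.all((m >= 0) & (m <= 1))

    def test_zero_data_warns_zero(self, head16):
        assert np.all(prelocalize(np.zeros((16, 10)), head16) == 0)


class TestParcellate:
    def test_two_bumps_two_parcels(self, head16):
        pos = head16.source_positions
        c1, c2 = pos[5], pos[50]
        scores = np.exp(-8 * np.linalg.norm(pos - c1, axis=1) ** 2)
        scores += np.exp(-8 * np.linalg.norm(pos - c2, axis=1) ** 2)
        parc = parcellate(head16, scores, K_target=2)
        assert parc.n_parcels == 2
        labels = {parc.labels[5], parc.labels[50]}
        assert -1 not in labels and len(labels) == 2

    def test_uniform_scores_deterministic(self, head16):
        scores = np.full(head16.n_sources, 0.5)
        p1 = parcellate(head16, scores, K_target=4)
        p2 = parcellate(head16, scores, K_target=4)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        # tie rule: the single seed is the lowest index
        assert p1.labels[0] == 0

    def test_disjoint_and_coverage(self, head16):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=head16.n_sources)
        parc = parcellate(head16, scores, K_target=5, score_floor=0.3)
        seen = np.concatenate(parc.parcels)
        assert len(seen) == len(set(seen.tolist()))  # disjoint
        unassigned = np.flatnonzero(parc.labels == -1)
        assert len(seen) + len(unassigned) == head16.n_sources
        assert np.all(scores[unassigned] < 0.3)
        assert np.all((parc.alpha > 0) & (parc.alpha < 1))

    def test_k_target_validation(self, head16):
        with pytest.raises(ValueError):
            parcellate(head16, np.ones(head16.n_sources), K_target=0)
        with pytest.raises(ValueError):
            parcellate(head16, np.ones(head16.n_sources), K_target=60)


def _random_reference(rng, r=15, parcel_size=5, alpha=None):
    parcels = [np.arange(i, i + parcel_size) for i in range(0, r, parcel_size)]
    covs = []
    for _ in parcels:
        A = rng.normal(size=(parcel_size, parcel_size))
        covs.append(A @ A.T / parcel_size + np.eye(parcel_size))
    K = len(parcels)
    a = np.full(K, 0.5) if alpha is None else np.full(K, alpha)
    return MEMReference(parcels, a, covs)


class TestMEMSolve:
    def test_zero_data_zero_solution(self):
        rng = np.random.default_rng(0)
        ref = _random_reference(rng)
        G = rng.normal(size=(6, 15))
        sol = mem_solve(np.zeros(6), G, ref)
        assert np.abs(sol.w_star).max() == 0.0
        np.testing.assert_allclose(sol.alpha_post, 0.5)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_gaussian_limit_matches_closed_form(self, seed):
        """All parcels active: MEM = minimum-norm Gaussian solution."""
        rng = np.random.default_rng(seed)
        q, r = 6, 15
        ref = _random_reference(rng, r=r, alpha=1.0)
        G = rng.normal(size=(q, r))
        d = rng.normal(size=q)
        sol = mem_solve(d, G, ref, eta=1.0, grad_tol=1e-10)
        SJ = sla.block_diag(*ref.covariances)
        oracle = SJ @ G.T @ np.linalg.solve(G @ SJ @ G.T + np.eye(q), d)
        np.testing.assert_allclose(sol.w_star, oracle, atol=1e-6)
        assert sol.converged

    def test_active_parcel_concentrates_energy(self, head16):
        """High-SNR data from one parcel: that parcel dominates w* energy."""
        rng = np.random.default_rng(9)
        scores = rng.uniform(0.2, 0.4, size=head16.n_sources)
        parc = parcellate(head16, scores, K_target=4)
        ref = build_reference(head16, parc, sigma2=1.0)
        true_pid = 1
        idx = ref.parcels[true_pid]
        j = np.zeros(head16.n_sources)
        j[idx] = 5.0
        d = head16.lead_field @ j + 0.01 * rng.normal(size=16)
        sol = mem_solve(d, head16.lead_field, ref, eta=1.0)
        energies = np.array([np.sum(sol.w_star[p] ** 2) for p in ref.parcels])
        assert int(np.argmax(energies)) == true_pid
        assert energies[true_pid] > energies.sum() - energies[true_pid]

    def test_dual_concavity_along_segments(self):
        """Second differences of D along random lines are non-positive."""
        rng = np.random.default_rng(11)
        ref = _random_reference(rng, alpha=0.3)
        G = rng.normal(size=(6, 15))
        d = rng.normal(size=6)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6) * 0.5
            vals = [dual_value(a + t * b, d, G, ref) for t in np.linspace(-1, 1, 9)]
            second = np.diff(vals, 2)
            assert np.all(second <= 1e-8)

    def test_entropy_nonpositive_discrete(self):
        """S_mu(f) = -KL(f mu || mu) <= 0, equality iff f == 1."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            mu = rng.dirichlet(np.ones(8))
            p = rng.dirichlet(np.ones(8))
            f = p / mu
            S = -np.sum(mu * f * np.log(f))
            assert S <= 1e-12
        f1 = np.ones(8)
        mu = rng.dirichlet(np.ones(8))
        assert abs(-np.sum(mu * f1 * np.log(f1))) < 1e-15

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(0)
        ref = _random_reference(rng)
        with pytest.raises(ValueError):
            mem_solve(np.zeros(4), rng.normal(size=(6, 15)), ref)


class TestLocalize:
    def test_zero_input_zero_energy(self, head16):
        rng = np.random.default_rng(0)
        z = TrialSet(
            [
                Trial(np.zeros((16, 64)), 1, "S1",
                      rng.standard_normal((16, 40)), 100.0)
                for _ in range(2)
            ]
        )
        est = localize(z, 1, head16, levels=3)
        assert np.all(est.energy == 0)
        assert est.skipped_fraction == 1.0

    def test_single_source_recovery(self, head32):
        cfg = SynthConfig(
            n_trials_per_class=20, rng_seed=101, target_snr=10.0,
            n_active_per_class=1,
        )
        X, _ = simulate_subject_pair(head32, cfg)
        X = window_trials(bandpass(X))
        act = default_active_sets(head32, cfg)
        est = localize(X, 1, head32)
        peak = int(np.argmax(est.energy))
        true = act[1][0][0]
        assert est.parcellation.labels[peak] == est.parcellation.labels[true] != -1

    def test_noise_only_mostly_skipped(self, head32):
        rng = np.random.default_rng(5)
        noise = TrialSet(
            [
                Trial(rng.standard_normal((32, 250)), 1, "S1",
                      rng.standard_normal((32, 50)), 100.0)
                for _ in range(20)
            ]
        )
        est_noise = localize(noise, 1, head32)
        assert est_noise.skipped_fraction >= 0.8

        cfg = SynthConfig(n_trials_per_class=20, rng_seed=6, target_snr=10.0)
        X, _ = simulate_subject_pair(head32, cfg)
        est_sig = localize(window_trials(bandpass(X)), 1, head32)
        assert est_sig.energy.sum() > 10 * est_noise.energy.sum()

    def test_energy_map_invariants(self, head32, pair32):
        X, _, _ = pair32
        est = localize(X, 1, head32)
        assert np.all(est.energy >= 0) and np.all(np.isfinite(est.energy))
        total = sum(v.sum() for v in est.per_scale_energy.values())
        assert np.isclose(total, est.energy.sum())
        # time courses exist and invert the stored stack shape
        J = est.time_courses()
        assert J.shape == (head32.n_sources, X.n_samples)
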