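"""HMM estimation, stationary routes, model selection machinery."""

import numpy as np
import pytest

from gatescape.markov import (
    DegenerateStateError,
    chapman_kolmogorov,
    cluster_assign,
    estimate_hmm,
    fractional_uncertainty,
    leading_eigenvector_pair,
    match_states,
    rmsd_measure,
    sample_representative_frames,
    selection_score,
    stationary_two_routes,
    state_posteriors,
)


class TestClustering:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, size=(500, 2))
        b = rng.normal(5.0, 0.1, size=(500, 2))
        dtraj, centers = cluster_assign(np.vstack([a, b]), n_clusters=2, seed=1)
        first, second = dtraj[:500], dtraj[500:]
        purity = max(np.mean(first == 0), np.mean(first == 1))
        assert purity >= 0.99
        assert np.mean(second == (1 - round(np.mean(first)))) >= 0.99

    def test_each_point_its_own_cluster(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 3))
        dtraj, centers = cluster_assign(x, n_clusters=20, seed=3)
        assert len(set(dtraj.tolist())) == 20

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 2))
        a, _ = cluster_assign(x, n_clusters=8, seed=5)
        b, _ = cluster_assign(x, n_clusters=8, seed=5)
        assert np.array_equal(a, b)

    def test_rejects_more_clusters_than_frames(self):
        with pytest.raises(ValueError):
            cluster_assign(np.zeros((5, 2)), n_clusters=10, seed=0)


class TestStationaryRoutes:
    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        mu, nu = stationary_two_routes(T)
        assert np.allclose(mu, [2 / 3, 1 / 3], atol=1e-10)
        assert np.allclose(nu, [2 / 3, 1 / 3], atol=1e-10)

    def test_doubly_stochastic_gives_uniform(self):
        T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        T = 0.7 * T + 0.3 * np.eye(3)
        mu, nu = stationary_two_routes(T)
        assert np.allclose(mu, 1 / 3, atol=1e-10)
        assert np.allclose(nu, 1 / 3, atol=1e-10)

    def test_defining_property_on_random_chains(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            T = rng.dirichlet(np.ones(5), size=5)
            mu, nu = stationary_two_routes(T)
            assert np.max(np.abs(mu @ T - mu)) < 1e-10
            assert np.max(np.abs(nu @ T - nu)) < 1e-10

    def test_reducible_chain_rejected(self):
        T = np.eye(3)
        with pytest.raises(ValueError):
            stationary_two_routes(T)


class TestFractionalUncertainty:
    def test_identical_vectors(self):
        assert fractional_uncertainty([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_forced_arithmetic(self):
        f = fractional_uncertainty([0.5, 0.5], [0.4, 0.6])
        assert f == pytest.approx(0.2)

    def test_degenerate_state_raises(self):
        with pytest.raises(DegenerateStateError):
            fractional_uncertainty([0.0, 1.0], [0.5, 0.5])

    def test_selection_score_measures_population_nonuniformity(self):
        # doubly stochastic chain: left and right eigenvectors coincide
        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        assert selection_score(T) < 1e-10
        # skewed chain: score equals mean |pi - 1/N| / pi
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        mu, nu = leading_eigenvector_pair(T)
        assert np.allclose(nu, 0.5, atol=1e-10)
        assert selection_score(T) == pytest.approx(
            np.mean(np.abs(mu - 0.5) / mu), abs=1e-12)


class TestEstimation:
    def test_single_state_model(self):
        d = np.array([0, 1, 0, 1, 1, 0, 1] * 20)
        m = estimate_hmm([d], 1, lag=1.0, seed=0)
        assert np.allclose(m.transition, [[1.0]])
        assert np.allclose(m.stationary, [1.0])

    def test_alternating_sequence_gives_flip_chain(self):
        d = np.tile([0, 1], 500)
        m = estimate_hmm([d], 2, lag=1.0, seed=1)
        T = m.transition
        off = sorted([T[0, 1], T[1, 0]])
        assert off[0] > 1 - 1e-3 and off[1] > 1 - 1e-3

    def test_parameter_recovery_2state(self, gt2, traj2):
        dtraj = traj2.hidden_path  # perfectly discretized observations
        m = estimate_hmm([dtraj], 2, lag=1.0, seed=2, max_iter=100)
        # align states: state 0 emits symbol 0
        order = np.argsort(np.argmax(m.emission, axis=1))
        Trec = m.transition[np.ix_(order, order)]
        assert np.max(np.abs(Trec - gt2.transition)) < 0.02

    def test_row_stochastic_and_stationary(self, traj2):
        m = estimate_hmm([traj2.hidden_path], 2, lag=1.0, seed=3)
        assert np.allclose(m.transition.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(m.emission.sum(axis=1), 1.0, atol=1e-10)
        assert np.max(np.abs(m.stationary @ m.transition - m.stationary)) < 1e-8

    def test_rejects_bad_lag(self, traj2):
        with pytest.raises(ValueError):
            estimate_hmm([traj2.hidden_path], 2, lag=0.5, dt=1.0)


class TestStateMatching:
    def test_permuted_emissions_matched(self):
        rng = np.random.default_rng(7)
        B = rng.dirichlet(np.ones(8), size=4)
        perm = np.array([2, 0, 3, 1])
        p = match_states(B, B[perm])
        assert np.allclose(B[perm][p], B)


class TestRepresentativeSampling:
    def test_deterministic_emissions_keep_frames_in_state(self, gt2, traj2):
        d = traj2.hidden_path
        m = estimate_hmm([d], 2, lag=1.0, seed=4)
        owner = np.argmax(m.emission, axis=0)  # symbol -> state
        samples = sample_representative_frames(m, [d], n_per_state=50, seed=5)
        for s, idx in enumerate(samples):
            assert np.all(owner[d[idx]] == s)

    def test_zero_samples(self, traj2):
        m = estimate_hmm([traj2.hidden_path], 2, lag=1.0, seed=6)
        samples = sample_representative_frames(m, [traj2.hidden_path], 0, seed=0)
        assert all(len(s) == 0 for s in samples)

    def test_sampling_frequency_tracks_posterior_weight(self, traj2):
        m = estimate_hmm([traj2.hidden_path], 2, lag=1.0, seed=7)
        gam = np.vstack(state_posteriors(m, [traj2.hidden_path]))
        n_draws = 10_000
        samples = sample_representative_frames(m, [traj2.hidden_path],
                                               n_draws, seed=8)
        w = gam[:, 0] / gam[:, 0].sum()
        counts = np.bincount(samples[0], minlength=len(w))
        # aggregate check: state-0-heavy half of frames gets its share within 3 SE
        heavy = w > np.median(w)
        p = w[heavy].sum()
        se = np.sqrt(p * (1 - p) / n_draws)
        assert abs(counts[heavy].sum() / n_draws - p) < 3 * se + 1e-9


class TestChapmanKolmogorov:
    def test_markov_data_self_consistency(self, gt2, traj2):
        m = estimate_hmm([traj2.hidden_path], 2, lag=1.0, seed=9, max_iter=100)
        table = chapman_kolmogorov(m, [traj2.hidden_path], multiples=range(2, 5),
                                   seed=10)
        assert len(table) == 3
        assert table.max_abs_discrepancy.max() < 0.03

    def test_iid_observations_give_rank_one_chain(self):
        rng = np.random.default_rng(11)
        d = rng.choice(4, p=[0.4, 0.3, 0.2, 0.1], size=50_000)
        m = estimate_hmm([d], 2, lag=1.0, seed=12, max_iter=50)
        # with no dynamics the rows of T coincide, so T^k = T for every k
        T = m.transition
        for k in (2, 3, 5):
            assert np.max(np.abs(np.linalg.matrix_power(T, k) - T)) < 0.05


class TestRmsdMeasure:
    def test_identical_frames_give_zero(self):
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert rmsd_measure([np.stack([frame] * 5), np.stack([frame] * 5)]) == \
            pytest.approx(0.0, abs=1e-10)

    @staticmethod
    def _kabsch(P, Q):
        """Independent SVD-based rigid superposition of P onto Q."""
        P = P - P.mean(axis=0)
        Q = Q - Q.mean(axis=0)
        U, _, Vt = np.linalg.svd(P.T @ Q)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        return (R @ P.T).T

    def test_matches_direct_per_frame_oracle(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(4, 3))
        frames = [base + rng.normal(0, 0.01, size=(4, 3)) for _ in range(10)]
        per_state = [np.stack(frames[:5]), np.stack(frames[5:])]
        result = rmsd_measure(per_state)
        # oracle: same two-pass mean-reference procedure, independent rotation solver
        ref = frames[0] - frames[0].mean(axis=0)
        for _ in range(2):
            aligned = np.stack([self._kabsch(f, ref) for f in frames])
            ref = aligned.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=2), axis=1)).sum() / 2
        assert result == pytest.approx(oracle, abs=1e-10)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            rmsd_measure([np.zeros((1, 4, 3))])
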