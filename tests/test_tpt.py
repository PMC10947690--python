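"""State labeling, open probabilities and transition path theory."""

import numpy as np
import pytest

from gatescape._channels import CHANNELS
from gatescape.markov import estimate_hmm
from gatescape.synthetic import simulate_feature_trajectory
from gatescape.tpt import (
    StateLabeling,
    boundary_scan,
    label_states,
    open_probability,
    tpt_flux,
)

# printed 10-state reference: per-channel open/closed label per state and
# the equilibrium population of each state
REF_LABELS = [  # rows: states 1..10; columns: 2a 2b 2c 2e 3 S
    "COOCOC", "OOCCOO", "OOCCCC", "OOCCCC", "OOOCOC",
    "CCOOCO", "OOOCOO", "OCOOCC", "CCCCCC", "OOCCCO",
]
REF_POPULATIONS = [0.071, 0.081, 0.072, 0.140, 0.070,
                   0.081, 0.062, 0.090, 0.167, 0.166]
REF_OPEN_PROB = {"2a": 0.681, "2b": 0.662, "2c": 0.374,
                 "2e": 0.171, "3": 0.284, "S": 0.390}


def reference_labeling(boundary=0.5):
    means = np.where(np.array([[c == "O" for c in row] for row in REF_LABELS]),
                     0.65, 0.40)
    return StateLabeling(boundary=boundary, state_means=means,
                         labels=means > boundary)


class TestLabeling:
    def test_open_iff_strictly_above_boundary(self, gt2, traj2):
        m = estimate_hmm([traj2.hidden_path], 2, lag=1.0, seed=0)
        lab = label_states(m, [traj2.hidden_path], [traj2], boundary=0.5)
        order = np.argsort(lab.state_means[:, 0])
        # closed state ~0.40 nm, open state ~0.65 nm in every channel
        assert np.allclose(lab.state_means[order[0]], 0.40, atol=0.02)
        assert np.allclose(lab.state_means[order[1]], 0.65, atol=0.02)
        assert not lab.labels[order[0]].any()
        assert lab.labels[order[1]].all()

    def test_boundary_tie_counts_closed(self):
        lab = StateLabeling(boundary=0.5,
                            state_means=np.full((3, 6), 0.5),
                            labels=np.full((3, 6), 0.5) > 0.5)
        assert not lab.labels.any()


class TestOpenProbability:
    def test_reference_table_marginals(self):
        probs = open_probability(reference_labeling(), REF_POPULATIONS)
        for c in CHANNELS:
            assert probs[c] == pytest.approx(REF_OPEN_PROB[c], abs=5e-4)

    def test_all_states_open_sums_to_one(self):
        lab = StateLabeling(boundary=0.3, state_means=np.full((4, 6), 0.6),
                            labels=np.full((4, 6), True))
        probs = open_probability(lab, np.full(4, 0.25))
        assert all(v == pytest.approx(1.0) for v in probs.values())


class TestTptFlux:
    def test_two_state_closed_form(self):
        res = tpt_flux([[0.9, 0.1], [0.2, 0.8]], [2 / 3, 1 / 3], [0], [1])
        assert res.total_flux == pytest.approx(1 / 15, abs=1e-12)
        assert res.forward_committor[0] == 0.0
        assert res.forward_committor[1] == 1.0

    def test_absorbing_source_has_zero_flux(self):
        T = np.array([[1.0, 0.0, 0.0],
                      [0.5, 0.25, 0.25],
                      [0.0, 0.5, 0.5]])
        pi = np.array([1.0, 0.0, 0.0])
        res = tpt_flux(T, pi, [0], [2])
        assert res.total_flux == pytest.approx(0.0, abs=1e-15)

    def test_committor_matches_monte_carlo_first_passage(self):
        rng = np.random.default_rng(1)
        T = rng.dirichlet(np.ones(6) * 2, size=6)
        w, V = np.linalg.eig(T.T)
        mu = np.real(V[:, np.argmin(np.abs(w - 1))])
        mu = np.abs(mu) / np.abs(mu).sum()
        A, B = [0], [5]
        res = tpt_flux(T, mu, A, B)
        n_walkers = 20_000
        cum = np.cumsum(T, axis=1)
        for start in [1, 3]:
            hits = 0
            state = np.full(n_walkers, start)
            active = np.ones(n_walkers, bool)
            for _ in range(500):
                if not active.any():
                    break
                u = rng.random(active.sum())
                nxt = np.array([np.searchsorted(cum[s], x)
                                for s, x in zip(state[active], u)])
                state[active] = nxt
                hit_b = active.copy()
                hit_b[active] = nxt == 5
                hit_a = active.copy()
                hit_a[active] = nxt == 0
                hits += hit_b.sum()
                active &= ~(hit_a | hit_b)
            p_mc = hits / n_walkers
            se = np.sqrt(p_mc * (1 - p_mc) / n_walkers)
            assert abs(res.forward_committor[start] - p_mc) < 3 * se + 1e-6

    def test_flux_conservation_at_intermediates(self):
        rng = np.random.default_rng(2)
        T = rng.dirichlet(np.ones(6), size=6)
        w, V = np.linalg.eig(T.T)
        mu = np.real(V[:, np.argmin(np.abs(w - 1))])
        mu = np.abs(mu) / np.abs(mu).sum()
        res = tpt_flux(T, mu, [0, 1], [4, 5])
        F = res.gross_flux
        net = F - F.T
        for i in [2, 3]:  # intermediate states: net inflow equals net outflow
            assert abs(net[i, :].sum()) < 1e-10
        # flux out of A equals flux into B
        out_A = net[np.ix_([0, 1], [2, 3, 4, 5])].sum()
        into_B = net[np.ix_([0, 1, 2, 3], [4, 5])].sum()
        assert out_A == pytest.approx(into_B, abs=1e-10)

    def test_rejects_bad_macrostates(self):
        T = [[0.9, 0.1], [0.2, 0.8]]
        with pytest.raises(ValueError):
            tpt_flux(T, [0.5, 0.5], [], [1])
        with pytest.raises(ValueError):
            tpt_flux(T, [0.5, 0.5], [0], [0])


@pytest.fixture(scope="module")
def fitted(gt2):
    trajs = [simulate_feature_trajectory(gt2, 10_000, seed=30 + i)
             for i in range(2)]
    dtrajs = [t.hidden_path for t in trajs]
    models = [estimate_hmm(dtrajs, 2, lag=1.0, seed=40 + i)
              for i in range(3)]
    return models, dtrajs, trajs


class TestBoundaryScan:
    def test_single_model_has_zero_sd(self, fitted):
        models, dtrajs, trajs = fitted
        df = boundary_scan(models[:1], dtrajs, trajs,
                           boundaries=[0.5])
        for c in CHANNELS:
            assert df[f"flux_sd_{c}"].iloc[0] == 0.0

    def test_flux_constant_between_emission_means(self, fitted):
        # state means at 0.40/0.65 nm: any boundary strictly between them
        # yields the same one-vs-one macrostate split, hence identical flux
        models, dtrajs, trajs = fitted
        df = boundary_scan(models, dtrajs, trajs,
                           boundaries=[0.45, 0.50, 0.55, 0.60])
        for c in CHANNELS:
            assert df[f"flux_mean_{c}"].std() == pytest.approx(0.0, abs=1e-12)

    def test_boundary_below_all_means_is_missing(self, fitted):
        models, dtrajs, trajs = fitted
        with pytest.warns(UserWarning):
            df = boundary_scan(models, dtrajs, trajs, boundaries=[0.2])
        assert df[[f"flux_mean_{c}" for c in CHANNELS]].isna().all().all()
        assert len(df.attrs["missing"]) == len(CHANNELS) * len(models)
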