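"""Discrete-observation hidden Markov models of clustered TICA coordinates.

The pipeline discretizes projected features by k-means, estimates a
discrete-emission HMM by expectation-maximization at a chosen lag time,
and selects the cluster count, lag and state count by the fractional
uncertainty

    f = ( sum_i |mu_i - nu_i| / mu_i ) / N                       (score)

computed from the left (mu) and right (nu) eigenvectors of the estimated
transition matrix at eigenvalue 1, each normalized to unit sum.  Since
the right eigenvector of a row-stochastic matrix is the ones vector, nu
is uniform and f scores how far the equilibrium populations deviate from
uniform occupancy; the score is zero exactly when the transition matrix
is doubly stochastic.  Across many seeded replicate models the mean f
attains a minimum at a state count whose metastable decomposition is
balanced — over-split models carry starved states, merged models carry
bloated ones.

A second, purely numerical reading of the same formula — mu and nu as
two independent numerical routes to the stationary vector — is provided
by :func:`stationary_two_routes` and serves as a self-consistency check
on converged models (f below ~1e-8 for any well-conditioned chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from hmmlearn.hmm import CategoricalHMM
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .tica import tica_fit, tica_project


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_assign(coords, n_clusters: int = 64, seed: int = 0):
    """k-means discretization of (lists of) coordinate arrays.

    Returns ``(dtrajs, centers)`` where ``dtrajs`` mirrors the input list
    structure.  Seeding is k-means++ and fully determined by ``seed``.
    """
    single = not isinstance(coords, (list, tuple))
    arrays = [np.atleast_2d(np.asarray(c, float))
              for c in ([coords] if single else coords)]
    arrays = [a.T if a.shape[0] == 1 and a.size > 1 else a for a in arrays]
    stacked = np.vstack(arrays)
    if stacked.shape[0] < n_clusters:
        raise ValueError("fewer frames than clusters")
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=5).fit(stacked)
    labels = km.labels_.astype(np.int64)
    dtrajs, i = [], 0
    for a in arrays:
        dtrajs.append(labels[i:i + a.shape[0]])
        i += a.shape[0]
    return (dtrajs[0] if single else dtrajs), km.cluster_centers_


# ---------------------------------------------------------------------------
# stationary vectors and the fractional-uncertainty score
# ---------------------------------------------------------------------------

def _check_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -1e-12) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("transition matrix must be row-stochastic")
    return T


def _require_irreducible(T: np.ndarray) -> None:
    n, _ = connected_components(T > 0, directed=True, connection="strong")
    if n != 1:
        raise ValueError("transition matrix is reducible")


def stationary_two_routes(T) -> tuple[np.ndarray, np.ndarray]:
    """Two independent numerical routes to the stationary distribution.

    ``mu``: left eigenvector of T at the eigenvalue closest to 1 (dense
    eigensolver), normalized to unit sum.  ``nu``: least-squares solution
    of the null-space system (T' - I) x = 0 with the unit-sum constraint
    appended.  Their disagreement measures numerical self-consistency.
    """
    T = _check_stochastic(T)
    _require_irreducible(T)
    n = T.shape[0]
    w, V = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    mu = np.real(V[:, i])
    mu = np.abs(mu) / np.abs(mu).sum()
    A = np.vstack([T.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    nu, *_ = np.linalg.lstsq(A, b, rcond=None)
    return mu, nu


def leading_eigenvector_pair(T) -> tuple[np.ndarray, np.ndarray]:
    """Left and right eigenvectors of T at eigenvalue 1, each unit-sum.

    The left vector is the stationary distribution; the right vector of a
    row-stochastic matrix is constant, so its unit-sum normalization is the
    uniform distribution (computed numerically, not assumed).
    """
    T = _check_stochastic(T)
    _require_irreducible(T)
    wl, Vl = scipy.linalg.eig(T.T)
    mu = np.real(Vl[:, int(np.argmin(np.abs(wl - 1.0)))])
    mu = np.abs(mu) / np.abs(mu).sum()
    wr, Vr = scipy.linalg.eig(T)
    nu = np.real(Vr[:, int(np.argmin(np.abs(wr - 1.0)))])
    nu = np.abs(nu) / np.abs(nu).sum()
    return mu, nu


class DegenerateStateError(ValueError):
    """Stationary weight of one or more states at or below the floor."""

    def __init__(self, states):
        self.states = list(states)
        super().__init__(f"degenerate states with stationary weight <= floor: {self.states}")


def fractional_uncertainty(mu, nu, floor: float = 1e-12) -> float:
    """Mean relative discrepancy f = (sum_i |mu_i - nu_i| / mu_i) / N.

    Zero iff the two vectors coincide; states with mu_i at or below
    ``floor`` raise :class:`DegenerateStateError` rather than silently
    inflating the score.
    """
    mu = np.asarray(mu, float)
    nu = np.asarray(nu, float)
    if mu.shape != nu.shape:
        raise ValueError("vector length mismatch")
    bad = np.flatnonzero(mu <= floor)
    if bad.size:
        raise DegenerateStateError(bad)
    return float(np.mean(np.abs(mu - nu) / mu))


def selection_score(T) -> float:
    """Fractional uncertainty of the left/right eigenvector pair of T."""
    return fractional_uncertainty(*leading_eigenvector_pair(T))


# ---------------------------------------------------------------------------
# HMM estimation
# ---------------------------------------------------------------------------

@dataclass
class HiddenMarkovModel:
    """Discrete-emission HMM estimated at a fixed lag time."""

    n_states: int
    lag: float  # ps
    stride: int  # frames between strided observations
    transition: np.ndarray  # (n_states, n_states) row-stochastic
    emission: np.ndarray  # (n_states, n_symbols) row-stochastic
    startprob: np.ndarray
    stationary: np.ndarray  # stationary vector of `transition`
    log_likelihood: float
    converged: bool = True

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[1]


def _count_matrix(dtrajs, n_symbols: int) -> np.ndarray:
    C = np.zeros((n_symbols, n_symbols))
    for d in dtrajs:
        np.add.at(C, (d[:-1], d[1:]), 1.0)
    return C


def _spectral_initialization(dtrajs, n_states: int, n_symbols: int, rng,
                             perturbation: float = 0.1):
    """Initial (startprob, T, B) from a cluster-level Markov model.

    A maximum-likelihood Markov model on the discrete clusters is
    coarse-grained to ``n_states`` metastable groups by k-means in the
    space of its leading right eigenvectors (a PCCA-style split), giving
    deterministic aggregate transition and emission matrices; replicate
    diversity comes from multiplicative log-normal perturbation of the
    emissions re-seeded per replicate.
    """
    C = _count_matrix(dtrajs, n_symbols) + 1e-4
    pops = C.sum(axis=1)
    T_micro = C / pops[:, None]
    if n_states == 1:
        groups = np.zeros(n_symbols, dtype=int)
    else:
        w, V = scipy.linalg.eig(T_micro)
        order = np.argsort(-np.real(w))
        comps = np.real(V[:, order[:n_states]])
        comps = comps / np.maximum(np.abs(comps).max(axis=0), 1e-12)
        km = KMeans(n_clusters=n_states, n_init=5,
                    random_state=int(rng.integers(2**31))).fit(comps)
        groups = km.labels_
        # guarantee every macro state owns at least one cluster
        for s in range(n_states):
            if not np.any(groups == s):
                groups[int(rng.integers(n_symbols))] = s
    member = np.zeros((n_states, n_symbols))
    member[groups, np.arange(n_symbols)] = 1.0
    C_macro = member @ C @ member.T
    T0 = C_macro / C_macro.sum(axis=1, keepdims=True)
    B0 = member * pops[None, :]
    if perturbation > 0:
        B0 = B0 * np.exp(rng.normal(0.0, perturbation, size=B0.shape))
    B0 = B0 + 1e-6
    B0 /= B0.sum(axis=1, keepdims=True)
    T0 = 0.98 * T0 + 0.02 / n_states
    start = member @ pops
    start = start / start.sum()
    return start, T0, B0


def _to_hmmlearn(hmm: HiddenMarkovModel) -> CategoricalHMM:
    m = CategoricalHMM(n_components=hmm.n_states, n_features=hmm.n_symbols,
                       init_params="", params="")
    m.startprob_ = np.asarray(hmm.startprob, float)
    m.transmat_ = np.asarray(hmm.transition, float)
    m.emissionprob_ = np.asarray(hmm.emission, float)
    return m


def estimate_hmm(dtrajs, n_states: int, lag: float = 1.0, seed: int = 0,
                 max_iter: int = 200, tol: float = 1e-4, dt: float = 1.0,
                 n_symbols: int | None = None,
                 init_perturbation: float = 0.1) -> HiddenMarkovModel:
    """Baum-Welch estimation of a discrete-emission HMM on strided observations.

    ``dtrajs`` are integer cluster trajectories at frame resolution; they
    are strided by ``lag/dt`` before estimation (unconditional stride).
    Initialization coarse-grains a cluster-level Markov model spectrally;
    EM then refines it with a monotonically non-decreasing log-likelihood.
    Non-convergence at ``max_iter`` flags the model, it does not fail.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, np.int64) for d in dtrajs]
    stride = int(round(lag / dt))
    if stride < 1 or abs(lag / dt - stride) > 1e-9:
        raise ValueError("lag must be a positive multiple of dt")
    strided = [d[::stride] for d in dtrajs]
    if any(len(s) < 2 for s in strided):
        raise ValueError("every trajectory must be longer than the lag")
    if n_symbols is None:
        n_symbols = int(max(d.max() for d in dtrajs)) + 1
    if n_states > n_symbols:
        raise ValueError("n_states cannot exceed the number of clusters")

    rng = np.random.default_rng(seed)
    start, T0, B0 = _spectral_initialization(
        strided, n_states, n_symbols, rng, perturbation=init_perturbation)

    model = CategoricalHMM(
        n_components=n_states, n_features=n_symbols, init_params="",
        params="ste", n_iter=max_iter, tol=tol,
        random_state=int(rng.integers(2**31)))
    model.startprob_ = start
    model.transmat_ = T0
    model.emissionprob_ = B0
    X = np.concatenate(strided)[:, None]
    lengths = [len(s) for s in strided]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)

    T = np.asarray(model.transmat_, float)
    T = np.maximum(T, 0.0)
    T /= T.sum(axis=1, keepdims=True)
    try:
        pi, _ = stationary_two_routes(T)
    except ValueError:  # reducible estimate: fall back to dominant eigenvector
        w, V = scipy.linalg.eig(T.T)
        pi = np.abs(np.real(V[:, int(np.argmin(np.abs(w - 1.0)))]))
        pi /= pi.sum()
    return HiddenMarkovModel(
        n_states=n_states, lag=float(lag), stride=stride, transition=T,
        emission=np.asarray(model.emissionprob_, float),
        startprob=np.asarray(model.startprob_, float), stationary=pi,
        log_likelihood=float(model.monitor_.history[-1]),
        converged=bool(model.monitor_.converged),
    )


def state_posteriors(hmm: HiddenMarkovModel, dtrajs) -> list[np.ndarray]:
    """Per-strided-frame posterior state memberships, one array per trajectory."""
    m = _to_hmmlearn(hmm)
    out = []
    for d in dtrajs:
        s = np.asarray(d, np.int64)[::hmm.stride]
        out.append(m.predict_proba(s[:, None]))
    return out


def sample_representative_frames(hmm: HiddenMarkovModel, dtrajs,
                                 n_per_state: int, seed: int = 0) -> list[np.ndarray]:
    """Strided-frame indices drawn per state with posterior-proportional weights.

    Returns one array of global (concatenated, strided) frame indices per
    state; a state with zero posterior mass yields an empty sample and a
    warning.
    """
    gammas = np.vstack(state_posteriors(hmm, dtrajs))
    rng = np.random.default_rng(seed)
    samples = []
    for s in range(hmm.n_states):
        w = gammas[:, s]
        total = w.sum()
        if total <= 0 or n_per_state == 0:
            if total <= 0:
                warnings.warn(f"state {s} has zero posterior mass; empty sample")
            samples.append(np.empty(0, dtype=np.int64))
            continue
        samples.append(rng.choice(len(w), size=n_per_state, p=w / total))
    return samples


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    table: pd.DataFrame  # one row per (n_clusters, lag, n_states)
    best_config: tuple[int, float, int]  # (n_clusters, lag ps, n_states)
    best_model: HiddenMarkovModel  # smallest-f replicate of the best config
    best_ensemble: list  # all replicates of the best config
    best_dtrajs: list  # discretization used by the best config


def select_model(features, clusters=(50, 64, 100, 200), lags=(20.0, 100.0, 200.0),
                 states=range(6, 21), models_per_state: int = 100, seed: int = 0,
                 tica_k: int | None = None, max_iter: int = 200,
                 tol: float = 1e-4) -> ModelSelectionResult:
    """Scan cluster counts, lag times and state counts by mean fractional uncertainty.

    For every configuration, ``models_per_state`` replicate HMMs are fitted
    with seeded initialization perturbations; the configuration minimizing
    the mean selection score wins and, of its replicates, the single model
    with the smallest score is returned.  Replicates whose score is
    degenerate (a starved state) are recorded as NaN and excluded from the
    mean.
    """
    features = list(features)
    dt = float(features[0].dt)
    master = np.random.default_rng(seed)
    rows = []
    best = None  # (mean_f, config, model, ensemble, dtrajs)
    for n_clusters in clusters:
        for lag in lags:
            tica = tica_fit(features, lag=lag, k=tica_k)
            coords = [tica_project(tica, f) for f in features]
            dtrajs, _ = cluster_assign(
                coords, n_clusters=n_clusters, seed=int(master.integers(2**31)))
            for n_states in states:
                fs, cons, models = [], [], []
                for _ in range(models_per_state):
                    rep_seed = int(master.integers(2**31))
                    m = estimate_hmm(dtrajs, n_states, lag=lag, seed=rep_seed,
                                     max_iter=max_iter, tol=tol, dt=dt)
                    models.append(m)
                    try:
                        fs.append(selection_score(m.transition))
                        cons.append(fractional_uncertainty(*stationary_two_routes(m.transition)))
                    except (DegenerateStateError, ValueError):
                        fs.append(np.nan)
                        cons.append(np.nan)
                fs = np.asarray(fs)
                valid = fs[~np.isnan(fs)]
                mean_f = float(valid.mean()) if valid.size else np.nan
                sd_f = float(valid.std()) if valid.size else np.nan
                rows.append({
                    "n_clusters": n_clusters, "lag_ps": lag, "n_states": n_states,
                    "mean_f": mean_f, "sd_f": sd_f, "n_valid": int(valid.size),
                    "mean_f_consistency": float(np.nanmean(cons)) if valid.size else np.nan,
                })
                if valid.size and (best is None or mean_f < best[0]):
                    i_best = int(np.nanargmin(fs))
                    best = (mean_f, (n_clusters, lag, n_states),
                            models[i_best], models, dtrajs)
    if best is None:
        raise RuntimeError("no configuration produced a valid model")
    table = pd.DataFrame(rows)
    return ModelSelectionResult(table=table, best_config=best[1],
                                best_model=best[2], best_ensemble=best[3],
                                best_dtrajs=best[4])


# ---------------------------------------------------------------------------
# state matching, Chapman-Kolmogorov, RMSD measure
# ---------------------------------------------------------------------------

def match_states(emission_a: np.ndarray, emission_b: np.ndarray) -> np.ndarray:
    """Permutation p mapping model-b states onto model-a states.

    Maximum-weight bipartite matching on emission-distribution overlap
    (sum of element-wise minima); ``p[i]`` is the b-state paired with
    a-state ``i``.
    """
    A = np.asarray(emission_a, float)
    B = np.asarray(emission_b, float)
    overlap = np.minimum(A[:, None, :], B[None, :, :]).sum(axis=2)
    _, cols = linear_sum_assignment(-overlap)
    return cols


def chapman_kolmogorov(hmm: HiddenMarkovModel, dtrajs, multiples=range(2, 6),
                       seed: int = 0, dt: float = 1.0,
                       max_iter: int = 200, tol: float = 1e-4) -> pd.DataFrame:
    """Compare T(tau)^k against a re-estimated T(k*tau) after state matching.

    Returns a table with one row per lag multiple k and the max-abs element
    discrepancy.  Multiples for which the trajectories are too short are
    dropped with a warning.
    """
    dtrajs = [np.asarray(d, np.int64) for d in dtrajs]
    rng = np.random.default_rng(seed)
    rows = []
    for k in multiples:
        lag_k = hmm.lag * k
        stride_k = int(round(lag_k / dt))
        if any(len(d) <= stride_k for d in dtrajs):
            warnings.warn(f"trajectories too short for lag multiple k={k}; truncating")
            break
        mk = estimate_hmm(dtrajs, hmm.n_states, lag=lag_k,
                          seed=int(rng.integers(2**31)), max_iter=max_iter,
                          tol=tol, dt=dt, n_symbols=hmm.n_symbols,
                          init_perturbation=0.0)
        p = match_states(hmm.emission, mk.emission)
        Tk_matched = mk.transition[np.ix_(p, p)]
        Tpow = np.linalg.matrix_power(hmm.transition, k)
        rows.append({"k": k, "lag_ps": lag_k,
                     "max_abs_discrepancy": float(np.max(np.abs(Tpow - Tk_matched)))})
    return pd.DataFrame(rows)


def _kabsch_aligned(frame: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``frame`` onto ``ref`` (both (n_atoms, 3), centered copies)."""
    f = frame - frame.mean(axis=0)
    r = ref - ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(r, f)
    return rot.apply(f)


def rmsd_measure(representative_coords_per_state) -> float:
    """Summed RMSD of representative conformations to their ensemble mean.

    ``representative_coords_per_state`` is a sequence (one entry per HMM
    state) of (n_frames, n_atoms, 3) coordinate arrays of the gating-pair
    atoms.  All frames are rigidly superposed onto the ensemble-mean
    conformation (computed by aligning to the first frame, averaging, then
    one refinement pass); the per-frame RMSDs are summed over all frames
    and divided by the number of states.
    """
    stacks = [np.asarray(c, float) for c in representative_coords_per_state
              if np.asarray(c).size]
    n_states = len(representative_coords_per_state)
    frames = [f for c in stacks for f in c]
    if len(frames) < 2:
        raise ValueError("need at least two representative frames in total")
    ref = frames[0] - frames[0].mean(axis=0)
    for _ in range(2):
        aligned = np.array([_kabsch_aligned(f, ref) for f in frames])
        ref = aligned.mean(axis=0)
    rmsds = np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=2), axis=1))
    return float(rmsds.sum() / n_states)
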