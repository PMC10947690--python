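"""Synthetic input generator with known ground truth.

The downstream analyses consume three kinds of per-frame observations
that normally come out of an MD pipeline: tunnel-detection records in
the shape CAVER emits, six gating-residue-pair minimum distances, and
membrane atom coordinates with channel-exit anchors.  This module
generates all three from a single latent metastable Markov chain, so
that every estimator in the package has a recoverable ground truth.

Units follow the field's mixed convention: gating distances in nm,
structural coordinates and tunnel radii in Å.  Conversions are always
explicit (``NM_PER_ANGSTROM``).

Key built-in conditions (overridable):

* bottleneck radii are truncated (clipped, not rejected) at the 1.0 Å
  tunnel-detection floor;
* per-channel detection probabilities and radius statistics default to
  the prevalences and bottleneck radii of the six channels of
  membrane-bound CYP3A4 (3313 analysed frames);
* per-channel open-state probability targets default to the published
  equilibrium open probabilities, with open/closed emission means
  placed on either side of the 0.5 nm gating boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._channels import CHANNELS, N_CHANNELS, channel_index

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

#: detection floor for tunnel bottleneck radii (Å)
RADIUS_FLOOR = 1.0

#: gating distances are clipped below this physical floor (nm)
DISTANCE_FLOOR = 0.05

#: reference per-channel prevalence (detected snapshots / 3313 frames)
DEFAULT_DETECTION_PROB = {
    "2a": 2329 / 3313,
    "2b": 3129 / 3313,
    "2c": 222 / 3313,
    "2e": 1603 / 3313,
    "3": 527 / 3313,
    "S": 1855 / 3313,
}

#: reference per-channel bottleneck radius mean/SD (Å)
DEFAULT_RADIUS_STATS = {
    "2a": (1.48, 0.38),
    "2b": (1.77, 0.39),
    "2c": (1.16, 0.17),
    "2e": (1.35, 0.23),
    "3": (1.44, 0.39),
    "S": (1.40, 0.32),
}

#: reference per-channel average length (Å) for generated tunnel profiles
DEFAULT_LENGTH = {
    "2a": 25.11, "2b": 21.52, "2c": 26.19, "2e": 15.75, "3": 27.31, "S": 21.86,
}

#: reference per-channel per-snapshot throughput mean/SD
DEFAULT_THROUGHPUT_STATS = {
    "2a": (0.57, 0.11),
    "2b": (0.67, 0.09),
    "2c": (0.42, 0.11),
    "2e": (0.62, 0.08),
    "3": (0.54, 0.12),
    "S": (0.56, 0.12),
}

#: reference per-channel equilibrium open probability at the 0.5 nm boundary
DEFAULT_OPEN_TARGETS = {
    "2a": 0.681, "2b": 0.662, "2c": 0.374, "2e": 0.171, "3": 0.284, "S": 0.390,
}

#: residue pools from which bottleneck sets are drawn, loosely modelled on
#: the most frequent bottleneck residues of each CYP3A4 channel
DEFAULT_RESIDUE_POOLS = {
    "2a": (50, 51, 57, 211, 215, 216, 220, 221, 225),
    "2b": (106, 210, 214, 218, 222, 227, 231, 235),
    "2c": (113, 117, 239, 243, 247, 251, 255),
    "2e": (104, 108, 112, 116, 119, 120, 124),
    "3": (219, 223, 227, 233, 237, 241),
    "S": (212, 216, 300, 304, 480, 484, 488),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthHMM:
    """Latent metastable chain driving gating distances and channel detection.

    ``transition`` is row-stochastic at a lag of one frame; ``emission_mean``
    and ``emission_sd`` are (n_states, 6) arrays of state-conditional gating
    distances (nm) in canonical channel order; ``stationary`` solves
    ``stationary @ transition = stationary``.
    """

    n_states: int
    transition: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray
    stationary: np.ndarray
    seed: int

    def __post_init__(self):
        T = np.asarray(self.transition, float)
        if T.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition must be row-stochastic")
        pi = np.asarray(self.stationary, float)
        if np.abs(pi.sum() - 1.0) > 1e-10 or np.max(np.abs(pi @ T - pi)) > 1e-10:
            raise ValueError("stationary vector does not satisfy pi @ T = pi")
        if np.any(np.asarray(self.emission_sd, float) <= 0):
            raise ValueError("emission_sd must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "transition": np.asarray(self.transition).tolist(),
            "emission_mean": np.asarray(self.emission_mean).tolist(),
            "emission_sd": np.asarray(self.emission_sd).tolist(),
            "stationary": np.asarray(self.stationary).tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthHMM":
        return cls(
            n_states=int(d["n_states"]),
            transition=np.asarray(d["transition"], float),
            emission_mean=np.asarray(d["emission_mean"], float),
            emission_sd=np.asarray(d["emission_sd"], float),
            stationary=np.asarray(d["stationary"], float),
            seed=int(d["seed"]),
        )


@dataclass
class FeatureTrajectory:
    """Per-frame six gating-pair minimum distances (nm) for one trajectory."""

    traj_id: str
    dt: float  # ps per frame
    distances: np.ndarray  # (n_frames, 6), canonical channel order
    hidden_path: np.ndarray | None = None  # ground truth only

    def __post_init__(self):
        D = np.asarray(self.distances, float)
        if D.ndim != 2 or D.shape[1] != N_CHANNELS:
            raise ValueError("distances must be (n_frames, 6)")
        if D.shape[0] < 2:
            raise ValueError("need at least two frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(D <= 0):
            raise ValueError("distances must be strictly positive")
        self.distances = D

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]


@dataclass
class MembraneFrame:
    """Leaflet-flagged membrane atom coordinates plus exit anchors for one frame.

    Coordinates in Å.  ``head_xyz``/``tail_xyz`` are (n, 3) arrays with the
    matching boolean masks ``head_contact``/``tail_contact`` marking the
    leaflet in contact with the protein.  ``exit_anchor_xyz`` maps each
    channel label to a (2, 3) array of the two Cα anchor positions.
    """

    frame_index: int
    head_xyz: np.ndarray
    head_contact: np.ndarray
    tail_xyz: np.ndarray
    tail_contact: np.ndarray
    exit_anchor_xyz: dict[str, np.ndarray]

    def __post_init__(self):
        hz = self.head_xyz[self.head_contact, 2]
        tz = self.tail_xyz[self.tail_contact, 2]
        if hz.size and tz.size and not hz.mean() > tz.mean():
            raise ValueError("contact head plane must lie above contact tail plane")
        for c, a in self.exit_anchor_xyz.items():
            if np.asarray(a).shape != (2, 3):
                raise ValueError(f"channel {c}: exactly two exit anchors required")


@dataclass(frozen=True)
class ChannelSnapshotRecord:
    """One per-frame tunnel observation, in the shape a tunnel finder emits."""

    frame_index: int
    channel: str
    bottleneck_radius: float  # Å
    bottleneck_residues: frozenset[int]
    bottleneck_xyz: tuple[float, float, float]  # Å
    length: float  # Å
    curvature: float  # >= 1
    profile: tuple[tuple[float, float], ...] | None = None  # (arc Å, radius Å)
    throughput: float | None = None  # in [0, 1]

    def __post_init__(self):
        channel_index(self.channel)
        if self.bottleneck_radius < RADIUS_FLOOR:
            raise ValueError(f"bottleneck_radius below the {RADIUS_FLOOR} Å detection floor")
        if self.curvature < 1.0:
            raise ValueError("curvature must be >= 1")
        if not self.bottleneck_residues:
            raise ValueError("bottleneck_residues must be non-empty")
        if self.throughput is not None and not 0.0 <= self.throughput <= 1.0:
            raise ValueError("throughput must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bottleneck_residues"] = sorted(self.bottleneck_residues)
        d["bottleneck_xyz"] = list(self.bottleneck_xyz)
        if self.profile is not None:
            d["profile"] = [list(p) for p in self.profile]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSnapshotRecord":
        return cls(
            frame_index=int(d["frame_index"]),
            channel=str(d["channel"]),
            bottleneck_radius=float(d["bottleneck_radius"]),
            bottleneck_residues=frozenset(int(r) for r in d["bottleneck_residues"]),
            bottleneck_xyz=tuple(float(x) for x in d["bottleneck_xyz"]),
            length=float(d["length"]),
            curvature=float(d["curvature"]),
            profile=None if d.get("profile") is None
            else tuple((float(s), float(r)) for s, r in d["profile"]),
            throughput=None if d.get("throughput") is None else float(d["throughput"]),
        )


# ---------------------------------------------------------------------------
# ground-truth model construction
# ---------------------------------------------------------------------------

def _stationary_of(T: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    # polish with a few power iterations so pi @ T = pi holds to 1e-12
    for _ in range(200):
        nxt = pi @ T
        if np.max(np.abs(nxt - pi)) < 1e-15:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def _best_subset(pi: np.ndarray, target: float, rng, resolution: float = 0.002):
    """Non-empty subset of states whose stationary mass best matches ``target``.

    Subset-sum dynamic programming on a rounded-sum grid; the state order is
    shuffled so distinct channels pick distinct (equally good) subsets.
    """
    order = rng.permutation(len(pi))
    reachable: dict[int, tuple[float, list[int]]] = {0: (0.0, [])}
    for s in order:
        updates = {}
        for key, (total, subset) in reachable.items():
            t2 = total + pi[s]
            k2 = int(round(t2 / resolution))
            if k2 not in reachable and k2 not in updates:
                updates[k2] = (t2, subset + [int(s)])
        reachable.update(updates)
    candidates = [(abs(total - target), total, subset)
                  for total, subset in reachable.values() if subset]
    return min(candidates)[2]


def make_ground_truth_hmm(
    n_states: int,
    seed: int,
    open_targets=None,
    min_diag: float = 0.9,
) -> GroundTruthHMM:
    """Build a metastable ground-truth chain with targeted open probabilities.

    ``open_targets`` gives, per channel, the desired stationary-weighted
    probability of being in a state whose emission mean exceeds 0.5 nm
    (default: the built-in equilibrium open probabilities).  States are
    assigned open/closed per channel by a greedy subset-sum over the
    stationary weights, then open means are drawn in 0.58–0.72 nm and
    closed means in 0.32–0.44 nm.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if open_targets is None:
        open_targets = [DEFAULT_OPEN_TARGETS[c] for c in CHANNELS]
    targets = np.asarray(
        [open_targets[c] for c in CHANNELS] if isinstance(open_targets, dict)
        else open_targets, float)
    if targets.shape != (N_CHANNELS,) or np.any(targets <= 0) or np.any(targets >= 1):
        raise ValueError("open_targets must be six values in (0, 1)")

    rng = np.random.default_rng(seed)
    diag = rng.uniform(min_diag, 0.995, size=n_states)
    T = rng.dirichlet(np.ones(n_states - 1), size=n_states) * (1.0 - diag)[:, None]
    full = np.empty((n_states, n_states))
    for i in range(n_states):
        row = np.insert(T[i], i, diag[i])
        full[i] = row
    full /= full.sum(axis=1, keepdims=True)
    pi = _stationary_of(full)

    mean = np.empty((n_states, N_CHANNELS))
    sd = rng.uniform(0.025, 0.05, size=(n_states, N_CHANNELS))
    for j in range(N_CHANNELS):
        subset = _best_subset(pi, targets[j], rng)
        open_mask = np.zeros(n_states, bool)
        open_mask[subset] = True
        mean[open_mask, j] = rng.uniform(0.58, 0.72, size=open_mask.sum())
        mean[~open_mask, j] = rng.uniform(0.32, 0.44, size=(~open_mask).sum())

    return GroundTruthHMM(
        n_states=n_states, transition=full, emission_mean=mean,
        emission_sd=sd, stationary=pi, seed=seed,
    )


def hierarchical_4state_ground_truth(seed: int = 0) -> GroundTruthHMM:
    """Fixed 4-state chain for state-count-recovery experiments.

    The transition matrix is symmetric (hence uniform stationary) with one
    state coupled an order of magnitude more weakly than the others, and
    the emission means ladder 0.35/0.45/0.60/0.72 nm across the 0.5 nm
    gating boundary.  Because the weak coupling makes every coarse lumping
    of the chain unbalanced (1+3 or 2+1+1 splits of uniform weights) while
    the 4-state decomposition itself is perfectly balanced, the state count
    is identifiable by a population-uniformity criterion: merged models
    carry bloated states, over-split models starved ones.
    """
    T = np.array([
        [0.994, 0.002, 0.002, 0.002],
        [0.002, 0.920, 0.040, 0.038],
        [0.002, 0.040, 0.920, 0.038],
        [0.002, 0.038, 0.038, 0.922],
    ])
    rng = np.random.default_rng(seed)
    mean = np.array([[0.35] * 6, [0.45] * 6, [0.60] * 6, [0.72] * 6])
    mean = mean + rng.normal(0.0, 0.01, size=mean.shape)
    return GroundTruthHMM(
        n_states=4, transition=T, emission_mean=mean,
        emission_sd=np.full((4, 6), 0.03), stationary=np.full(4, 0.25),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_hidden_path(model: GroundTruthHMM, n_frames: int, rng) -> np.ndarray:
    """Sample the latent chain, started from its stationary distribution."""
    cum = np.cumsum(model.transition, axis=1)
    path = np.empty(n_frames, dtype=np.int64)
    path[0] = rng.choice(model.n_states, p=model.stationary)
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def simulate_feature_trajectory(
    model: GroundTruthHMM,
    n_frames: int,
    dt: float = 20.0,
    seed: int = 0,
    traj_id: str | None = None,
) -> FeatureTrajectory:
    """Sample gating distances from the latent chain (Gaussian emissions, nm).

    Distances are truncated (clipped) below at ``DISTANCE_FLOOR``; the hidden
    path is retained for recovery tests.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    path = simulate_hidden_path(model, n_frames, rng)
    d = rng.normal(model.emission_mean[path], model.emission_sd[path])
    d = np.maximum(d, DISTANCE_FLOOR)
    return FeatureTrajectory(
        traj_id=traj_id or f"traj-{seed}", dt=float(dt),
        distances=d, hidden_path=path,
    )


#: default per-channel exit-anchor heights above the head plane (Å); the
#: channel between the membrane-embedded helices sits at the head plane,
#: the solvent channel highest above it
DEFAULT_EXIT_HEIGHT = {"2a": 5.0, "2b": 8.0, "2c": 15.0, "2e": 16.0, "3": 0.0, "S": 18.0}


def simulate_membrane_frames(
    n_frames: int,
    n_lipids_per_leaflet: int = 64,
    head_z: float = 20.0,
    tail_z: float = 12.0,
    jitter_sd: float = 1.0,
    seed: int = 0,
    box_xy: float = 100.0,
    exit_heights: dict[str, float] | None = None,
    anchor_jitter_sd: float = 0.5,
) -> list[MembraneFrame]:
    """Planar bilayer with per-atom Gaussian jitter plus channel exit anchors.

    The contact leaflet (protein side, +z) has head atoms near ``head_z`` and
    tail atoms near ``tail_z``; the distal leaflet is mirrored below.  Exit
    anchors for each channel are placed so their midpoint sits at
    ``head_z + exit_heights[channel]`` on average.
    """
    if head_z <= tail_z:
        raise ValueError("head_z must exceed tail_z")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if exit_heights is None:
        exit_heights = dict(DEFAULT_EXIT_HEIGHT)
    rng = np.random.default_rng(seed)
    n = n_lipids_per_leaflet
    grid = rng.uniform(0.0, box_xy, size=(2 * n, 2))  # fixed lateral positions
    anchor_xy = {c: rng.uniform(0.3 * box_xy, 0.7 * box_xy, size=2) for c in CHANNELS}
    thickness = head_z - tail_z
    frames: list[MembraneFrame] = []
    contact = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    for f in range(n_frames):
        head_zs = np.concatenate([
            np.full(n, head_z), np.full(n, tail_z - 4.0 - thickness)])
        tail_zs = np.concatenate([
            np.full(n, tail_z), np.full(n, tail_z - 4.0)])
        if jitter_sd > 0:
            head_zs = head_zs + rng.normal(0.0, jitter_sd, 2 * n)
            tail_zs = tail_zs + rng.normal(0.0, jitter_sd, 2 * n)
        head = np.column_stack([grid, head_zs])
        tail = np.column_stack([grid, tail_zs])
        anchors = {}
        for c in CHANNELS:
            centre = np.array([*anchor_xy[c], head_z + exit_heights[c]])
            offset = np.array([2.0, 0.0, 0.0])
            pair = np.vstack([centre + offset, centre - offset])
            if anchor_jitter_sd > 0:
                pair = pair + rng.normal(0.0, anchor_jitter_sd, size=(2, 3))
            anchors[c] = pair
        frames.append(MembraneFrame(
            frame_index=f, head_xyz=head, head_contact=contact,
            tail_xyz=tail, tail_contact=contact, exit_anchor_xyz=anchors,
        ))
    return frames


def simulate_channel_records(
    traj: FeatureTrajectory,
    model: GroundTruthHMM,
    detection_prob_per_state: dict[str, np.ndarray] | None = None,
    radius_mean: dict[str, np.ndarray] | None = None,
    radius_sd: dict[str, np.ndarray] | None = None,
    residue_pools: dict[str, tuple[int, ...]] | None = None,
    throughput_stats: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    start_point: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[ChannelSnapshotRecord]:
    """Emit tunnel-detection records driven by the trajectory's hidden path.

    Each frame and channel: a Bernoulli detection with the current state's
    probability; a bottleneck radius drawn Gaussian then clipped at the
    1.0 Å floor; a 3–6 residue bottleneck set drawn from the channel's pool
    with geometrically decaying position weights; a bottleneck location whose
    distance from ``start_point`` is consistent with the chosen residues
    (each pool position maps to a depth along the tunnel); a radius profile;
    and a per-snapshot throughput drawn from the channel's reference
    statistics (clipped to (0, 1]), the way a tunnel finder reports it.
    """
    if traj.hidden_path is None:
        raise ValueError("trajectory must carry its ground-truth hidden_path")
    n_states = model.n_states

    def _per_state(spec_map, default_map, transform):
        out = {}
        for c in CHANNELS:
            if spec_map is not None and c in spec_map:
                v = np.asarray(spec_map[c], float)
                out[c] = np.full(n_states, v) if v.ndim == 0 else v
            else:
                out[c] = np.full(n_states, transform(default_map[c]))
        return out

    det = _per_state(detection_prob_per_state, DEFAULT_DETECTION_PROB, lambda v: v)
    rmean = _per_state(radius_mean, DEFAULT_RADIUS_STATS, lambda v: v[0])
    rsd = _per_state(radius_sd, DEFAULT_RADIUS_STATS, lambda v: v[1])
    pools = dict(DEFAULT_RESIDUE_POOLS)
    if residue_pools:
        pools.update(residue_pools)
    tstats = dict(DEFAULT_THROUGHPUT_STATS)
    if throughput_stats:
        tstats.update(throughput_stats)

    rng = np.random.default_rng(seed)
    start = np.asarray(start_point, float)
    path = traj.hidden_path
    records: list[ChannelSnapshotRecord] = []
    for c in CHANNELS:
        pool = np.asarray(pools[c])
        npool = len(pool)
        # geometric position weights: early pool members dominate bottlenecks
        weights = 0.6 ** np.arange(npool)
        weights /= weights.sum()
        depth = np.linspace(0.3, 1.0, npool) * DEFAULT_LENGTH[c]  # Å from start
        detected = rng.random(traj.n_frames) < det[c][path]
        for f in np.flatnonzero(detected):
            s = path[f]
            radius = max(rng.normal(rmean[c][s], rsd[c][s]), RADIUS_FLOOR)
            size = rng.integers(3, min(6, npool) + 1)
            idx = rng.choice(npool, size=size, replace=False, p=weights)
            residues = frozenset(int(r) for r in pool[idx])
            dist = float(np.mean(depth[idx]) + rng.normal(0.0, 1.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz = start + abs(dist) * direction
            length = DEFAULT_LENGTH[c] * (1.0 + rng.normal(0.0, 0.1))
            length = max(length, 5.0)
            curvature = 1.0 + abs(rng.normal(0.3, 0.15))
            arc = np.linspace(0.0, length, 8)
            prof_r = np.maximum(
                radius + np.abs(rng.normal(1.0, 0.4, size=8)), radius)
            prof_r[rng.integers(0, 8)] = radius  # bottleneck on the profile
            profile = tuple((float(a), float(r)) for a, r in zip(arc, prof_r))
            t_mean, t_sd = tstats[c]
            thrp = float(np.clip(rng.normal(t_mean, t_sd), 1e-6, 1.0))
            records.append(ChannelSnapshotRecord(
                frame_index=int(f), channel=c, bottleneck_radius=float(radius),
                bottleneck_residues=residues,
                bottleneck_xyz=tuple(float(x) for x in xyz),
                length=float(length), curvature=float(curvature),
                profile=profile, throughput=thrp,
            ))
    return records
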