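"""Gating-residue distance analyses.

Each channel has a pair of gating residues near the catalytic site whose
minimum inter-residue distance opens (large) or blocks (small) the
channel.  A gate is *open* when the distance strictly exceeds the
threshold (default 0.48 nm); a sample exactly at the threshold counts as
closed.  Distributions are at least bimodal — a closed mode near 0.4 nm
and open modes beyond 0.5 nm — and the analyses here quantify open
fractions, joint behaviour of gate pairs and rank correlations under a
lag-time scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from ._channels import CHANNELS


@dataclass(frozen=True)
class GatingConfig:
    """Gating residue pairs per channel plus the open/closed thresholds (nm)."""

    pairs: dict[str, tuple[int, int]]
    open_threshold: float = 0.48
    hmm_boundary: float = 0.50

    def __post_init__(self):
        if set(self.pairs) != set(CHANNELS):
            raise ValueError(f"exactly the six channels {CHANNELS} must be configured")
        if self.open_threshold <= 0 or self.hmm_boundary <= 0:
            raise ValueError("thresholds must be positive")


def min_contact_distance(atoms_a, atoms_b) -> float:
    """Closest-atoms contact distance between two residues (nm).

    Minimum pairwise Euclidean distance over all supplied atoms; hydrogens
    participate whenever they are present in the input.
    """
    A = np.atleast_2d(np.asarray(atoms_a, float))
    B = np.atleast_2d(np.asarray(atoms_b, float))
    if A.size == 0 or B.size == 0:
        raise ValueError("both atom lists must be non-empty")
    return float(cdist(A, B).min())


def histogram_edges(values, bin_width: float, origin: float = 0.0) -> np.ndarray:
    """Half-open bin edges [edge, edge+width) covering ``values``, anchored at origin."""
    v = np.asarray(values, float)
    lo = int(np.floor((v.min() - origin) / bin_width))
    hi = int(np.floor((v.max() - origin) / bin_width))
    return origin + np.arange(lo, hi + 2) * bin_width


def distance_distribution(series, bin_width: float = 0.02):
    """Histogram, mean and central 50%-mass interval of a distance series.

    Returns ``(edges, counts, mean, (q25, q75))``; the quantile band holds
    half the probability mass and serves as the asymmetric error bar.
    """
    v = np.asarray(series, float)
    if v.size == 0:
        raise ValueError("empty series")
    edges = histogram_edges(v, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    q25, q75 = np.quantile(v, [0.25, 0.75])
    return edges, counts, float(v.mean()), (float(q25), float(q75))


def open_fraction(series_per_trajectory, threshold: float = 0.48):
    """Mean percent of open samples, ± population SD across trajectories.

    Each trajectory contributes one pooled fraction of samples strictly
    above ``threshold`` (all channels pooled when the series are 2-D);
    these per-trajectory percentages are then averaged.
    """
    series_per_trajectory = list(series_per_trajectory)
    if not series_per_trajectory:
        raise ValueError("at least one trajectory required")
    fracs = np.array([
        100.0 * np.mean(np.asarray(s, float) > threshold)
        for s in series_per_trajectory
    ])
    return float(fracs.mean()), float(fracs.std())


def open_fraction_per_channel(trajs, threshold: float = 0.48) -> dict[str, tuple[float, float]]:
    """Per-channel open percentage mean ± SD across feature trajectories."""
    out = {}
    for j, c in enumerate(CHANNELS):
        out[c] = open_fraction([t.distances[:, j] for t in trajs], threshold)
    return out


def dual_distribution(series_i, series_j, bin_width: float = 0.02):
    """Joint 2-D histogram whose marginals equal the 1-D histograms exactly.

    Returns ``(edges_i, edges_j, counts)`` with counts shaped
    (len(edges_i)-1, len(edges_j)-1).
    """
    a = np.asarray(series_i, float)
    b = np.asarray(series_j, float)
    if a.shape != b.shape:
        raise ValueError("series length mismatch")
    ei = histogram_edges(a, bin_width)
    ej = histogram_edges(b, bin_width)
    counts, _, _ = np.histogram2d(a, b, bins=(ei, ej))
    return ei, ej, counts.astype(int)


def spearman_lag_scan(series_i_per_traj, series_j_per_traj, dt: float,
                      max_lag: float = 2000.0, step: float = 100.0):
    """Rank correlation of gate i at t against gate j at t+lag.

    Scans lags 0, step, 2*step, ... up to ``max_lag`` (ps), computing the
    Spearman coefficient per trajectory (average ranks for ties) and
    averaging over trajectories.  Returns ``(lags_ps, mean_rho, sd_rho)``.
    """
    if step % dt != 0:
        raise ValueError("step must be a multiple of dt")
    pairs = [(np.asarray(a, float), np.asarray(b, float))
             for a, b in zip(series_i_per_traj, series_j_per_traj)]
    n_min = min(len(a) for a, _ in pairs)
    max_steps = int(max_lag // dt)
    if max_steps >= n_min - 1:
        raise ValueError("max_lag too long for the shortest trajectory")
    stride = int(step // dt)
    lags = np.arange(0, max_steps + 1, stride)
    mean_rho, sd_rho = [], []
    for lag in lags:
        rhos = []
        for a, b in pairs:
            x = a[: len(a) - lag] if lag else a
            y = b[lag:]
            rhos.append(spearmanr(x, y).statistic)
        rhos = np.array(rhos, float)
        mean_rho.append(rhos.mean())
        sd_rho.append(rhos.std())
    return lags * dt, np.array(mean_rho), np.array(sd_rho)
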