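"""Bottleneck residue-trio statistics.

The narrowest cross-section of a tunnel is formed by a handful of
residues; co-occurrence of three of them ("trios") across frames marks
persistent constrictions.  A trio is admissible only if every pair of
its members is more than ``min_separation`` (default 3) sequence
positions apart, excluding trivially-associated sequence neighbours.
The occurrence frequency of trio i is f_i = c_i / N where c_i counts
frames (once per frame) in which the trio is a subset of the bottleneck
residue set and N is the number of frames the channel was detected in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrioRecord:
    trio: tuple[int, int, int]  # ascending residue ids
    channel: str
    count: int  # c_i: frames containing the trio
    frequency: float  # f_i = c_i / N
    first_occurrence_distance: float  # Å from bottleneck to channel start
    normalized_distance: float  # / furthest first-occurrence distance


def enumerate_trios(residues, min_separation: int = 3) -> set[tuple[int, int, int]]:
    """All ascending 3-subsets whose members are pairwise more than
    ``min_separation`` sequence positions apart."""
    res = sorted(set(int(r) for r in residues))
    if any(r <= 0 for r in res):
        raise ValueError("residue ids must be positive integers")
    out = set()
    for trio in combinations(res, 3):
        if all(b - a > min_separation for a, b in combinations(trio, 2)):
            out.add(trio)
    return out


def trio_frequencies(records, start_point=(0.0, 0.0, 0.0),
                     min_separation: int = 3) -> list[TrioRecord]:
    """Frequency and first-occurrence distance of every admissible trio.

    ``records`` are one channel's snapshot records; counts are per frame
    (a trio counts once per frame regardless of how many supersets of it
    appear), frequencies are normalized by the channel's detected-frame
    count, and each trio's distance is measured at its earliest frame then
    normalized to the furthest trio found.
    """
    records = sorted(records, key=lambda r: r.frame_index)
    if not records:
        raise ValueError("no records given")
    channel = records[0].channel
    start = np.asarray(start_point, float)
    n_frames = len({r.frame_index for r in records})
    counts: dict[tuple, int] = {}
    first_dist: dict[tuple, float] = {}
    for rec in records:
        dist = float(np.linalg.norm(np.asarray(rec.bottleneck_xyz) - start))
        for trio in enumerate_trios(rec.bottleneck_residues, min_separation):
            counts[trio] = counts.get(trio, 0) + 1
            first_dist.setdefault(trio, dist)
    if not counts:
        return []
    dmax = max(first_dist.values())
    return [
        TrioRecord(
            trio=t, channel=channel, count=c, frequency=c / n_frames,
            first_occurrence_distance=first_dist[t],
            normalized_distance=first_dist[t] / dmax if dmax > 0 else 0.0,
        )
        for t, c in counts.items()
    ]


def top_k_trios(trios, k: int) -> list[TrioRecord]:
    """The k most frequent trios, ties broken by ascending residue triple."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(trios, key=lambda t: (-t.frequency, t.trio))[:k]


def trio_radius_histogram(records, trio, bin_width: float = 0.125,
                          origin: float = 1.0):
    """Histogram of bottleneck radii over frames containing ``trio``.

    Bins are half-open [edge, edge + width) anchored at ``origin`` (the
    1.0 Å detection floor by default).  Returns (bin left edges, counts);
    the counts sum to the trio's frame count c_i.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    trio_set = frozenset(trio)
    radii = np.array([r.bottleneck_radius for r in records
                      if trio_set <= r.bottleneck_residues])
    if radii.size == 0:
        return np.array([origin]), np.array([0])
    idx = np.floor((radii - origin) / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = origin + np.arange(lo, hi + 1) * bin_width
    return edges, counts


def trios_table(trios) -> pd.DataFrame:
    """Long-format table of trio records (one row per trio)."""
    return pd.DataFrame([
        {"channel": t.channel,
         "trio": "-".join(map(str, t.trio)),
         "count": t.count, "frequency": t.frequency,
         "first_occurrence_distance": t.first_occurrence_distance,
         "normalized_distance": t.normalized_distance}
        for t in trios
    ])
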