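"""Per-channel summary statistics of tunnel-detection records.

Aggregates per-frame snapshot records of a channel into the familiar
tunnel-analysis summary: prevalence, bottleneck-radius statistics,
length, curvature, throughput and priority.  Throughput scores how
easily a ligand traverses the tunnel in one snapshot (1 = easiest);
priority is the average throughput over *all* frames, counting frames
where the channel was undetected as zero:

    priority = avg_throughput * snapshots / total_frames

Standard deviations use the population convention (divide by n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._channels import CHANNELS
from .synthetic import ChannelSnapshotRecord


class DuplicateRecordError(ValueError):
    """Two records for the same (frame, channel)."""


def throughput_from_profile(profile) -> float:
    """Ease-of-passage score in (0, 1] from a tunnel radius profile.

    ``profile`` is a sequence of (arc position Å, radius Å) pairs with
    non-decreasing positions and positive radii.  The score is the cost
    integral exp(-∫ ds / r(s)^2) evaluated with the trapezoidal rule on
    the profile segments, so it increases with every radius and decreases
    with tunnel length.
    """
    prof = np.asarray(profile, float)
    if prof.ndim != 2 or prof.shape[0] < 2 or prof.shape[1] != 2:
        raise ValueError("profile needs at least two (arc, radius) points")
    s, r = prof[:, 0], prof[:, 1]
    if np.any(np.diff(s) < 0):
        raise ValueError("arc positions must be non-decreasing")
    if np.any(r <= 0):
        raise ValueError("profile radii must be positive")
    inv2 = 1.0 / r**2
    cost = float(np.sum(np.diff(s) * 0.5 * (inv2[:-1] + inv2[1:])))
    return math.exp(-cost)


def prevalence_percent(snapshots: int, total_frames: int) -> float:
    """Percentage of frames in which the channel was detected."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    if not 0 <= snapshots <= total_frames:
        raise ValueError("snapshots must lie in [0, total_frames]")
    return 100.0 * snapshots / total_frames


def fractional_deviation(mean: float, sd: float) -> float:
    """Relative spread 100 * sd / mean (percent)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return 100.0 * sd / mean


@dataclass(frozen=True)
class ChannelSummary:
    channel: str
    snapshots: int
    total_frames: int
    avg_bottleneck_radius: float | None
    sd_bottleneck_radius: float | None
    max_bottleneck_radius: float | None
    avg_length: float | None
    sd_length: float | None
    avg_curvature: float | None
    sd_curvature: float | None
    avg_throughput: float | None
    sd_throughput: float | None
    priority: float


def _record_throughput(rec: ChannelSnapshotRecord) -> float:
    if rec.throughput is not None:
        return rec.throughput
    if rec.profile is None:
        raise ValueError(
            f"record frame={rec.frame_index} channel={rec.channel}: "
            "neither throughput nor profile available")
    return throughput_from_profile(rec.profile)


def summarize_channel(records, total_frames: int, channel: str | None = None) -> ChannelSummary:
    """Aggregate one channel's snapshot records into a summary row.

    Means and SDs are over detected frames only; an empty record list yields
    zero snapshots, priority 0 and missing (None) means.  Per-snapshot
    throughput stored on a record is used verbatim, otherwise it is computed
    from the record's radius profile.
    """
    records = list(records)
    if channel is None and records:
        channel = records[0].channel
    channel = channel or "?"
    if any(r.channel != channel for r in records):
        raise ValueError("records span more than one channel")
    frames = [r.frame_index for r in records]
    if len(set(frames)) != len(frames):
        raise DuplicateRecordError(f"duplicate (frame, channel) records for {channel}")
    if total_frames < len(set(frames)):
        raise ValueError("total_frames smaller than the number of detected frames")
    records = sorted(records, key=lambda r: r.frame_index)  # exact order invariance
    n = len(records)
    if n == 0:
        return ChannelSummary(channel, 0, total_frames, None, None, None,
                              None, None, None, None, None, None, 0.0)
    radius = np.array([r.bottleneck_radius for r in records])
    length = np.array([r.length for r in records])
    curv = np.array([r.curvature for r in records])
    thrp = np.array([_record_throughput(r) for r in records])
    avg_thrp = float(thrp.mean())
    return ChannelSummary(
        channel=channel, snapshots=n, total_frames=total_frames,
        avg_bottleneck_radius=float(radius.mean()),
        sd_bottleneck_radius=float(radius.std()),
        max_bottleneck_radius=float(radius.max()),
        avg_length=float(length.mean()), sd_length=float(length.std()),
        avg_curvature=float(curv.mean()), sd_curvature=float(curv.std()),
        avg_throughput=avg_thrp, sd_throughput=float(thrp.std()),
        priority=avg_thrp * n / total_frames,
    )


def summarize_all(records, total_frames: int) -> pd.DataFrame:
    """One summary row per canonical channel, in Table-style column order."""
    by_channel: dict[str, list] = {c: [] for c in CHANNELS}
    for r in records:
        by_channel[r.channel].append(r)
    rows = []
    for c in CHANNELS:
        s = summarize_channel(by_channel[c], total_frames, channel=c)
        rows.append({
            "channel": s.channel, "snapshots": s.snapshots,
            "avg_bottleneck_radius": s.avg_bottleneck_radius,
            "sd_bottleneck_radius": s.sd_bottleneck_radius,
            "max_bottleneck_radius": s.max_bottleneck_radius,
            "avg_length": s.avg_length, "sd_length": s.sd_length,
            "avg_curvature": s.avg_curvature, "sd_curvature": s.sd_curvature,
            "priority": s.priority,
            "avg_throughput": s.avg_throughput, "sd_throughput": s.sd_throughput,
        })
    return pd.DataFrame(rows)
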