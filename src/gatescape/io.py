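"""Fixture-bundle readers and writers (TSV / JSON-lines / JSON).

Formats:

* features: TSV with columns ``frame, t_ps, d_2a, d_2b, d_2c, d_2e, d_3, d_S``
  (distances in nm);
* channel records: JSON-lines, one snapshot record per line;
* membrane frames: TSV with columns
  ``frame, role(head|tail), leaflet(contact|distal), x, y, z`` (Å), plus a
  companion anchors TSV ``frame, channel, anchor(0|1), x, y, z``;
* ground truth: plain JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._channels import CHANNELS, DISTANCE_COLUMNS
from .synthetic import ChannelSnapshotRecord, FeatureTrajectory, GroundTruthHMM, MembraneFrame


# -- features ---------------------------------------------------------------

def write_features_tsv(traj: FeatureTrajectory, path) -> None:
    df = pd.DataFrame(traj.distances, columns=list(DISTANCE_COLUMNS))
    df.insert(0, "t_ps", np.arange(traj.n_frames) * traj.dt)
    df.insert(0, "frame", np.arange(traj.n_frames))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_features_tsv(path, traj_id: str | None = None) -> FeatureTrajectory:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DISTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    t = df["t_ps"].to_numpy(float)
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return FeatureTrajectory(
        traj_id=traj_id or Path(path).stem, dt=dt,
        distances=df[list(DISTANCE_COLUMNS)].to_numpy(float),
    )


# -- channel records --------------------------------------------------------

def write_records_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def read_records_jsonl(path) -> list[ChannelSnapshotRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(ChannelSnapshotRecord.from_dict(json.loads(line)))
    return records


# -- membrane frames --------------------------------------------------------

def write_membrane_tsv(frames: list[MembraneFrame], atoms_path, anchors_path) -> None:
    rows = []
    for fr in frames:
        for xyz, contact, role in (
            (fr.head_xyz, fr.head_contact, "head"),
            (fr.tail_xyz, fr.tail_contact, "tail"),
        ):
            for (x, y, z), c in zip(xyz, contact):
                rows.append((fr.frame_index, role, "contact" if c else "distal", x, y, z))
    pd.DataFrame(rows, columns=["frame", "role", "leaflet", "x", "y", "z"]).to_csv(
        atoms_path, sep="\t", index=False, float_format="%.4f")
    arows = []
    for fr in frames:
        for ch in CHANNELS:
            for k, (x, y, z) in enumerate(fr.exit_anchor_xyz[ch]):
                arows.append((fr.frame_index, ch, k, x, y, z))
    pd.DataFrame(arows, columns=["frame", "channel", "anchor", "x", "y", "z"]).to_csv(
        anchors_path, sep="\t", index=False, float_format="%.4f")


def read_membrane_tsv(atoms_path, anchors_path) -> list[MembraneFrame]:
    atoms = pd.read_csv(atoms_path, sep="\t")
    anchors = pd.read_csv(anchors_path, sep="\t", dtype={"channel": str})
    frames = []
    for f, grp in atoms.groupby("frame", sort=True):
        head = grp[grp.role == "head"]
        tail = grp[grp.role == "tail"]
        agrp = anchors[anchors.frame == f]
        anchor_map = {}
        for ch in CHANNELS:
            sub = agrp[agrp.channel == ch].sort_values("anchor")
            anchor_map[ch] = sub[["x", "y", "z"]].to_numpy(float)
        frames.append(MembraneFrame(
            frame_index=int(f),
            head_xyz=head[["x", "y", "z"]].to_numpy(float),
            head_contact=(head.leaflet == "contact").to_numpy(),
            tail_xyz=tail[["x", "y", "z"]].to_numpy(float),
            tail_contact=(tail.leaflet == "contact").to_numpy(),
            exit_anchor_xyz=anchor_map,
        ))
    return frames


# -- ground truth -----------------------------------------------------------

def write_ground_truth_json(model: GroundTruthHMM, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)


def read_ground_truth_json(path) -> GroundTruthHMM:
    with open(path) as fh:
        return GroundTruthHMM.from_dict(json.load(fh))
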