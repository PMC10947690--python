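"""Channel-exit geometry relative to the membrane.

Each channel's exit is the midpoint of two Cα anchor atoms.  With the
bilayer built in the x-y plane, heights are measured along z against
leaflet planes obtained by averaging the z-values of the contact-leaflet
atoms (head-group nitrogens for the nitrogen plane, designated tail
carbons for the tail plane):

    h_i = (z_c)_i - <z_N>_i        (frame i, Å)

Radial proximity is the minimum full 3D Euclidean distance from the exit
to any contact-leaflet atom of the relevant species.  Only the leaflet in
contact with the membrane-embedded helices enters any calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._channels import CHANNELS


def exit_location(anchor_a, anchor_b) -> np.ndarray:
    """Component-wise midpoint of the two exit anchor atoms (Å)."""
    return 0.5 * (np.asarray(anchor_a, float) + np.asarray(anchor_b, float))


def plane_height(exit_z: float, leaflet_atom_zs) -> float:
    """Height of the exit above the leaflet plane (positive = above)."""
    zs = np.asarray(leaflet_atom_zs, float)
    if zs.size == 0:
        raise ValueError("leaflet atom list is empty")
    return float(exit_z - zs.mean())


def min_radial_distance(exit_point, atoms) -> float:
    """Minimum Euclidean distance from the exit to any listed atom (Å)."""
    atoms = np.atleast_2d(np.asarray(atoms, float))
    if atoms.size == 0:
        raise ValueError("atom list is empty")
    return float(np.min(np.linalg.norm(atoms - np.asarray(exit_point, float), axis=1)))


@dataclass
class ExitSeries:
    """Per-frame exit geometry for one channel (all arrays same length)."""

    channel: str
    exit_xyz: np.ndarray  # (n_frames, 3) Å
    h_N: np.ndarray  # height above head-nitrogen plane, Å
    h_T: np.ndarray  # height above tail-carbon plane, Å
    r_N: np.ndarray  # min radial distance to a contact head nitrogen, Å
    r_T: np.ndarray  # min radial distance to a contact tail carbon, Å

    def __post_init__(self):
        n = len(self.exit_xyz)
        if not (len(self.h_N) == len(self.h_T) == len(self.r_N) == len(self.r_T) == n):
            raise ValueError("per-frame series length mismatch")
        if np.any(self.r_N < 0) or np.any(self.r_T < 0):
            raise ValueError("radial distances must be non-negative")


def compute_exit_series(frames, channels=CHANNELS) -> dict[str, ExitSeries]:
    """Exit location, plane heights and radial minima for every frame.

    Exits exist in every frame (anchors are always defined), whether or not
    the tunnel itself was detected there.
    """
    out = {}
    for c in channels:
        exits, hN, hT, rN, rT = [], [], [], [], []
        for fr in frames:
            e = exit_location(*fr.exit_anchor_xyz[c])
            heads = fr.head_xyz[fr.head_contact]
            tails = fr.tail_xyz[fr.tail_contact]
            exits.append(e)
            hN.append(plane_height(e[2], heads[:, 2]))
            hT.append(plane_height(e[2], tails[:, 2]))
            rN.append(min_radial_distance(e, heads))
            rT.append(min_radial_distance(e, tails))
        out[c] = ExitSeries(c, np.array(exits), np.array(hN), np.array(hT),
                            np.array(rN), np.array(rT))
    return out


def channel_correlations(series: dict[str, np.ndarray], method: str = "pearson") -> pd.DataFrame:
    """Symmetric 6x6 correlation matrix of per-frame channel series.

    Frames are used listwise (all channels defined).  A constant series has
    undefined correlation and is reported as NaN.
    """
    if method != "pearson":
        raise ValueError("only pearson correlation is supported")
    df = pd.DataFrame({c: np.asarray(series[c], float) for c in CHANNELS if c in series})
    if len(df) < 3:
        raise ValueError("need at least 3 common frames")
    return df.corr(method="pearson")
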