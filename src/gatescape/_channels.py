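"""Canonical channel labels and column ordering.

The six access/egress tunnels of a membrane-bound cytochrome P450 are
conventionally labelled 2a, 2b, 2c, 2e, 3 and S (S = solvent channel).
Every table and array in this package uses this fixed column order so
that joins across modules are unambiguous.
"""

CHANNELS: tuple[str, ...] = ("2a", "2b", "2c", "2e", "3", "S")

#: feature-table column names for the six gating-pair minimum distances (nm)
DISTANCE_COLUMNS: tuple[str, ...] = tuple(f"d_{c}" for c in CHANNELS)

N_CHANNELS = len(CHANNELS)


def channel_index(channel: str) -> int:
    """Position of *channel* in the canonical order; raises ValueError if unknown."""
    try:
        return CHANNELS.index(channel)
    except ValueError:
        raise ValueError(f"unknown channel label {channel!r}; expected one of {CHANNELS}") from None
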