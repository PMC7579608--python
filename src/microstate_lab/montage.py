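"""Electrode montages: channel identities and unit-sphere scalp positions.

Coordinate convention: +x right, +y anterior, +z superior; all positions lie
on the unit sphere. Only the upper part of the sphere (z >= -0.2) is used,
mimicking scalp coverage of a sensor net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: lowest z-coordinate covered by electrodes (just below the equator)
Z_FLOOR = -0.2

MIN_CHANNELS = 8


@dataclass(frozen=True)
class Montage:
    """Electrode set with 3D unit-sphere positions.

    Parameters
    ----------
    channel_ids
        Unique channel labels, one per electrode.
    positions
        Array of shape ``(n_channels, 3)``; every row must have unit norm.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids and positions length mismatch")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if len(self.channel_ids) < MIN_CHANNELS:
            raise ValueError(f"montage needs at least {MIN_CHANNELS} channels")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("all positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def angles(self) -> np.ndarray:
        """Pairwise great-circle angles (radians), shape (n, n)."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)

    def cosines(self) -> np.ndarray:
        """Pairwise direction cosines (dot products), shape (n, n)."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)


def make_montage(n_channels: int = 32) -> Montage:
    """Build a deterministic quasi-uniform scalp montage.

    Uses a Fibonacci lattice restricted to z >= -0.2: points are spread at
    the golden angle in azimuth while z descends linearly from the vertex,
    which gives near-uniform areal density over the covered cap.

    Parameters
    ----------
    n_channels
        Number of electrodes (>= 8). 32 is the desk-scale default; pass 128
        for a high-density-net-sized array.
    """
    if n_channels < MIN_CHANNELS:
        raise ValueError(f"n_channels must be >= {MIN_CHANNELS}, got {n_channels}")
    k = np.arange(n_channels)
    z = 1.0 - (k + 0.5) * (1.0 - Z_FLOOR) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = k * _GOLDEN_ANGLE
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    ids = tuple(f"E{i + 1:03d}" for i in k)
    return Montage(ids, pos)
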