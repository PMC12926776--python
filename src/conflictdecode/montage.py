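"""Electrode montages: channel labels, 2-D layout positions, neighbor graphs.

A montage fixes the channel dimension of every epoch tensor.  The default
fixture is a 28-channel subset of the international 10-20 / 10-10 system —
the intersection scale of a 64-channel and a 32-channel cap, so that multi-
session data recorded with different caps can be reduced to a common set of
electrodes.  Positions are 2-D head-plane coordinates (projected from the
standard polar layout: x = right, y = anterior, head radius 1) and are used
for topographic plotting and for building the spatial neighbor graph that
cluster statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeMontage", "default_montage", "STANDARD_POSITIONS"]

# Approximate 2-D positions (azimuthal projection) for the standard labels.
# Mapping: (theta deg from Cz toward the given direction, radius 0..1),
# converted to x (right+) / y (anterior+).
_POLAR = {
    "Fp1": (-18, 0.95), "Fp2": (18, 0.95),
    "F7": (-54, 0.95), "F3": (-39, 0.60), "Fz": (0, 0.48), "F4": (39, 0.60), "F8": (54, 0.95),
    "FC5": (-69, 0.72), "FC1": (-31, 0.30), "FC2": (31, 0.30), "FC6": (69, 0.72),
    "T7": (-90, 0.95), "C3": (-90, 0.48), "Cz": (0, 0.0), "C4": (90, 0.48), "T8": (90, 0.95),
    "CP5": (-111, 0.72), "CP1": (-149, 0.30), "CP2": (149, 0.30), "CP6": (111, 0.72),
    "P7": (-126, 0.95), "P3": (-141, 0.60), "Pz": (180, 0.48), "P4": (141, 0.60), "P8": (126, 0.95),
    "O1": (-162, 0.95), "Oz": (180, 0.95), "O2": (162, 0.95),
}


def _polar_to_xy(theta_deg: float, radius: float) -> tuple[float, float]:
    th = np.deg2rad(theta_deg)
    # theta measured from the anterior direction, positive clockwise (to the right)
    return radius * np.sin(th), radius * np.cos(th)


STANDARD_POSITIONS: dict[str, tuple[float, float]] = {
    lab: _polar_to_xy(t, r) for lab, (t, r) in _POLAR.items()
}


@dataclass(frozen=True)
class ElectrodeMontage:
    """Ordered channel labels with 2-D positions and a symmetric neighbor graph.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names in canonical (alphabetical) order.
    positions : ndarray, shape (n_channels, 2)
        Head-plane coordinates, x toward the right ear, y toward the nasion.
    adjacency : ndarray of bool, shape (n_channels, n_channels)
        Symmetric spatial neighbor relation with an empty diagonal.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        adj = np.asarray(self.adjacency, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "adjacency", adj)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        n = len(labels)
        if pos.shape != (n, 2):
            raise ValueError(f"positions must have shape ({n}, 2), got {pos.shape}")
        if adj.shape != (n, n):
            raise ValueError(f"adjacency must have shape ({n}, {n}), got {adj.shape}")
        if adj.diagonal().any():
            raise ValueError("adjacency must have no self-edges")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, keep: list[str]) -> "ElectrodeMontage":
        """Restrict to ``keep`` (canonical alphabetical order), preserving edges."""
        keep_sorted = sorted(keep)
        missing = [c for c in keep_sorted if c not in self.labels]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        idx = np.array([self.labels.index(c) for c in keep_sorted], dtype=int)
        return ElectrodeMontage(
            labels=tuple(keep_sorted),
            positions=self.positions[idx],
            adjacency=self.adjacency[np.ix_(idx, idx)],
        )


def _distance_adjacency(positions: np.ndarray, radius: float) -> np.ndarray:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = (d > 0) & (d <= radius)
    return adj | adj.T


def default_montage(radius: float = 0.62) -> ElectrodeMontage:
    """The 28-channel 10-20/10-10 fixture montage.

    Neighbors are channel pairs closer than ``radius`` in the unit-head
    plane; the default connects each electrode to its immediate spatial
    neighbors (median degree about 5) without skipping across the scalp.
    """
    labels = tuple(sorted(STANDARD_POSITIONS))
    pos = np.array([STANDARD_POSITIONS[c] for c in labels], dtype=float)
    return ElectrodeMontage(labels=labels, positions=pos,
                            adjacency=_distance_adjacency(pos, radius))
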