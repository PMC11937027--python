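"""Scalp electrode geometry for the 19-channel 10-20 montage.

Coordinates are unit-sphere positions derived from the standard 10-20
angular placements (x to the right preauricular point, y to the nasion,
z to the vertex).  Distances between these positions drive the
distance-based adjacency builder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ElectrodeLayout", "standard_1020_layout", "STANDARD_1020_CHANNELS"]

_S = np.sin(np.deg2rad([18.0, 54.0]))  # ring azimuth offsets
_C = np.cos(np.deg2rad([18.0, 54.0]))
_R2 = np.sqrt(0.5)

# unit-sphere 10-20 coordinates (x right, y anterior, z superior)
_COORDS_1020 = {
    "Fp1": (-_S[0], _C[0], 0.0),
    "Fp2": (+_S[0], _C[0], 0.0),
    "F7": (-_S[1], _C[1], 0.0),
    "F3": (-0.545, 0.673, 0.5),
    "Fz": (0.0, _R2, _R2),
    "F4": (+0.545, 0.673, 0.5),
    "F8": (+_S[1], _C[1], 0.0),
    "T3": (-1.0, 0.0, 0.0),
    "C3": (-_R2, 0.0, _R2),
    "Cz": (0.0, 0.0, 1.0),
    "C4": (+_R2, 0.0, _R2),
    "T4": (+1.0, 0.0, 0.0),
    "T5": (-_S[1], -_C[1], 0.0),
    "P3": (-0.545, -0.673, 0.5),
    "Pz": (0.0, -_R2, _R2),
    "P4": (+0.545, -0.673, 0.5),
    "T6": (+_S[1], -_C[1], 0.0),
    "O1": (-_S[0], -_C[0], 0.0),
    "O2": (+_S[0], -_C[0], 0.0),
}

STANDARD_1020_CHANNELS = tuple(_COORDS_1020)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Per-channel 3-D electrode positions, unit-sphere normalized."""

    coords: np.ndarray
    labels: tuple

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n_channels, 3) array")
        if coords.shape[0] != len(self.labels):
            raise ValueError("one coordinate triple per label required")
        norms = np.linalg.norm(coords, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("electrode at the origin cannot be normalized")
        coords = coords / norms[:, None]
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_channels(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean distance matrix between electrode positions."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def standard_1020_layout(labels=STANDARD_1020_CHANNELS) -> ElectrodeLayout:
    """Look up unit-sphere positions for 10-20 montage labels, in order.

    Raises
    ------
    KeyError
        If a label is not one of the 19 packaged 10-20 electrodes.
    """
    coords = []
    for lab in labels:
        if lab not in _COORDS_1020:
            raise KeyError(f"unknown electrode {lab!r}; not in the 10-20 fixture")
        coords.append(_COORDS_1020[lab])
    return ElectrodeLayout(np.array(coords, dtype=float), tuple(labels))
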