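"""Core in-memory container for coarse-grained and atomistic frames.

A :class:`BeadConfiguration` is one frame of named particles (CG beads or
atoms) with residue bookkeeping, per-lipid leaflet tags and a rectangular
box.  All coordinates are in nanometres; the box is orthorhombic with
lengths ``(Lx, Ly, Lz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BeadConfiguration", "minimum_image_xy"]


@dataclass
class BeadConfiguration:
    """One frame of named beads/atoms with positions and a rectangular box.

    Parameters
    ----------
    names : array of str
        Per-bead label (``W``, ``PO4``, ``NA+``, backbone identifiers, ...).
    residue_names : array of str
        Per-bead residue species (``POPC``, ``CHOL``, ``MEL``, ``W``, ...).
    residue_ids : array of int
        Per-bead residue index (1-based, as in GRO files).
    positions : (n, 3) float array
        Coordinates in nm, wrapped into ``[0, box)``.
    box : (3,) float array
        Orthorhombic box lengths ``(Lx, Ly, Lz)`` in nm.
    leaflet_tags : array of str
        Per-bead tag ``upper`` / ``lower`` / ``none``.
    """

    names: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    leaflet_tags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.leaflet_tags is None:
            self.leaflet_tags = np.full(len(self.names), "none", dtype=object)
        else:
            self.leaflet_tags = np.asarray(self.leaflet_tags, dtype=object)
        n = len(self.names)
        if not (
            len(self.residue_names) == len(self.residue_ids)
            == self.positions.shape[0] == len(self.leaflet_tags) == n
        ):
            raise ValueError("per-bead arrays must share one length")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if self.box.shape != (3,) or not np.all(np.isfinite(self.box)) or np.any(self.box <= 0):
            raise ValueError("box must be three positive finite lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    # -- convenience -------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.names)

    def copy(self) -> "BeadConfiguration":
        return BeadConfiguration(
            names=self.names.copy(),
            residue_names=self.residue_names.copy(),
            residue_ids=self.residue_ids.copy(),
            positions=self.positions.copy(),
            box=self.box.copy(),
            leaflet_tags=self.leaflet_tags.copy(),
        )

    def with_positions(self, positions: np.ndarray) -> "BeadConfiguration":
        return replace(self, positions=np.asarray(positions, dtype=np.float64))

    def select(self, mask: np.ndarray) -> "BeadConfiguration":
        """Sub-configuration of the beads where ``mask`` is true."""
        return BeadConfiguration(
            names=self.names[mask],
            residue_names=self.residue_names[mask],
            residue_ids=self.residue_ids[mask],
            positions=self.positions[mask],
            box=self.box.copy(),
            leaflet_tags=self.leaflet_tags[mask],
        )

    def wrap(self) -> "BeadConfiguration":
        """Wrap all coordinates into ``[0, box)`` component-wise."""
        return self.with_positions(np.mod(self.positions, self.box))

    def concatenate(self, other: "BeadConfiguration") -> "BeadConfiguration":
        if not np.allclose(self.box, other.box):
            raise ValueError("cannot concatenate frames with different boxes")
        return BeadConfiguration(
            names=np.concatenate([self.names, other.names]),
            residue_names=np.concatenate([self.residue_names, other.residue_names]),
            residue_ids=np.concatenate([self.residue_ids, other.residue_ids]),
            positions=np.vstack([self.positions, other.positions]),
            box=self.box.copy(),
            leaflet_tags=np.concatenate([self.leaflet_tags, other.leaflet_tags]),
        )


def minimum_image_xy(dxy: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention in x and y only.

    Membrane systems are periodic laterally but finite in z, so distances
    to the pore axis and between lipids are folded in xy alone.
    """
    dxy = np.atleast_2d(np.asarray(dxy, dtype=np.float64))
    out = dxy - np.round(dxy / box[:2]) * box[:2]
    return out
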