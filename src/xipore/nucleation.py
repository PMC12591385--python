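"""Sliced-cylinder pore nucleation coordinate.

The nucleation coordinate xi measures how far a transmembrane polar
defect has grown.  A cylinder of radius ``R`` is erected along z through
the membrane and divided into ``n_slices`` slices of thickness ``d``;
each slice is "occupied" in proportion to the number of polar particles
(water and lipid-phosphate beads for coarse-grained systems; water
oxygens and lipid phosphorus for atomistic ones) it contains, saturating
at ``saturation_count`` particles:

    xi = (1 / N_s) * sum_s min(1, n_s / N_0)

A flat, unperturbed bilayer scores roughly 0.2 (only the slices next to
the headgroup regions hold polar particles) and a continuous
water-filled pore scores 1.0.

Counting here is hard (non-smooth): this package only ever evaluates xi
on stored configurations or drives Metropolis-style sampling, so the
gradient of xi is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import BeadConfiguration, minimum_image_xy

__all__ = [
    "XiSpec",
    "SliceOccupancy",
    "CentralPolarCount",
    "compute_xi",
    "select_slice_count",
    "count_central_polar",
    "write_xi_series",
    "read_xi_series",
]

#: water molecules represented by one coarse-grained W bead
WATERS_PER_W_BEAD = 4


class GeometryError(ValueError):
    """Slice stack does not fit the box, or similar geometric impossibility."""


@dataclass(frozen=True)
class XiSpec:
    """Full parameterization of the nucleation coordinate.

    Parameters
    ----------
    center_xy : (x, y) in nm or None
        Cylinder axis; ``None`` means the box xy-center.
    radius : float
        Cylinder radius in nm (closed disk, periodic in xy).
    slice_thickness : float
        Slice thickness ``d`` in nm: 0.2 for coarse-grained systems,
        0.1 for atomistic ones.
    n_slices : int
        Number of slices ``N_s``; calibrated per membrane so that a flat
        bilayer scores close to 0.2 (see :func:`select_slice_count`).
    saturation_count : int
        Polar particles per slice for full occupancy (``N_0``).
    polar_selection : tuple of str
        Particle names counted as polar.
    z_anchor : str or float
        Where the slice stack is centered: ``"polar_com"`` (mean z of
        the polar selection, the default), ``"po4_mean"``,
        ``"box_center"``, or an explicit z in nm.
    """

    center_xy: tuple[float, float] | None = None
    radius: float = 1.2
    slice_thickness: float = 0.2
    n_slices: int = 19
    saturation_count: int = 2
    polar_selection: tuple[str, ...] = ("W", "PO4")
    z_anchor: str | float = "polar_com"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if self.n_slices < 2:
            raise ValueError("n_slices must be at least 2")
        if self.saturation_count <= 0:
            raise ValueError("saturation_count must be positive")
        if not self.polar_selection:
            raise ValueError("polar_selection must not be empty")

    @property
    def stack_height(self) -> float:
        return self.n_slices * self.slice_thickness

    @classmethod
    def cg_default(cls, **overrides) -> "XiSpec":
        """Coarse-grained defaults: 0.2 nm slices, W/PO4 beads, N_0 = 2."""
        params = dict(slice_thickness=0.2, n_slices=19, saturation_count=2,
                      polar_selection=("W", "PO4"))
        params.update(overrides)
        return cls(**params)

    @classmethod
    def aa_default(cls, **overrides) -> "XiSpec":
        """Atomistic defaults: 0.1 nm slices, OW/P atoms, N_0 = 3."""
        params = dict(slice_thickness=0.1, n_slices=38, saturation_count=3,
                      polar_selection=("OW", "P"))
        params.update(overrides)
        return cls(**params)


@dataclass
class SliceOccupancy:
    """Per-slice polar counts and occupancies, plus the resulting xi."""

    per_slice_counts: np.ndarray
    per_slice_occupancy: np.ndarray
    xi: float
    z_center: float = field(default=np.nan)
    slice_edges: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class CentralPolarCount:
    """Polar particle count in the central window and its water equivalent."""

    raw_count: int
    water_equivalent: int


def _resolve_center_xy(config: BeadConfiguration, spec: XiSpec) -> np.ndarray:
    if spec.center_xy is None:
        return config.box[:2] / 2.0
    return np.asarray(spec.center_xy, dtype=np.float64)


def _resolve_z_center(config: BeadConfiguration, spec: XiSpec, polar_mask: np.ndarray) -> float:
    anchor = spec.z_anchor
    if isinstance(anchor, (int, float)) and not isinstance(anchor, bool):
        return float(anchor)
    if anchor == "polar_com":
        return float(np.mean(config.positions[polar_mask, 2]))
    if anchor == "po4_mean":
        mask = np.isin(config.names.astype(str), ("PO4", "P"))
        if not mask.any():
            raise ValueError("z_anchor 'po4_mean' requires PO4/P particles")
        return float(np.mean(config.positions[mask, 2]))
    if anchor == "box_center":
        return float(config.box[2] / 2.0)
    raise ValueError(f"unknown z_anchor {anchor!r}")


def _polar_mask(config: BeadConfiguration, spec: XiSpec) -> np.ndarray:
    mask = np.isin(config.names.astype(str), spec.polar_selection)
    if not mask.any():
        raise ValueError(
            f"no particles matching polar selection {spec.polar_selection} in configuration"
        )
    return mask


def compute_xi(config: BeadConfiguration, spec: XiSpec) -> SliceOccupancy:
    """Evaluate the nucleation coordinate on one frame.

    Polar particles are binned into ``n_slices`` z-slices of thickness
    ``slice_thickness`` centered on the anchor z; a particle contributes
    to a slice when its xy distance to the cylinder axis is at most
    ``radius`` under the xy minimum-image convention.

    Returns
    -------
    SliceOccupancy
        Per-slice counts, saturated occupancies, and xi in [0, 1].
    """
    if spec.stack_height > config.box[2] + 1e-9:
        raise GeometryError(
            f"slice stack height {spec.stack_height:.3f} nm exceeds box z "
            f"{config.box[2]:.3f} nm"
        )
    mask = _polar_mask(config, spec)
    center_xy = _resolve_center_xy(config, spec)
    z_center = _resolve_z_center(config, spec, mask)

    pos = config.positions[mask]
    dxy = minimum_image_xy(pos[:, :2] - center_xy, config.box)
    radial_ok = np.einsum("ij,ij->i", dxy, dxy) <= spec.radius**2 + 1e-12

    z0 = z_center - spec.stack_height / 2.0
    idx = np.floor((pos[:, 2] - z0) / spec.slice_thickness).astype(int)
    in_stack = (idx >= 0) & (idx < spec.n_slices)

    sel = radial_ok & in_stack
    counts = np.bincount(idx[sel], minlength=spec.n_slices).astype(np.int64)
    occupancy = np.minimum(1.0, counts / spec.saturation_count)
    edges = z0 + spec.slice_thickness * np.arange(spec.n_slices + 1)
    return SliceOccupancy(
        per_slice_counts=counts,
        per_slice_occupancy=occupancy,
        xi=float(np.mean(occupancy)),
        z_center=z_center,
        slice_edges=edges,
    )


def select_slice_count(
    flat_configs: Sequence[BeadConfiguration],
    spec_template: XiSpec,
    candidates: Sequence[int],
    target: float = 0.2,
) -> int:
    """Calibrate the slice count against unbiased flat-membrane frames.

    Returns the candidate ``n_slices`` whose mean xi over the flat
    configurations is closest to ``target`` (0.2 for an unperturbed
    bilayer); ties break toward the smaller count.
    """
    if len(candidates) == 0:
        raise ValueError("candidates must be nonempty")
    if len(flat_configs) == 0:
        raise ValueError("flat_configs must be nonempty")
    best_n, best_err = None, np.inf
    for n_s in sorted(int(c) for c in candidates):
        spec = replace(spec_template, n_slices=n_s)
        mean_xi = float(np.mean([compute_xi(cfg, spec).xi for cfg in flat_configs]))
        err = abs(mean_xi - target)
        if err < best_err - 1e-15:
            best_n, best_err = n_s, err
    assert best_n is not None
    return best_n


def count_central_polar(
    config: BeadConfiguration, spec: XiSpec, window_nm: float = 1.0
) -> CentralPolarCount:
    """Count polar particles in the central ``window_nm`` of the pore cylinder.

    The water-molecule equivalent is the W-bead count times four for
    coarse-grained selections, or the water-oxygen count for atomistic
    ones.
    """
    if window_nm > spec.stack_height + 1e-9:
        raise ValueError("central window is taller than the slice stack")
    mask = _polar_mask(config, spec)
    center_xy = _resolve_center_xy(config, spec)
    z_center = _resolve_z_center(config, spec, mask)

    pos = config.positions[mask]
    names = config.names[mask].astype(str)
    dxy = minimum_image_xy(pos[:, :2] - center_xy, config.box)
    radial_ok = np.einsum("ij,ij->i", dxy, dxy) <= spec.radius**2 + 1e-12
    z_ok = np.abs(pos[:, 2] - z_center) <= window_nm / 2.0 + 1e-12
    sel = radial_ok & z_ok

    raw = int(np.count_nonzero(sel))
    if "W" in spec.polar_selection:
        water_equiv = int(np.count_nonzero(sel & (names == "W"))) * WATERS_PER_W_BEAD
    else:
        water_equiv = int(np.count_nonzero(sel & (names == "OW")))
    return CentralPolarCount(raw_count=raw, water_equivalent=water_equiv)


def write_xi_series(times: Iterable[float], xis: Iterable[float], path: str | Path) -> None:
    """Write a (time, xi) series as two-column plain text."""
    arr = np.column_stack([np.asarray(list(times)), np.asarray(list(xis))])
    np.savetxt(path, arr, fmt="%.6f", header="time_ns xi", comments="# ")


def read_xi_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time, xi) plain-text series."""
    arr = np.loadtxt(path, ndmin=2)
    return arr[:, 0], arr[:, 1]
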