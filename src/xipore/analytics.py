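"""Trajectory statistics for membrane/peptide pore systems.

Implements the per-frame and time-averaged metrics used to characterize
pore formation in asymmetric bilayers: lipid flip-flop fraction,
pore-proximal lipid counts and species fractions, pore-lining peptide
count, peptide tilt angles, area per lipid, bilayer thickness from the
head-phosphorus density profile, the area compressibility modulus from
box-area fluctuations, deuterium-style order parameters, and the
adjacent-averaging smoother used for time-series plots.

Conventions: lateral distances use the minimum-image convention in xy
only (membranes are finite in z); "within r" means a closed disk; the
membrane midplane is the mean z of all lipid tail-end C4A/C4B beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import BeadConfiguration, minimum_image_xy

__all__ = [
    "AnalysisFrameSeries",
    "TiltRecord",
    "PoreLiningCount",
    "flip_flop_fraction",
    "count_near_pore",
    "smooth_series",
    "pore_lining_count",
    "reference_lining_density",
    "tilt_angles",
    "area_per_lipid",
    "bilayer_thickness",
    "area_compressibility",
    "lipid_fraction_near_pore",
    "choose_enrichment_radius",
    "order_parameter",
    "flip_flop_series",
]

_BOLTZMANN_J_PER_K = 1.380649e-23
#: head-phosphate particle names, coarse-grained and atomistic
HEAD_NAMES = ("PO4", "P")
#: lipid tail-end bead names defining the midplane
TAIL_END_NAMES = ("C4A", "C4B")


class PeakDetectionError(ValueError):
    """The head-phosphorus density profile is not bimodal."""


class EmptyRegionError(ValueError):
    """No lipids ever enter the requested region."""


@dataclass
class AnalysisFrameSeries:
    """Ordered frames with times (ns) and the pore-axis xy position."""

    frames: List[BeadConfiguration]
    times: np.ndarray
    pore_center_xy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.frames) != len(self.times):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pore_center_xy is not None:
            self.pore_center_xy = np.asarray(self.pore_center_xy, dtype=np.float64)
            box = self.frames[0].box
            if np.any(self.pore_center_xy < 0) or np.any(self.pore_center_xy > box[:2]):
                raise ValueError("pore center must lie inside the box")

    def center_for(self, frame: BeadConfiguration) -> np.ndarray:
        if self.pore_center_xy is not None:
            return self.pore_center_xy
        return frame.box[:2] / 2.0

    @classmethod
    def from_trajectory(cls, trajectory, pore_center_xy=None) -> "AnalysisFrameSeries":
        """Adapter for :class:`~xipore.membrane.ToyTrajectory`."""
        return cls(frames=list(trajectory.frames), times=np.asarray(trajectory.times),
                   pore_center_xy=pore_center_xy)


@dataclass(frozen=True)
class TiltRecord:
    """Tilt angle of one peptide and whether it lines the pore."""

    peptide_id: int
    angle: float           # degrees in [0, 90]
    pore_lining: bool


@dataclass(frozen=True)
class PoreLiningCount:
    """Pore-lining peptide count: normalized density and its integer rounding."""

    value: float
    rounded: int


def _midplane(frame: BeadConfiguration) -> float:
    mask = np.isin(frame.names.astype(str), TAIL_END_NAMES)
    if not mask.any():
        raise ValueError("no C4A/C4B tail-end beads to define the midplane")
    return float(np.mean(frame.positions[mask, 2]))


def flip_flop_fraction(frame: BeadConfiguration, species: str = "POPS") -> float:
    """Fraction of a species' headgroups above the membrane midplane.

    The midplane is the mean z of all lipid tail-end C4A/C4B beads;
    the numerator counts the species' PO4 beads with larger z.
    """
    names = frame.names.astype(str)
    resnames = frame.residue_names.astype(str)
    heads = (resnames == species) & np.isin(names, HEAD_NAMES)
    n_total = int(np.count_nonzero(heads))
    if n_total == 0:
        raise ValueError(f"no {species} headgroup beads in frame")
    mid = _midplane(frame)
    n_upper = int(np.count_nonzero(frame.positions[heads, 2] > mid))
    return n_upper / n_total


def flip_flop_series(series: AnalysisFrameSeries, species: str = "POPS") -> np.ndarray:
    """Per-frame flip-flop fraction over a frame series."""
    return np.array([flip_flop_fraction(f, species) for f in series.frames])


def count_near_pore(frame: BeadConfiguration, species: str, radius: float,
                    pore_center_xy: Optional[np.ndarray] = None) -> int:
    """Count a species' head beads within ``radius`` of the pore axis.

    Closed-disk convention; xy minimum image.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = (np.asarray(pore_center_xy, dtype=np.float64)
              if pore_center_xy is not None else frame.box[:2] / 2.0)
    names = frame.names.astype(str)
    resnames = frame.residue_names.astype(str)
    heads = (resnames == species) & np.isin(names, HEAD_NAMES)
    d = minimum_image_xy(frame.positions[heads, :2] - center, frame.box)
    return int(np.count_nonzero(np.einsum("ij,ij->i", d, d) <= radius**2 + 1e-12))


def smooth_series(values: Sequence[float], window: int = 10) -> np.ndarray:
    """Adjacent averaging with a centered window that shrinks at the edges.

    Output has the same length as the input; window 1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    v = np.asarray(values, dtype=np.float64)
    n = len(v)
    out = np.empty(n)
    left_span = (window - 1) // 2
    right_span = window // 2
    cumsum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n):
        lo = max(0, i - left_span)
        hi = min(n, i + right_span + 1)
        out[i] = (cumsum[hi] - cumsum[lo]) / (hi - lo)
    return out


def pore_lining_count(frame: BeadConfiguration, reference_density: float,
                      window_nm: float = 1.0) -> PoreLiningCount:
    """Pore-lining peptide count from central-window backbone density.

    Counts peptide backbone beads whose z lies within ``window_nm/2`` of
    the membrane midplane and normalizes by ``reference_density``, the
    corresponding count for a single fully pore-lining peptide (see
    :func:`reference_lining_density`).
    """
    if reference_density <= 0:
        raise ValueError("reference_density must be positive")
    names = frame.names.astype(str)
    backbone = (frame.residue_names.astype(str) == "MEL") & np.char.startswith(
        names.astype("U16"), "BB"
    )
    if not backbone.any():
        return PoreLiningCount(0.0, 0)
    mid = _midplane(frame)
    z = frame.positions[backbone, 2]
    count = int(np.count_nonzero(np.abs(z - mid) <= window_nm / 2.0 + 1e-12))
    value = count / reference_density
    return PoreLiningCount(value=value, rounded=int(round(value)))


def reference_lining_density(n_residues: int = 26, rise_per_residue: float = 0.15,
                             window_nm: float = 1.0) -> float:
    """Central-window backbone-bead count of one fully inserted peptide.

    The reference peptide is placed transmembrane at 90 degrees tilt
    (helix axis along z) centered on the midplane; the count of its
    backbone beads inside the central window defines the density of
    "one pore-lining peptide".
    """
    i = np.arange(n_residues)
    z = (i - (n_residues - 1) / 2.0) * rise_per_residue
    return float(np.count_nonzero(np.abs(z) <= window_nm / 2.0 + 1e-12))


def tilt_angles(frame: BeadConfiguration, window_nm: float = 1.0) -> List[TiltRecord]:
    """Tilt angle of each peptide from its terminal backbone vector.

    The angle between the N-terminus-to-C-terminus backbone vector and
    the membrane xy-plane: 0 degrees lies flat, 90 degrees is fully
    pore-lining.  ``pore_lining`` is set when the peptide contributes
    backbone beads to the central window about the midplane.
    """
    names = frame.names.astype(str)
    resnames = frame.residue_names.astype(str)
    backbone = (resnames == "MEL") & np.char.startswith(names.astype("U16"), "BB")
    records: List[TiltRecord] = []
    if not backbone.any():
        return records
    mid = _midplane(frame)
    for rid in np.unique(frame.residue_ids[backbone]):
        m = backbone & (frame.residue_ids == rid)
        idx = np.flatnonzero(m)
        order = np.argsort([int(names[i][2:]) for i in idx])
        pts = frame.positions[idx[order]]
        v = pts[-1] - pts[0]
        norm = float(np.linalg.norm(v))
        if norm < 1e-9:
            raise ValueError(f"degenerate terminal vector for peptide residue {rid}")
        angle = math.degrees(math.asin(min(1.0, abs(v[2]) / norm)))
        lining = bool(np.any(np.abs(pts[:, 2] - mid) <= window_nm / 2.0 + 1e-12))
        records.append(TiltRecord(peptide_id=int(rid), angle=angle, pore_lining=lining))
    return records


def _upper_leaflet_count(frame: BeadConfiguration) -> int:
    upper = frame.leaflet_tags.astype(str) == "upper"
    return len(np.unique(frame.residue_ids[upper]))


def area_per_lipid(series: AnalysisFrameSeries) -> float:
    """Mean xy box area divided by the mean upper-leaflet molecule count.

    Cholesterol counts toward the upper-leaflet total.
    """
    areas = [float(f.box[0] * f.box[1]) for f in series.frames]
    counts = [_upper_leaflet_count(f) for f in series.frames]
    if np.mean(counts) == 0:
        raise ValueError("no upper-leaflet lipids tagged")
    return float(np.mean(areas) / np.mean(counts))


def bilayer_thickness(series: AnalysisFrameSeries, n_bins: int = 200) -> float:
    """Head-phosphate peak-to-peak distance from a 200-bin z density profile.

    The z histogram of head-phosphorus particles over all frames is
    split at its median z; the distance between the maximal-density bin
    centers of the two halves is the thickness.
    """
    z_all: List[np.ndarray] = []
    for f in series.frames:
        heads = np.isin(f.names.astype(str), HEAD_NAMES)
        z_all.append(f.positions[heads, 2])
    z = np.concatenate(z_all)
    if z.size == 0:
        raise ValueError("no head-phosphate particles in series")
    lz = max(float(f.box[2]) for f in series.frames)
    counts, edges = np.histogram(z, bins=n_bins, range=(0.0, lz))
    centers = 0.5 * (edges[:-1] + edges[1:])
    median = float(np.median(z))
    lower = centers < median
    upper = ~lower
    if counts[lower].sum() == 0 or counts[upper].sum() == 0:
        raise PeakDetectionError("head-phosphate density profile is unimodal")
    peak_lo = centers[lower][np.argmax(counts[lower])]
    peak_hi = centers[upper][np.argmax(counts[upper])]
    return float(peak_hi - peak_lo)


def area_compressibility_from_areas(areas: np.ndarray, temperature: float = 310.0) -> float:
    """K_A = k_B T <A> / Var(A) from a raw xy-area series (nm^2), in mN/m."""
    areas = np.asarray(areas, dtype=np.float64)
    if len(areas) < 100:
        raise ValueError("need at least 100 frames for a fluctuation estimate")
    var = float(np.var(areas, ddof=1))
    if var <= 0:
        raise ValueError("degenerate input: zero area variance")
    mean = float(np.mean(areas))
    # nm^2 / nm^4 with k_B in J/K -> N/m carries a factor 1e18; report mN/m
    return _BOLTZMANN_J_PER_K * temperature * mean / var * 1e21


def area_compressibility(series: AnalysisFrameSeries, temperature: float = 310.0) -> float:
    """Area compressibility modulus K_A from box-area fluctuations, in mN/m.

    K_A = k_B T <A> / Var(A), the standard equilibrium fluctuation
    estimator.  Higher K_A means the bilayer better resists applied
    lateral stress.
    """
    areas = np.array([float(f.box[0] * f.box[1]) for f in series.frames])
    return area_compressibility_from_areas(areas, temperature)


def lipid_fraction_near_pore(series: AnalysisFrameSeries, radius: float = 1.6) -> Dict[str, float]:
    """Time-averaged species fractions of head phosphates within ``radius``.

    The average per-species head count within the pore radius is
    normalized by the average total head count; fractions sum to one.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    totals: Dict[str, float] = {}
    n_frames = len(series.frames)
    for f in series.frames:
        center = series.center_for(f)
        heads = np.isin(f.names.astype(str), HEAD_NAMES)
        d = minimum_image_xy(f.positions[heads, :2] - center, f.box)
        within = np.einsum("ij,ij->i", d, d) <= radius**2 + 1e-12
        for sp in f.residue_names[heads][within]:
            totals[str(sp)] = totals.get(str(sp), 0.0) + 1.0
    grand = sum(totals.values())
    if grand == 0:
        raise EmptyRegionError(f"no lipid heads ever within {radius} nm of the pore")
    return {sp: v / grand for sp, v in sorted(totals.items())}


def choose_enrichment_radius(series: AnalysisFrameSeries, target_count: int = 30,
                             grid_step: float = 0.1) -> float:
    """Smallest radius on a 0.1 nm grid holding ``target_count`` lipids on average.

    Mirrors the calibration that sets the pore-enrichment radius so an
    average of 30 lipid heads fall within it for the fully nucleated
    pore state.
    """
    if target_count < 1:
        raise ValueError("target_count must be at least 1")
    box = series.frames[0].box
    r_max = min(box[0], box[1]) / 2.0
    counts_cache: List[np.ndarray] = []
    for f in series.frames:
        center = series.center_for(f)
        heads = np.isin(f.names.astype(str), HEAD_NAMES)
        d = minimum_image_xy(f.positions[heads, :2] - center, f.box)
        counts_cache.append(np.sqrt(np.einsum("ij,ij->i", d, d)))
    r = grid_step
    while r <= r_max + 1e-9:
        mean_count = float(np.mean([
            np.count_nonzero(dist <= r + 1e-12) for dist in counts_cache
        ]))
        if mean_count >= target_count:
            return round(r, 10)
        r += grid_step
    raise ValueError(
        f"target count {target_count} not reachable within half box ({r_max:.2f} nm)"
    )


def order_parameter(frame: BeadConfiguration,
                    pairs_by_position: Sequence[Sequence[tuple[int, int]]]) -> np.ndarray:
    """Segmental order parameter S = <(3 cos^2 theta - 1) / 2> per tail position.

    ``pairs_by_position[p]`` lists (i, j) particle index pairs whose
    vectors define tail position ``p``; theta is the angle of each
    vector to the membrane normal (z).  Values lie in [-0.5, 1.0]:
    1 for vectors along z, -0.5 for in-plane vectors, 0 for isotropic.
    """
    out = np.empty(len(pairs_by_position))
    for p, pairs in enumerate(pairs_by_position):
        pairs_arr = np.asarray(list(pairs), dtype=int)
        if pairs_arr.size == 0:
            raise ValueError(f"no vector pairs for position {p}")
        v = frame.positions[pairs_arr[:, 1]] - frame.positions[pairs_arr[:, 0]]
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(f"zero-length vector at position {p}")
        cos2 = (v[:, 2] / norms) ** 2
        out[p] = float(np.mean(1.5 * cos2 - 0.5))
    return out


def metrics_table(series: AnalysisFrameSeries, species: str = "POPS",
                  radius: float = 2.0) -> pd.DataFrame:
    """Tidy per-frame table: time, flip-flop fraction, near-pore count, area."""
    rows = []
    for t, f in zip(series.times, series.frames):
        rows.append({
            "time_ns": float(t),
            "flip_flop_fraction": flip_flop_fraction(f, species),
            "near_pore_count": count_near_pore(f, species, radius, series.center_for(f)),
            "area_nm2": float(f.box[0] * f.box[1]),
        })
    return pd.DataFrame(rows)
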