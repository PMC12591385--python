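"""Synthetic coarse-grained membrane, peptide and toy-trajectory generator.

Everything downstream of this module (the nucleation coordinate, the
equilibration scheduler, WHAM, backmapping and the trajectory
analytics) is exercised on configurations produced here, so the
generator aims for *geometric* realism only: MARTINI-style bead stacks
on jittered lattices, correct species counting for asymmetric red blood
cell (RBC) mimetic leaflet compositions, solvation and 150 mM salt with
exact electroneutrality, carved transmembrane polar defects of
prescribed nucleation-coordinate value, and overdamped toy dynamics
with controlled lipid flip-flop rates and box-area fluctuations.  No
force field is involved anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .core import BeadConfiguration, minimum_image_xy
from .nucleation import XiSpec, compute_xi

__all__ = [
    "MembraneSpec",
    "PeptideModel",
    "ToyTrajectoryParams",
    "ToyTrajectory",
    "MEL_SEQUENCE",
    "DEFAULT_APL",
    "largest_remainder_counts",
    "build_membrane",
    "make_peptide_model",
    "place_peptides",
    "carve_pore",
    "simulate_toy_trajectory",
    "rbc_spec",
    "popc_spec",
]


class InfeasibleSpecError(ValueError):
    """The requested membrane cannot be realized (area too small, etc.)."""


class PlacementError(ValueError):
    """Peptide grid placement does not fit the box."""


#: melittin, the 26-residue bee-venom peptide used as the hemolytic control
MEL_SEQUENCE = "GIGAVLKVLTTGLPALISWIKRKRQQ"

#: assumed area per lipid in nm^2, used only to convert a target membrane
#: area into integer leaflet counts; ratios, not absolute values, matter
DEFAULT_APL: Dict[str, float] = {
    "POPC": 0.64,
    "POPE": 0.60,
    "POPS": 0.62,
    "POSM": 0.55,
    "CHOL": 0.40,
}

# per-leaflet bead stacks: (bead name, |z| offset from the midplane in nm);
# heads outward, tails inward.  Tail-end beads are C4A/C4B for every
# phospholipid so the midplane estimate used by the flip-flop metric is
# species-independent.
_LIPID_STACKS: Dict[str, List[tuple[str, float]]] = {
    "POPC": [("NC3", 2.25), ("PO4", 1.95), ("GL1", 1.60), ("GL2", 1.50),
             ("C1A", 1.20), ("D2A", 0.90), ("C3A", 0.60), ("C4A", 0.30),
             ("C1B", 1.20), ("C2B", 0.90), ("C3B", 0.60), ("C4B", 0.30)],
    "POPE": [("NH3", 2.25), ("PO4", 1.95), ("GL1", 1.60), ("GL2", 1.50),
             ("C1A", 1.20), ("D2A", 0.90), ("C3A", 0.60), ("C4A", 0.30),
             ("C1B", 1.20), ("C2B", 0.90), ("C3B", 0.60), ("C4B", 0.30)],
    "POPS": [("CNO", 2.25), ("PO4", 1.95), ("GL1", 1.60), ("GL2", 1.50),
             ("C1A", 1.20), ("D2A", 0.90), ("C3A", 0.60), ("C4A", 0.30),
             ("C1B", 1.20), ("C2B", 0.90), ("C3B", 0.60), ("C4B", 0.30)],
    "POSM": [("NC3", 2.25), ("PO4", 1.95), ("AM1", 1.60), ("AM2", 1.50),
             ("T1A", 1.20), ("C2A", 0.90), ("C3A", 0.60), ("C4A", 0.30),
             ("C1B", 1.20), ("C2B", 0.90), ("C3B", 0.60), ("C4B", 0.30)],
    "CHOL": [("ROH", 1.75), ("R1", 1.45), ("R2", 1.35), ("R3", 1.15),
             ("R4", 1.05), ("R5", 0.85), ("C1", 0.55), ("C2", 0.30)],
}

#: formal charge per lipid (MARTINI headgroup convention)
LIPID_CHARGE: Dict[str, int] = {"POPC": 0, "POPE": 0, "POPS": -1, "POSM": 0, "CHOL": 0}

#: half of the headgroup-phosphate layer separation, nm
_HEAD_HALF_SEPARATION = 1.95
#: z extent the membrane occupies before solvent starts, nm
_MEMBRANE_HALF_THICKNESS = 2.4
#: per-lipid rigid z jitter and per-bead positional jitter, nm
_LIPID_Z_JITTER = 0.25
_BEAD_JITTER = 0.05
_LATTICE_XY_JITTER = 0.08

#: molarity of pure water, mol/L, for the salt-count estimate
_WATER_MOLARITY = 55.5
_WATERS_PER_W = 4

_AA_CHARGE = {
    "K": 1, "R": 1, "D": -1, "E": -1,
}
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSpec:
    """Composition and size of a flat (optionally asymmetric) bilayer.

    ``chol_fraction`` is the cholesterol mole fraction applied per
    leaflet; the remaining ``1 - chol_fraction`` of each leaflet is
    distributed among the phospholipids according to the composition
    maps.  ``upper_count_adjustment`` is a signed lipid-count offset for
    the upper leaflet, used to fine-tune asymmetric builds toward a
    common projected area.
    """

    upper_composition: Mapping[str, float]
    lower_composition: Mapping[str, float]
    chol_fraction: float = 0.0
    target_area: float = 100.0
    apl_by_species: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_APL))
    upper_count_adjustment: int = 0
    box_z: float = 10.0

    def __post_init__(self) -> None:
        for label, comp in (("upper", self.upper_composition), ("lower", self.lower_composition)):
            if not comp:
                raise ValueError(f"{label} composition is empty")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} leaflet fractions sum to {total}, expected 1")
            if any(f < 0 for f in comp.values()):
                raise ValueError(f"{label} leaflet has a negative fraction")
            for sp in comp:
                if sp not in _LIPID_STACKS or sp == "CHOL":
                    raise ValueError(f"unknown lipid species {sp!r}")
        if not 0.0 <= self.chol_fraction < 1.0:
            raise ValueError("chol_fraction must be in [0, 1)")
        if self.target_area <= 0:
            raise ValueError("target_area must be positive")
        if self.box_z <= 0:
            raise ValueError("box_z must be positive")


def rbc_spec(chol_fraction: float = 0.0, target_area: float = 100.0,
             upper_count_adjustment: int = 0) -> MembraneSpec:
    """RBC-mimetic asymmetric composition.

    Outer (upper) leaflet 45% POPC / 45% POSM / 10% POPE; inner (lower)
    leaflet 20% POPC / 10% POSM / 45% POPE / 25% POPS.
    """
    return MembraneSpec(
        upper_composition={"POPC": 0.45, "POSM": 0.45, "POPE": 0.10},
        lower_composition={"POPC": 0.20, "POSM": 0.10, "POPE": 0.45, "POPS": 0.25},
        chol_fraction=chol_fraction,
        target_area=target_area,
        upper_count_adjustment=upper_count_adjustment,
    )


def popc_spec(chol_fraction: float = 0.0, target_area: float = 100.0) -> MembraneSpec:
    """Single-species POPC membrane, optionally with cholesterol."""
    return MembraneSpec(
        upper_composition={"POPC": 1.0},
        lower_composition={"POPC": 1.0},
        chol_fraction=chol_fraction,
        target_area=target_area,
    )


def largest_remainder_counts(fractions: Mapping[str, float], total: int) -> Dict[str, int]:
    """Apportion ``total`` among species by the largest-remainder rule.

    Floors of ``fraction * total`` are assigned first; leftover units go
    to the species with the largest fractional remainders (ties broken
    by species name for determinism).
    """
    if total < 0:
        raise ValueError("total must be nonnegative")
    quotas = {sp: f * total for sp, f in fractions.items()}
    counts = {sp: int(math.floor(q)) for sp, q in quotas.items()}
    leftover = total - sum(counts.values())
    remainders = sorted(
        quotas, key=lambda sp: (-(quotas[sp] - counts[sp]), sp)
    )
    for sp in remainders[:leftover]:
        counts[sp] += 1
    return counts


# ---------------------------------------------------------------------------
# membrane construction
# ---------------------------------------------------------------------------

def _leaflet_counts(spec: MembraneSpec, composition: Mapping[str, float],
                    adjustment: int = 0) -> Dict[str, int]:
    c = spec.chol_fraction
    mean_apl = c * spec.apl_by_species["CHOL"] + (1 - c) * sum(
        f * spec.apl_by_species[sp] for sp, f in composition.items()
    )
    n_total = int(round(spec.target_area / mean_apl)) + adjustment
    if n_total < 1:
        raise InfeasibleSpecError("target_area too small for a single lipid")
    fractions = {sp: (1 - c) * f for sp, f in composition.items() if f > 0}
    if c > 0:
        fractions["CHOL"] = c
    counts = largest_remainder_counts(fractions, n_total)
    for sp, n in counts.items():
        if n < 1:
            raise InfeasibleSpecError(
                f"target_area {spec.target_area} nm^2 rounds species {sp} to zero lipids"
            )
    return counts


def _place_leaflet(rng: np.random.Generator, counts: Dict[str, int], box: np.ndarray,
                   z_mid: float, sign: int, tag: str,
                   first_resid: int) -> tuple[list, list, list, list, list, int]:
    """Lay one leaflet's lipids on a jittered square lattice."""
    n = sum(counts.values())
    species = [sp for sp in sorted(counts) for _ in range(counts[sp])]
    rng.shuffle(species)
    nx = int(math.ceil(math.sqrt(n)))
    ny = int(math.ceil(n / nx))
    dx, dy = box[0] / nx, box[1] / ny
    sites = [((i + 0.5) * dx, (j + 0.5) * dy) for j in range(ny) for i in range(nx)][:n]

    names: list = []
    resnames: list = []
    resids: list = []
    positions: list = []
    tags: list = []
    resid = first_resid
    for (x0, y0), sp in zip(sites, species):
        xy_jit = rng.normal(0.0, _LATTICE_XY_JITTER, size=2)
        z_jit = rng.normal(0.0, _LIPID_Z_JITTER)
        for bead, z_off in _LIPID_STACKS[sp]:
            jit = rng.normal(0.0, _BEAD_JITTER, size=3)
            x = x0 + xy_jit[0] + jit[0]
            y = y0 + xy_jit[1] + jit[1]
            z = z_mid + sign * (z_off + z_jit) + jit[2]
            names.append(bead)
            resnames.append(sp)
            resids.append(resid)
            positions.append((x, y, z))
            tags.append(tag)
        resid += 1
    return names, resnames, resids, positions, tags, resid


def _solvate(rng: np.random.Generator, n_waters: int, box: np.ndarray, z_mid: float,
             first_resid: int) -> tuple[list, list, list, list, list, int]:
    """Fill the two solvent slabs with W beads on a jittered cubic lattice."""
    slab_lo = (0.25, z_mid - _MEMBRANE_HALF_THICKNESS - 0.15)
    slab_hi = (z_mid + _MEMBRANE_HALF_THICKNESS + 0.15, box[2] - 0.25)
    slabs = [slab_lo, slab_hi]
    heights = [hi - lo for lo, hi in slabs]
    if min(heights) <= 0:
        raise InfeasibleSpecError("box_z leaves no room for solvent slabs")
    per_slab = [int(round(n_waters * h / sum(heights))) for h in heights]
    per_slab[1] = n_waters - per_slab[0]

    names: list = []
    resnames: list = []
    resids: list = []
    positions: list = []
    tags: list = []
    resid = first_resid
    for (lo, hi), n_slab in zip(slabs, per_slab):
        if n_slab == 0:
            continue
        vol = box[0] * box[1] * (hi - lo)
        spacing = (vol / n_slab) ** (1.0 / 3.0)
        nx = max(1, int(math.ceil(box[0] / spacing)))
        ny = max(1, int(math.ceil(box[1] / spacing)))
        nz = max(1, int(math.ceil(n_slab / (nx * ny))))
        k = 0
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    if k >= n_slab:
                        break
                    jit = rng.normal(0.0, 0.03, size=3)
                    x = (ix + 0.5) * box[0] / nx + jit[0]
                    y = (iy + 0.5) * box[1] / ny + jit[1]
                    z = lo + (iz + 0.5) * (hi - lo) / nz + jit[2]
                    names.append("W")
                    resnames.append("W")
                    resids.append(resid)
                    positions.append((x, y, min(max(z, lo), hi)))
                    tags.append("none")
                    resid += 1
                    k += 1
    return names, resnames, resids, positions, tags, resid


def build_membrane(spec: MembraneSpec, seed: int = 0) -> BeadConfiguration:
    """Assemble a flat solvated bilayer from a composition specification.

    Lipids are placed on jittered per-leaflet lattices with heads
    outward; species counts follow largest-remainder rounding of the
    leaflet compositions; the system is solvated with at least 10 W
    beads (40 water molecules) per membrane component and 150 mM NaCl
    plus counterions for exact electroneutrality.
    """
    rng = np.random.default_rng(seed)
    side = math.sqrt(spec.target_area)
    box = np.array([side, side, spec.box_z], dtype=np.float64)
    z_mid = spec.box_z / 2.0

    upper_counts = _leaflet_counts(spec, spec.upper_composition, spec.upper_count_adjustment)
    lower_counts = _leaflet_counts(spec, spec.lower_composition)

    names: list = []
    resnames: list = []
    resids: list = []
    positions: list = []
    tags: list = []
    resid = 1
    for counts, sign, tag in ((upper_counts, +1, "upper"), (lower_counts, -1, "lower")):
        out = _place_leaflet(rng, counts, box, z_mid, sign, tag, resid)
        names += out[0]; resnames += out[1]; resids += out[2]
        positions += out[3]; tags += out[4]; resid = out[5]

    n_components = sum(upper_counts.values()) + sum(lower_counts.values())
    n_w_retained = 10 * n_components
    # 150 mM NaCl relative to the retained water volume (4 waters per W
    # bead), then counterions to neutralize the lipid charge; ions replace
    # solvent beads, so extra W beads are placed to keep >= 10 W per
    # membrane component after the swap
    n_pairs = int(round(n_w_retained * _WATERS_PER_W * 0.150 / _WATER_MOLARITY))
    lipid_charge = sum(
        LIPID_CHARGE[sp] * n
        for counts in (upper_counts, lower_counts)
        for sp, n in counts.items()
    )
    n_na = n_pairs + max(0, -lipid_charge)
    n_cl = n_pairs + max(0, lipid_charge)
    n_waters = n_w_retained + n_na + n_cl
    out = _solvate(rng, n_waters, box, z_mid, resid)
    names += out[0]; resnames += out[1]; resids += out[2]
    positions += out[3]; tags += out[4]; resid = out[5]

    config = BeadConfiguration(
        names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids, dtype=np.int64),
        positions=np.array(positions, dtype=np.float64),
        box=box,
        leaflet_tags=np.array(tags, dtype=object),
    ).wrap()

    w_indices = np.flatnonzero(config.names.astype(str) == "W")
    if n_na + n_cl > len(w_indices):
        raise InfeasibleSpecError("not enough solvent beads to place the requested ions")
    chosen = rng.choice(w_indices, size=n_na + n_cl, replace=False)
    for i in chosen[:n_na]:
        config.names[i] = "NA+"
        config.residue_names[i] = "ION"
    for i in chosen[n_na:]:
        config.names[i] = "CL-"
        config.residue_names[i] = "ION"
    return config


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

@dataclass
class PeptideModel:
    """Backbone-resolution peptide model (one bead per residue).

    The kinked conformation mirrors a helix whose proper dihedrals at
    the terminal coils and the central turn are removed; those residue
    indices are recorded in ``flexible_residues`` (1-based).
    """

    sequence: str
    conformation: str
    backbone_positions: np.ndarray
    per_residue_charge: np.ndarray
    net_charge: int
    flexible_residues: frozenset[int] = frozenset()

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def make_peptide_model(sequence: str, conformation: str = "helical") -> PeptideModel:
    """Build an idealized helical (or kinked) peptide backbone model.

    Side-chain charges follow the MARTINI convention (+1 for Lys/Arg,
    -1 for Asp/Glu); the N-terminus carries +1 and the C-terminus is
    treated as amidated (neutral).  For melittin this yields a net
    charge of +6.
    """
    sequence = sequence.upper()
    if conformation not in ("helical", "kinked"):
        raise ValueError("conformation must be 'helical' or 'kinked'")
    bad = set(sequence) - _AA_LETTERS
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")

    charges = np.array([_AA_CHARGE.get(aa, 0) for aa in sequence], dtype=np.int64)
    net = int(charges.sum()) + 1  # +1 N-terminus; amidated C-terminus is neutral

    # ideal alpha-helix backbone: 0.15 nm rise and 100 degrees per residue,
    # 0.23 nm helix radius, axis along x and centered at the origin
    i = np.arange(n)
    phase = np.deg2rad(100.0 * i)
    axis = (i - (n - 1) / 2.0) * 0.15
    backbone = np.column_stack([axis, 0.23 * np.cos(phase), 0.23 * np.sin(phase)])

    flexible = frozenset({1, 11, 26} if conformation == "kinked" else set())
    return PeptideModel(
        sequence=sequence,
        conformation=conformation,
        backbone_positions=backbone,
        per_residue_charge=charges,
        net_charge=net,
        flexible_residues=flexible,
    )


def place_peptides(config: BeadConfiguration, model: PeptideModel, n_peptides: int,
                   offset: float = 2.5) -> BeadConfiguration:
    """Place peptide copies on an evenly spaced xy grid above the membrane.

    Each copy sits with its helix axis in the xy-plane (along y) at
    ``membrane COM z + offset``.  Chloride counterions are converted
    from solvent beads to keep the total system charge at zero.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if n_peptides < 1:
        raise ValueError("n_peptides must be at least 1")
    box = config.box
    rows = int(math.floor(math.sqrt(n_peptides)))
    cols = int(math.ceil(n_peptides / rows))
    spacing_x = box[0] / cols
    spacing_y = box[1] / rows
    extent_y = (model.n_residues - 1) * 0.15
    if spacing_x < 0.5 or spacing_y - extent_y < 0.5:
        raise PlacementError(
            f"{rows}x{cols} grid with {model.n_residues}-residue peptides does not fit "
            f"a {box[0]:.1f}x{box[1]:.1f} nm box"
        )

    membrane_mask = config.leaflet_tags.astype(str) != "none"
    if not membrane_mask.any():
        raise ValueError("configuration has no membrane to place peptides above")
    z_com = float(np.mean(config.positions[membrane_mask, 2]))
    z_target = z_com + offset

    # helix axis along y: swap the model's x axis into y
    template = model.backbone_positions[:, [1, 0, 2]].copy()

    names: list = []
    resnames: list = []
    resids: list = []
    positions: list = []
    tags: list = []
    next_resid = int(config.residue_ids.max()) + 1 if config.n_beads else 1
    placed = 0
    for j in range(rows):
        for i in range(cols):
            if placed >= n_peptides:
                break
            if n_peptides == 1:
                cx, cy = box[0] / 2.0, box[1] / 2.0
            else:
                cx = (i + 0.5) * spacing_x
                cy = (j + 0.5) * spacing_y
            pts = template + np.array([cx, cy, z_target])
            for r in range(model.n_residues):
                names.append(f"BB{r + 1}")
                resnames.append("MEL")
                resids.append(next_resid)
                positions.append(tuple(pts[r]))
                tags.append("none")
            next_resid += 1
            placed += 1

    peptide = BeadConfiguration(
        names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.array(resids, dtype=np.int64),
        positions=np.array(positions, dtype=np.float64),
        box=box.copy(),
        leaflet_tags=np.array(tags, dtype=object),
    )
    merged = config.concatenate(peptide).wrap()

    # neutralize the peptide charge by converting W beads to chloride
    total_peptide_charge = model.net_charge * n_peptides
    if total_peptide_charge > 0:
        w_indices = np.flatnonzero(merged.names.astype(str) == "W")
        if len(w_indices) < total_peptide_charge:
            raise InfeasibleSpecError("not enough solvent beads for counterions")
        for i in w_indices[:total_peptide_charge]:
            merged.names[i] = "CL-"
            merged.residue_names[i] = "ION"
    return merged


def total_charge(config: BeadConfiguration, peptide_net_charge: int = 0,
                 n_peptides: int = 0) -> int:
    """Formal system charge: lipids + ions + (optionally) peptides."""
    names = config.names.astype(str)
    charge = -int(np.count_nonzero(
        (config.residue_names.astype(str) == "POPS") & (names == "PO4")
    ))
    charge += int(np.count_nonzero(names == "NA+"))
    charge -= int(np.count_nonzero(names == "CL-"))
    charge += peptide_net_charge * n_peptides
    return charge


# ---------------------------------------------------------------------------
# pore carving
# ---------------------------------------------------------------------------

def carve_pore(config: BeadConfiguration, xi_target: float, xi_spec: XiSpec,
               seed: int = 0) -> BeadConfiguration:
    """Relocate solvent into the pore cylinder until xi matches ``xi_target``.

    Lipid residues overlapping the filled column are displaced radially
    outward first; W beads from the bulk are then moved into the
    unsaturated slices (center outward) until the mean slice occupancy
    reaches the target.  A flat membrane already within 0.05 of the
    target is returned unchanged.
    """
    if not 0.2 <= xi_target <= 1.0:
        raise ValueError("xi_target must lie in [0.2, 1.0]")
    rng = np.random.default_rng(seed)
    occ = compute_xi(config, xi_spec)
    if abs(occ.xi - xi_target) <= 0.05:
        return config.copy()

    result = config.copy()
    center_xy = (np.asarray(xi_spec.center_xy, dtype=np.float64)
                 if xi_spec.center_xy is not None else result.box[:2] / 2.0)

    # slices ordered from the stack center outward
    n_s = xi_spec.n_slices
    order = sorted(range(n_s), key=lambda s: (abs(s - (n_s - 1) / 2.0), s))

    # displace overlapping lipid residues radially outward
    names = result.names.astype(str)
    tags = result.leaflet_tags.astype(str)
    lipid_mask = tags != "none"
    z_lo, z_hi = occ.slice_edges[0], occ.slice_edges[-1]
    dxy_all = minimum_image_xy(result.positions[:, :2] - center_xy, result.box)
    r_all = np.sqrt(np.einsum("ij,ij->i", dxy_all, dxy_all))
    overlap = (lipid_mask & (r_all < xi_spec.radius)
               & (result.positions[:, 2] > z_lo) & (result.positions[:, 2] < z_hi))
    for resid in np.unique(result.residue_ids[overlap]):
        res_mask = result.residue_ids == resid
        com_xy = result.positions[res_mask, :2].mean(axis=0)
        d = minimum_image_xy(com_xy - center_xy, result.box)[0]
        r = float(np.hypot(*d))
        if r < 1e-6:
            theta = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            r = 1.0
        shift = d / r * (xi_spec.radius + 0.3 - r)
        result.positions[res_mask, 0] += shift[0]
        result.positions[res_mask, 1] += shift[1]
    result = result.wrap()

    occ = compute_xi(result, xi_spec)
    counts = occ.per_slice_counts.copy()
    n0 = xi_spec.saturation_count
    target_total = xi_target * n_s  # in units of slice occupancy

    # W beads far from the cylinder are candidates for relocation
    names = result.names.astype(str)
    w_idx = np.flatnonzero(names == "W")
    dxy_w = minimum_image_xy(result.positions[w_idx, :2] - center_xy, result.box)
    r_w = np.sqrt(np.einsum("ij,ij->i", dxy_w, dxy_w))
    donors = list(w_idx[np.argsort(-r_w)])

    current_total = float(np.minimum(1.0, counts / n0).sum())
    quantum = 1.0 / n0
    moves: list[tuple[int, int]] = []  # (bead index, slice index)
    while current_total < target_total - quantum / 2.0:
        slice_idx = None
        for s in order:
            if counts[s] < n0:
                slice_idx = s
                break
        if slice_idx is None:
            break
        if not donors:
            raise InfeasibleSpecError("insufficient solvent to fill the requested defect")
        moves.append((donors.pop(0), slice_idx))
        counts[slice_idx] += 1
        current_total += quantum

    for bead, s in moves:
        theta = rng.uniform(0, 2 * np.pi)
        rad = xi_spec.radius * 0.8 * math.sqrt(rng.uniform())
        z = rng.uniform(occ.slice_edges[s] + 0.01, occ.slice_edges[s + 1] - 0.01)
        result.positions[bead] = (
            center_xy[0] + rad * math.cos(theta),
            center_xy[1] + rad * math.sin(theta),
            z,
        )
    return result.wrap()


# ---------------------------------------------------------------------------
# toy dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyTrajectoryParams:
    """Parameters of the overdamped toy membrane dynamics.

    ``flip_rate`` is the per-frame probability that a lower-leaflet
    lipid of ``flip_species`` translocates to the upper leaflet while
    the pore is open; ``flip_back_rate`` is the reverse rate, so the
    equilibrium upper fraction is ``flip_rate / (flip_rate +
    flip_back_rate)``.  Box-area fluctuations are drawn as a stationary
    Gaussian process with the requested mean and variance.  These are
    not physical dynamics: the diffusion step is a plain config knob.
    """

    timestep: float = 50.0            # ns between frames
    diffusion_step: float = 0.1       # nm lateral rms step per frame per lipid
    flip_species: str = "POPS"
    flip_rate: float = 0.03
    flip_back_rate: float = 0.07
    pore_open: bool = True
    area_mean: float = 100.0          # nm^2
    area_variance: float = 2.0        # nm^4

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must lie in [0, 1]")
        if not 0.0 <= self.flip_back_rate <= 1.0:
            raise ValueError("flip_back_rate must lie in [0, 1]")
        if self.area_variance < 0:
            raise ValueError("area_variance must be nonnegative")
        if self.area_mean <= 0:
            raise ValueError("area_mean must be positive")

    @property
    def flip_equilibrium_fraction(self) -> float:
        if self.flip_rate == 0 and self.flip_back_rate == 0:
            return 0.0
        return self.flip_rate / (self.flip_rate + self.flip_back_rate)


@dataclass
class ToyTrajectory:
    """An ordered frame sequence with the generating parameters attached."""

    frames: List[BeadConfiguration]
    times: np.ndarray
    params: ToyTrajectoryParams
    seed: int

    @property
    def timestep(self) -> float:
        return self.params.timestep


def sample_area_series(params: ToyTrajectoryParams, n_frames: int, seed: int = 0) -> np.ndarray:
    """Draw the stationary Gaussian box-area process on its own.

    The same process drives the per-frame boxes in
    :func:`simulate_toy_trajectory`; sampling it standalone allows long
    fluctuation analyses (e.g. area-compressibility estimates) without
    materializing bead coordinates.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)
    areas = rng.normal(params.area_mean, math.sqrt(params.area_variance), size=n_frames)
    return np.maximum(areas, 0.25 * params.area_mean)


def simulate_toy_trajectory(config: BeadConfiguration, params: ToyTrajectoryParams,
                            n_frames: int, seed: int = 0) -> ToyTrajectory:
    """Generate a toy trajectory from a starting configuration.

    Lipids random-walk laterally, flagged lipids flip between leaflets
    by z-reflection about the midplane, and the box xy-area fluctuates
    about its mean.  Fully reproducible from the seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)
    z_mid = config.box[2] / 2.0

    frames: List[BeadConfiguration] = []
    current = config.copy()

    resids = current.residue_ids
    lipid_mask = current.leaflet_tags.astype(str) != "none"
    lipid_resids, bead_lipid_ord = np.unique(resids, return_inverse=True)
    is_lipid_res = np.isin(lipid_resids, np.unique(resids[lipid_mask]))
    lipid_ord = np.flatnonzero(is_lipid_res)
    n_lip = len(lipid_ord)
    # per-residue-ordinal bookkeeping
    res_tag = np.full(len(lipid_resids), "none", dtype=object)
    for ord_ in lipid_ord:
        res_tag[ord_] = current.leaflet_tags[bead_lipid_ord == ord_][0]
    flip_ord = np.flatnonzero(is_lipid_res & np.isin(
        lipid_resids,
        np.unique(resids[current.residue_names.astype(str) == params.flip_species]),
    ))
    base_z = current.positions[:, 2].copy()
    # stationary vertical bobbing (OU) keeps the z distribution Gaussian
    # while decorrelating frames, so pooled density profiles converge
    z_bob_sd = 0.15
    z_bob_decay = 0.6
    d_z = np.zeros(len(lipid_resids))
    area_sd = math.sqrt(params.area_variance)

    for k in range(n_frames):
        if k > 0:
            # lateral random walk, whole residues move rigidly
            steps = rng.normal(0.0, params.diffusion_step, size=(n_lip, 2))
            per_res_step = np.zeros((len(lipid_resids), 2))
            per_res_step[lipid_ord] = steps
            current.positions[lipid_mask, :2] += per_res_step[bead_lipid_ord[lipid_mask]]
            # leaflet flips by z-reflection about the midplane
            if params.pore_open and len(flip_ord):
                u = rng.uniform(size=len(flip_ord))
                rates = np.where(res_tag[flip_ord] == "lower",
                                 params.flip_rate, params.flip_back_rate)
                flipping = flip_ord[u < rates]
                if len(flipping):
                    beads = np.isin(bead_lipid_ord, flipping)
                    base_z[beads] = 2 * z_mid - base_z[beads]
                    res_tag[flipping] = np.where(res_tag[flipping] == "lower",
                                                 "upper", "lower")
                    current.leaflet_tags[beads] = np.array(
                        [res_tag[o] for o in bead_lipid_ord[beads]], dtype=object
                    )
            d_z = z_bob_decay * d_z + math.sqrt(1 - z_bob_decay**2) * rng.normal(
                0.0, z_bob_sd, size=len(lipid_resids))
            current.positions[lipid_mask, 2] = (
                base_z[lipid_mask] + d_z[bead_lipid_ord[lipid_mask]]
            )
            # stationary Gaussian area process; positions rescale affinely
            area = max(rng.normal(params.area_mean, area_sd), 0.25 * params.area_mean)
            scale = math.sqrt(area / (current.box[0] * current.box[1]))
            current.positions[:, :2] *= scale
            current.box[0] *= scale
            current.box[1] *= scale
            current = current.wrap()
        frames.append(current.copy())

    times = np.arange(n_frames) * params.timestep
    return ToyTrajectory(frames=frames, times=times, params=params, seed=seed)
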