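# Methods

This note records what each component of `xipore` computes, the
assumptions behind it, the defaults and why, and what the synthetic
data generator does and does not emulate.

## The nucleation coordinate

`compute_xi` implements the sliced-cylinder coordinate
`xi = (1/N_s) sum_s min(1, n_s/N_0)`: polar particles inside a cylinder
of radius `R` (closed disk, minimum image in xy only — membranes are
periodic laterally and finite in z) are binned into `N_s` z-slices of
thickness `d` centered on the slice-stack anchor. Counting is *hard*
(non-smooth): this package only evaluates the coordinate on stored
configurations or drives Metropolis sampling, so `d(xi)/dx` is never
needed and the smooth switching functions used for biased MD forces are
out of scope.

Defaults, with units and rationale:

| parameter | CG | atomistic | why |
| --- | --- | --- | --- |
| slice thickness `d` | 0.2 nm | 0.1 nm | standard values for bead vs atom densities |
| saturation count `N_0` | 2 beads | 3 molecules | AA value is the unique choice making full occupancy of the central 1 nm equal ~30 waters at 0.1 nm slices; the CG value is a config default (not uniquely pinned by any anchor) |
| radius `R` | 1.2 nm | 1.2 nm | typical pore-column radius; configurable |
| polar selection | W, PO4 | OW, P | water + lipid phosphate |
| `N_s` | calibrated | calibrated | chosen per membrane so flat frames score ~0.2 |
| z anchor | polar mean z | polar mean z | recomputed per frame; options: `po4_mean`, `box_center`, explicit z |

`select_slice_count` scans candidate `N_s` over unbiased flat frames
and returns the count whose mean xi is closest to the flat anchor 0.2,
ties toward fewer slices. On the synthetic builders this lands at
`N_s ~ 22` (POPC) to `~ 28` (RBC) with flat xi 0.18-0.20; the absolute
counts differ from real MARTINI membranes because the synthetic head
density profile is a Gaussian of chosen width, not a force-field
property — only the calibration *procedure* and the flat/full anchors
carry over.

`count_central_polar` reports the polar count in the central window of
the cylinder and a water-molecule equivalent (x4 per W bead for CG — a
MARTINI W bead represents four waters — or the water-oxygen count for
atomistic selections).

## Synthetic membranes

`build_membrane` is a lattice placer, not a physical assembler. Each
leaflet's molecule count is `round(target_area / mean molecular
area)`, with per-species areas taken from a configurable prior (POPC
0.64, POPE 0.60, POPS 0.62, POSM 0.55, CHOL 0.40 nm^2; only ratios
matter). Species are apportioned by largest-remainder rounding, which
makes composition conservation exact and, for the RBC inner leaflet
(20/10/45/25 PC/SM/PE/PS at 100 nm^2), reproduces the 25% POPS
fraction exactly. Lipids sit on jittered square lattices with
MARTINI-style bead stacks (PO4 at +-1.95 nm about the midplane, tail
ends C4A/C4B for every species so the flip-flop midplane rule is
species-independent), heads outward. The per-lipid vertical jitter
(sd 0.25 nm) stands in for membrane undulations and sets the width of
the head-density peaks; it was chosen once so that slice-count
calibration behaves like it does on real flat membranes.

Solvation places `10 x (lipids + CHOL) + n_ions` W beads in the two
slabs; 150 mM NaCl is converted to an ion-pair count via 4 waters per W
bead and 55.5 mol/L, counterions enforce exact electroneutrality
(POPS -1, melittin +6), and ions replace W beads so the 10-per-component
floor still holds afterwards.

The melittin model is backbone-only (one bead per residue, ideal
alpha-helix: 0.15 nm rise, 100 degrees per turn, 0.23 nm radius).
Charges follow the MARTINI convention: +1 Lys/Arg, -1 Asp/Glu, +1
N-terminus, amidated (neutral) C-terminus — the only convention under
which melittin's 3 Lys + 2 Arg + N-terminus give the +6 net charge the
pore-lining electrostatics argument rests on. The kinked conformer is
bookkept by its flexible residues {1, 11, 26} (terminal coils and the
central turn); at backbone resolution its geometry is not altered.

`carve_pore` displaces lipids radially out of the cylinder and moves
far-away W beads into unsaturated slices (center outward) until the
recomputed xi is within 0.05 of the target; a flat membrane already
within tolerance is returned untouched. The round trip
`compute_xi(carve_pore(x, t))` is tested at t = 0.3 ... 1.0.

`simulate_toy_trajectory` is overdamped bookkeeping, not physics:
lipids random-walk laterally (rms step 0.1 nm/frame by default, a pure
config knob), lipids of the flip species translocate between leaflets
by z-reflection about the midplane with per-frame probabilities
`flip_rate` (up) and `flip_back_rate` (down) — the reverse rate exists
because a one-way process has no interior equilibrium; defaults
0.03/0.07 give the 0.3 equilibrium upper fraction used as the flip-flop
anchor — and the box xy-area follows an i.i.d. Gaussian with configured
mean and variance (default 100 nm^2, 2.0 nm^4, which corresponds to
K_A = 214 mN/m at 310 K). A stationary per-lipid vertical offset
(AR(1), sd 0.15 nm) decorrelates z between frames so pooled density
profiles converge; without it the head-density histogram is bin-noise
limited no matter how many frames are pooled. Everything is reproducible
bit-for-bit from the seed.

What the generator does **not** emulate: force-field energetics,
realistic diffusion constants, undulation spectra, curvature stress,
peptide conformational dynamics, or pore closure kinetics. Tests that
pass on this data certify the *estimators and protocol logic*, not any
biophysical prediction about real membranes.

## Equilibration scheduling

`plan_equilibration(xi_long)` emits the explicit pull/hold schedule:
50 ns pull from the flat state (xi = 0.2) to `xi_long`, a 5000 ns hold
(so the lining decision time t_cutoff is always 5050 ns), then for each
multiple of 0.1 strictly above `xi_long` a 50 ns pull and a 500 ns
hold — except no hold after the final pull to xi = 1.0, which is the
window-extraction point. Pull duration does not scale with xi distance.
These two rules are the only reading consistent with both printed
totals (6.2 us for xi_long in [0.7, 0.775]; 5.65 us in [0.8, 0.875]);
the total is therefore a step function of xi_long, constant on those
brackets (and e.g. 5.1 us for xi_long = 0.95). `run_xi_long_search`
wraps the restart loop: start at 0.7, step 0.025, stop at the first
xi_long whose lining oracle fires; the scheduler only plans — driving a
plan on synthetic data means carving a pore per phase.

`make_window_grid` returns the shared 23-center grid (0.2 to 0.7 by
0.05, 0.725 to 1.0 by 0.025) with 10000/20000 kJ/mol force constants
and 500 ns/window in CG mode, 5000/10000 kJ/mol and 50 ns/window with a
10 ns discard and 0.1 ns save interval in atomistic mode (400 retained
samples per window).

## Umbrella sampling and WHAM

`sample_surrogate` draws per-window samples by Metropolis sampling of
xi under `true PMF + harmonic bias` at the dataset temperature
(defaults: 310 K atomistic, 323 K CG, matching the two thermostat
settings the protocol uses). The Gaussian proposal width auto-tunes to
a 20-50% acceptance rate during burn-in (1000 steps), and one sample is
recorded every 10 Metropolis steps — the surrogate analogue of saving
configurations at fixed time intervals rather than every step. The
thinning matters quantitatively: recording every step leaves enough
chain autocorrelation that the harmonic-recovery RMSE fluctuates by
2x across seeds.

`WHAM` iterates the standard self-consistent equations on a common
histogram grid (default 200 bins over [0.15, 1.05]; bins with zero
global count are masked, not zero-filled) in log space with
log-sum-exp stabilization, converging on the maximum per-iteration
window-shift change (default 1e-6 kJ/mol, cap 1e5 iterations; hitting
the cap flags `converged=False` rather than raising). Adjacent windows
must share at least one occupied bin, otherwise a coverage error names
the gap. The profile is anchored to zero at its minimum. Statistical
inefficiency weighting and MBAR are out of scope; replica scatter is
summarized as pointwise mean +- standard error across seeds
(`replica_mean_se`), without aligning profiles first.

`convergence_series` re-solves on growing prefixes of each window's
samples (the cumulative-sampling-time convergence check);
`delta_g` interpolates two minimum-anchored profiles at an evaluation
point (1.0 = the full-pore state) and differences them.

Validation: a 200 (xi-0.6)^2 kJ/mol harmonic truth sampled at 5000
points per window on the 23-window grid is recovered with RMSE <= 0.5
kJ/mol over xi in [0.3, 0.9] (measured 0.15-0.35 across seeds); a flat
truth stays within histogram noise; duplicated windows match the
single-window profile; doubling all force constants moves the estimate
only within noise.

## Backmapping

The backmapping layer is purely geometric — no force-field
minimization; fidelity claims are bond lengths, chirality, cis/trans
isomerism and clash avoidance, audited by `validate_geometry`.

Mapping tables are plain text (`[residue]`, `[beads]`, `[bonds]` with
optional explicit lengths, `[chiral]`, `[cis]`, `[trans]`). Bundled
tables cover the four phospholipids (12-bead MARTINI-2.2-style
mappings; the sphingomyelin table is newly authored and carries the
sphingosine 4,5-trans double bond) and cholesterol (8 beads, all 8
stereocenters in the natural-product configuration; handedness signs
were frozen from a stereochemically correct 3D reference structure).
Atom naming is heavy-atom plus the stereo-defining hydrogens; the
atom-per-bead partitions are this package's own and are claimed to be
geometrically valid, not byte-identical to any published mapping file.
Equilibrium bond lengths come from a small generic element-pair table
(C-C 0.153, C=C 0.134, C-O 0.143, C-N 0.147, C-H 0.109, O-H 0.096,
P-O 0.161 nm; carbonyls 0.123 nm explicitly in the tables).

`project_structure` initializes every atom at its bead position plus a
deterministic spherical offset (<= 0.05 nm), then relaxes bonds by
iterative symmetric projection while re-centering each bead's atom
cloud on the bead (<= 500 sweeps). W beads expand to four waters; ion
beads to single atoms.

Repairs are applied in a loop (typically 1-2 rounds, capped at 20)
because they can mildly disturb one another:

1. **cis/trans**: the terminal dihedral atom is rotated about the bond
   axis onto the target (repair trigger 1 degree, audit tolerance 5),
   and the target isomerism is additionally encoded as 1-3 and 1-4
   distance constraints (sp2 120-degree geometry, planar unit) added to
   the bond set during relaxation. For 0/180-degree targets those
   distances pin the dihedral up to a mirror image with the same
   torsion, so plain distance projection maintains them. The downstream
   fragment is still traversed to reject directives across ring bonds.
   Rotating the whole downstream fragment instead would sweep tail
   atoms ~1 nm from their beads, which is incompatible with keeping
   bead centroids consistent.
2. **clash separation**: non-bonded pairs closer than 0.05 nm are
   pushed to 0.06 nm.
3. **chirality**: a violating movable substituent (always a hydrogen or
   terminal methyl bonded only to its center) is reflected through the
   plane of the center and the first two substituents. The reflection
   flips the signed volume while preserving the bond length exactly, so
   it needs no re-relaxation and is idempotent.

The audit checks bonds within [0.05, 0.25] nm, signed volumes against
directive signs, dihedrals within 5 degrees, and intra-residue clashes.
Across 200 randomly oriented single-lipid reconstructions (40 seeds x 5
species) the pipeline produces clean reports with bead-centroid
deviations <= 0.06 nm (tolerance 0.15 nm).

## Trajectory analytics

Conventions shared by all estimators: distances are xy minimum-image;
"within r" is a closed disk; the membrane midplane is the mean z of all
lipid tail-end C4A/C4B beads (all species, not just the flip species);
head-phosphate particles are PO4 (CG) or P (atomistic).

- `flip_flop_fraction`: species headgroups above the midplane over the
  species total.
- `count_near_pore` / `lipid_fraction_near_pore`: head counts within r
  of the pore axis; fractions are time-averaged counts normalized by
  the time-averaged total, so they sum to one.
- `choose_enrichment_radius`: smallest radius on a 0.1 nm grid whose
  time-averaged total head count reaches the target (the calibration
  that sets ~30 lipids for the full-pore state).
- `pore_lining_count`: peptide backbone beads within the central 1 nm
  window, normalized by the count for one fully inserted reference
  peptide (a 26-residue helix at 90 degrees tilt contributes 6 backbone
  beads to the window — the configurable "density of one pore-lining
  peptide"), reported with its nearest-integer rounding.
- `tilt_angles`: arcsin(|v_z|/|v|) of the N-to-C terminal backbone
  vector, 0 = flat, 90 = fully pore-lining; the lining flag is set when
  the peptide contributes any backbone bead to the central window (a
  bead-contribution rule; the alternative distance-cutoff definition is
  not used).
- `area_per_lipid`: mean box xy-area over mean upper-leaflet molecule
  count (cholesterol included).
- `bilayer_thickness`: 200-bin z histogram of head phosphates pooled
  over frames, split at the median z; thickness is the distance between
  the maximal-density bins of the two halves (a global maximum per
  half-space, deliberately not a general peak finder).
- `area_compressibility`: K_A = k_B T <A> / Var(A) in mN/m, the
  standard equilibrium fluctuation estimator; at 1e5 frames the sampling
  error of Var(A) is ~0.45%, so the 5% recovery check is dominated by
  the estimator itself.
- `order_parameter`: S = <(3 cos^2 theta - 1)/2> per tail position with
  theta against the membrane normal; bounds [-0.5, 1].
- `smooth_series`: centered adjacent averaging with shrinking windows
  at the edges (length-preserving, bounded by the input range). Note:
  shrinking-window averaging does not conserve the global mean of an
  arbitrary series — only of constant ones — so no such invariant is
  claimed.

## Problem sizes and determinism

The test suite and the acceptance script use deliberately modest
problem sizes — ~330-lipid membranes (100 nm^2), 400-frame toy
trajectories, 5000 umbrella samples per window, 1e5-sample area series,
10-molecule backmapping batches — chosen as the smallest sizes at which
each statistical check has comfortable margin (3+ standard errors)
against its tolerance. Every stochastic component takes an explicit
integer seed (numpy `default_rng`); reruns are bit-identical, and the
pipeline manifest records seeds plus a config digest.

## Known limitations

- The generator's geometric realism is limited to what the estimators
  measure; its calibrated slice counts and flat-xi values do not
  transfer quantitatively to force-field membranes.
- The WHAM solver has no autocorrelation correction; users feeding it
  correlated series should subsample first (the surrogate sampler
  already does).
- Backmapped structures are geometrically valid but not energetically
  relaxed; they are starting points, not equilibrated configurations.
- The peptide model is backbone-only; side-chain packing, rotamers and
  secondary-structure dynamics are out of scope.
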