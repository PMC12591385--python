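import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xipore import (
    MEL_SEQUENCE,
    XiSpec,
    build_membrane,
    carve_pore,
    compute_xi,
    make_peptide_model,
    place_peptides,
    popc_spec,
    rbc_spec,
    simulate_toy_trajectory,
)
from xipore.membrane import (
    InfeasibleSpecError,
    MembraneSpec,
    PlacementError,
    ToyTrajectoryParams,
    largest_remainder_counts,
    sample_area_series,
    total_charge,
)


# ---------------------------------------------------------------------------
# composition and counting
# ---------------------------------------------------------------------------

class TestBuildMembrane:
    def test_rbc_lower_leaflet_pops_fraction_is_exactly_one_quarter(self, rbc_membrane):
        tags = rbc_membrane.leaflet_tags.astype(str)
        res = rbc_membrane.residue_names.astype(str)
        lower = np.unique(rbc_membrane.residue_ids[tags == "lower"])
        lower_pops = np.unique(rbc_membrane.residue_ids[(tags == "lower") & (res == "POPS")])
        assert len(lower_pops) / len(lower) == 0.25

    def test_species_counts_match_largest_remainder_rounding(self, rbc_membrane):
        tags = rbc_membrane.leaflet_tags.astype(str)
        res = rbc_membrane.residue_names.astype(str)
        lower_ids = np.unique(rbc_membrane.residue_ids[tags == "lower"])
        observed = {
            sp: len(np.unique(rbc_membrane.residue_ids[(tags == "lower") & (res == sp)]))
            for sp in ("POPC", "POSM", "POPE", "POPS")
        }
        expected = largest_remainder_counts(
            {"POPC": 0.20, "POSM": 0.10, "POPE": 0.45, "POPS": 0.25}, len(lower_ids)
        )
        assert observed == expected

    def test_single_species_build_is_all_popc_without_cholesterol(self, popc_membrane):
        res = set(popc_membrane.residue_names.astype(str))
        assert "CHOL" not in res
        lipid_res = res - {"W", "ION", "MEL"}
        assert lipid_res == {"POPC"}

    @pytest.mark.parametrize("spec_factory", [popc_spec, rbc_spec,
                                              lambda: rbc_spec(chol_fraction=0.5)])
    def test_solvation_rule_ten_w_beads_per_component(self, spec_factory):
        cfg = build_membrane(spec_factory(), seed=3)
        names = cfg.names.astype(str)
        n_components = len(np.unique(cfg.residue_ids[cfg.leaflet_tags.astype(str) != "none"]))
        assert int((names == "W").sum()) >= 10 * n_components

    def test_system_is_electroneutral(self, rbc_membrane):
        assert total_charge(rbc_membrane) == 0

    def test_every_phospholipid_has_one_po4_bead(self, rbc_membrane):
        res = rbc_membrane.residue_names.astype(str)
        names = rbc_membrane.names.astype(str)
        for rid in np.unique(rbc_membrane.residue_ids[np.isin(res, ("POPC", "POPE", "POPS", "POSM"))]):
            m = rbc_membrane.residue_ids == rid
            assert int((names[m] == "PO4").sum()) == 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            MembraneSpec(upper_composition={"POPC": 0.9},
                         lower_composition={"POPC": 1.0})

    def test_tiny_area_is_infeasible(self):
        with pytest.raises(InfeasibleSpecError):
            build_membrane(rbc_spec(target_area=0.5), seed=0)

    def test_seed_determinism(self):
        a = build_membrane(popc_spec(), seed=11)
        b = build_membrane(popc_spec(), seed=11)
        assert np.array_equal(a.positions, b.positions)
        assert list(a.names) == list(b.names)

    def test_positions_wrapped_into_box(self, rbc_membrane):
        assert np.all(rbc_membrane.positions >= 0)
        assert np.all(rbc_membrane.positions < rbc_membrane.box)


@given(total=st.integers(min_value=0, max_value=500),
       weights=st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=6))
@settings(max_examples=50, deadline=None)
def test_largest_remainder_conserves_total(total, weights):
    s = sum(weights)
    fractions = {f"sp{i}": w / s for i, w in enumerate(weights)}
    counts = largest_remainder_counts(fractions, total)
    assert sum(counts.values()) == total
    for sp, f in fractions.items():
        assert abs(counts[sp] - f * total) < 1.0


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

class TestPeptideModel:
    def test_melittin_net_charge_is_plus_six(self):
        model = make_peptide_model(MEL_SEQUENCE, "helical")
        assert model.net_charge == 6

    def test_polyglycine_carries_only_the_terminal_charge(self):
        assert make_peptide_model("GGGG").net_charge == 1

    def test_balanced_side_chains_sum_to_terminal_charge(self):
        model = make_peptide_model("KRDE")
        assert int(model.per_residue_charge.sum()) == 0
        assert model.net_charge == 1

    def test_kinked_conformation_records_flexible_residues(self):
        model = make_peptide_model(MEL_SEQUENCE, "kinked")
        assert model.flexible_residues == frozenset({1, 11, 26})
        assert make_peptide_model(MEL_SEQUENCE, "helical").flexible_residues == frozenset()

    def test_unknown_residue_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            make_peptide_model("GIBBERISHX1")


class TestPlacePeptides:
    def test_two_by_four_grid_sits_at_offset_above_membrane(self, rbc_membrane):
        model = make_peptide_model(MEL_SEQUENCE)
        placed = place_peptides(rbc_membrane, model, n_peptides=8, offset=2.5)
        mem = placed.leaflet_tags.astype(str) != "none"
        z_com = placed.positions[mem, 2].mean()
        bb = placed.residue_names.astype(str) == "MEL"
        assert bb.sum() == 8 * 26
        assert np.all(np.abs(placed.positions[bb, 2] - (z_com + 2.5)) < 0.3)

    def test_single_peptide_centered_in_xy(self, rbc_membrane):
        model = make_peptide_model(MEL_SEQUENCE)
        placed = place_peptides(rbc_membrane, model, n_peptides=1)
        bb = placed.residue_names.astype(str) == "MEL"
        center = placed.positions[bb, :2].mean(axis=0)
        np.testing.assert_allclose(center, placed.box[:2] / 2.0, atol=0.1)

    def test_four_peptides_nearest_neighbor_spacing(self, rbc_membrane):
        model = make_peptide_model("GIGA")  # short peptide, clean geometry
        placed = place_peptides(rbc_membrane, model, n_peptides=4)
        bb = placed.residue_names.astype(str) == "MEL"
        rids = placed.residue_ids[bb]
        centers = np.array([
            placed.positions[bb & (placed.residue_ids == r), :2].mean(axis=0)
            for r in np.unique(rids)
        ])
        dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        np.testing.assert_allclose(dists.min(axis=1), 5.0, atol=0.01)

    def test_backbones_do_not_overlap(self, rbc_membrane):
        model = make_peptide_model(MEL_SEQUENCE)
        placed = place_peptides(rbc_membrane, model, n_peptides=8)
        bb = placed.residue_names.astype(str) == "MEL"
        rids = np.unique(placed.residue_ids[bb])
        for i, ra in enumerate(rids):
            pa = placed.positions[bb & (placed.residue_ids == ra)]
            for rb in rids[i + 1:]:
                pb = placed.positions[bb & (placed.residue_ids == rb)]
                d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
                assert d.min() > 0.5

    def test_charge_stays_neutral_after_placement(self, rbc_membrane):
        model = make_peptide_model(MEL_SEQUENCE)
        placed = place_peptides(rbc_membrane, model, n_peptides=8)
        assert total_charge(placed, peptide_net_charge=model.net_charge, n_peptides=8) == 0

    def test_oversized_grid_rejected(self, rbc_membrane):
        model = make_peptide_model(MEL_SEQUENCE)
        with pytest.raises(PlacementError):
            place_peptides(rbc_membrane, model, n_peptides=100)


# ---------------------------------------------------------------------------
# pore carving
# ---------------------------------------------------------------------------

class TestCarvePore:
    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7, 0.9, 1.0])
    def test_round_trip_through_compute_xi(self, rbc_membrane, target):
        spec = XiSpec.cg_default(n_slices=22)
        carved = carve_pore(rbc_membrane, target, spec, seed=3)
        assert abs(compute_xi(carved, spec).xi - target) <= 0.05

    def test_full_pore_saturates_every_slice(self, rbc_membrane):
        spec = XiSpec.cg_default(n_slices=22)
        carved = carve_pore(rbc_membrane, 1.0, spec, seed=3)
        occ = compute_xi(carved, spec)
        assert occ.xi == 1.0
        assert np.all(occ.per_slice_counts >= spec.saturation_count)

    def test_flat_membrane_near_target_is_unchanged(self, rbc_membrane):
        spec = XiSpec.cg_default(n_slices=22)
        flat_xi = compute_xi(rbc_membrane, spec).xi
        assume_close = abs(flat_xi - 0.2) <= 0.05
        carved = carve_pore(rbc_membrane, 0.2, spec, seed=3)
        if assume_close:
            assert np.array_equal(carved.positions, rbc_membrane.positions)

    def test_determinism(self, rbc_membrane):
        spec = XiSpec.cg_default(n_slices=22)
        a = carve_pore(rbc_membrane, 0.6, spec, seed=9)
        b = carve_pore(rbc_membrane, 0.6, spec, seed=9)
        assert np.array_equal(a.positions, b.positions)


# ---------------------------------------------------------------------------
# toy dynamics
# ---------------------------------------------------------------------------

class TestToyTrajectory:
    def test_zero_flip_rate_keeps_leaflets_fixed(self, rbc_membrane):
        params = ToyTrajectoryParams(flip_rate=0.0, flip_back_rate=0.0)
        traj = simulate_toy_trajectory(rbc_membrane, params, n_frames=10, seed=4)
        first = traj.frames[0].leaflet_tags
        last = traj.frames[-1].leaflet_tags
        assert list(first) == list(last)

    def test_area_moments_match_parameters(self):
        params = ToyTrajectoryParams(area_mean=100.0, area_variance=1.0)
        areas = sample_area_series(params, 100000, seed=6)
        se_mean = np.sqrt(1.0 / len(areas))
        assert abs(areas.mean() - 100.0) < 3 * se_mean
        se_var = 1.0 * np.sqrt(2.0 / (len(areas) - 1))
        assert abs(areas.var(ddof=1) - 1.0) < 3 * se_var

    def test_bead_identity_shared_across_frames(self, rbc_membrane):
        params = ToyTrajectoryParams()
        traj = simulate_toy_trajectory(rbc_membrane, params, n_frames=4, seed=2)
        for f in traj.frames[1:]:
            assert list(f.names) == list(traj.frames[0].names)
            assert np.array_equal(f.residue_ids, traj.frames[0].residue_ids)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ToyTrajectoryParams(area_variance=-1.0)

    def test_seed_determinism(self, rbc_membrane):
        params = ToyTrajectoryParams()
        a = simulate_toy_trajectory(rbc_membrane, params, n_frames=5, seed=3)
        b = simulate_toy_trajectory(rbc_membrane, params, n_frames=5, seed=3)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.positions, fb.positions)
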