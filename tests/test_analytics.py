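import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xipore.analytics import (
    AnalysisFrameSeries,
    EmptyRegionError,
    PeakDetectionError,
    area_compressibility,
    area_compressibility_from_areas,
    area_per_lipid,
    bilayer_thickness,
    choose_enrichment_radius,
    count_near_pore,
    flip_flop_fraction,
    flip_flop_series,
    lipid_fraction_near_pore,
    metrics_table,
    order_parameter,
    pore_lining_count,
    reference_lining_density,
    smooth_series,
    tilt_angles,
)
from xipore.core import BeadConfiguration
from xipore.membrane import ToyTrajectoryParams, sample_area_series, simulate_toy_trajectory


def make_frame(names, resnames, positions, box=(10.0, 10.0, 10.0), resids=None,
               tags=None):
    n = len(names)
    return BeadConfiguration(
        names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_ids=np.arange(1, n + 1) if resids is None else np.asarray(resids),
        positions=np.asarray(positions, dtype=float),
        box=np.asarray(box, dtype=float),
        leaflet_tags=None if tags is None else np.array(tags, dtype=object),
    )


def bilayer_frame(n_per_leaflet=50, sep=3.9, species="POPS", box=10.0, n_above=0,
                  species_upper=None):
    """Minimal frame with PO4 heads at +-sep/2 about z=5 and C4A/C4B tails.

    ``n_above`` lower-leaflet lipids are flipped above the midplane but
    keep their (lower-leaflet) species label.
    """
    rng = np.random.default_rng(0)
    names, resnames, resids, pos, tags = [], [], [], [], []
    rid = 1
    for leaflet, sign in (("upper", 1), ("lower", -1)):
        sp = species_upper if (leaflet == "upper" and species_upper) else species
        for k in range(n_per_leaflet):
            x, y = rng.uniform(0, box, 2)
            moved_up = leaflet == "lower" and k < n_above
            s = 1 if moved_up else sign
            for bead, dz in (("PO4", sep / 2), ("C4A", 0.3), ("C4B", 0.3)):
                names.append(bead)
                resnames.append(sp)
                resids.append(rid)
                pos.append((x, y, 5.0 + s * dz))
                tags.append("upper" if s == 1 else "lower")
            rid += 1
    return make_frame(names, resnames, pos, box=(box, box, 10.0), resids=resids,
                      tags=tags)


class TestFlipFlopFraction:
    def test_all_heads_below_midplane_gives_zero(self):
        frame = bilayer_frame(n_above=0, species_upper="POPC")
        assert flip_flop_fraction(frame, "POPS") == 0.0

    def test_thirty_of_hundred_above_gives_point_three(self):
        # 30 of 100 lower-leaflet POPS moved above the midplane
        frame = bilayer_frame(n_per_leaflet=100, n_above=30, species_upper="POPC")
        assert flip_flop_fraction(frame, "POPS") == pytest.approx(30 / 100)

    def test_invariant_under_rigid_z_translation(self):
        frame = bilayer_frame(n_per_leaflet=40, n_above=7)
        shifted = frame.with_positions(frame.positions + np.array([0.0, 0.0, 1.3]))
        shifted.box[2] = 20.0
        assert flip_flop_fraction(shifted, "POPS") == pytest.approx(
            flip_flop_fraction(frame, "POPS"))

    def test_absent_species_rejected(self):
        frame = bilayer_frame()
        with pytest.raises(ValueError):
            flip_flop_fraction(frame, "DOPC")

    def test_toy_trajectory_matches_generator_tags(self, rbc_membrane):
        params = ToyTrajectoryParams(flip_rate=0.05, flip_back_rate=0.05)
        traj = simulate_toy_trajectory(rbc_membrane, params, n_frames=30, seed=9)
        for frame in traj.frames[::10]:
            res = frame.residue_names.astype(str)
            tags = frame.leaflet_tags.astype(str)
            pops_ids = np.unique(frame.residue_ids[res == "POPS"])
            upper_ids = np.unique(frame.residue_ids[(res == "POPS") & (tags == "upper")])
            expected = len(upper_ids) / len(pops_ids)
            assert flip_flop_fraction(frame, "POPS") == pytest.approx(expected, abs=0.05)


class TestCountNearPore:
    def test_constructed_counts(self):
        pos = [(5 + 1.5, 5, 3)] * 5 + [(5 + 3.5, 5, 3)] * 4
        frame = make_frame(["PO4"] * 9, ["POPS"] * 9, pos)
        assert count_near_pore(frame, "POPS", 2.0) == 5

    def test_boundary_bead_is_counted(self):
        frame = make_frame(["PO4"], ["POPS"], [(7.0, 5.0, 5.0)])
        assert count_near_pore(frame, "POPS", 2.0) == 1

    def test_periodic_minimum_image(self):
        frame = make_frame(["PO4"], ["POPS"], [(9.8, 5.0, 5.0)], box=(10, 10, 10))
        # pore center at (5,5): direct distance 4.8, wrapped is still 4.8 in x;
        # place center at (0.5, 5) instead to exercise wrapping
        assert count_near_pore(frame, "POPS", 2.0, pore_center_xy=np.array([0.5, 5.0])) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        pos = rng.uniform(0, 10, size=(n, 3))
        frame = make_frame(["PO4"] * n, ["POPS"] * n, pos)
        r = 2.0
        center = np.array([5.0, 5.0])
        expected = 0
        for p in pos:
            dx = p[0] - center[0] - round((p[0] - center[0]) / 10) * 10
            dy = p[1] - center[1] - round((p[1] - center[1]) / 10) * 10
            if dx * dx + dy * dy <= r * r:
                expected += 1
        assert count_near_pore(frame, "POPS", r) == expected


class TestSmoothSeries:
    def test_constant_series_unchanged(self):
        out = smooth_series(np.full(20, 3.3), window=10)
        np.testing.assert_allclose(out, 3.3)

    def test_window_one_is_identity(self):
        v = np.arange(7.0)
        np.testing.assert_allclose(smooth_series(v, window=1), v)

    def test_ramp_matches_hand_computed_shrinking_windows(self):
        v = np.arange(10.0)
        out = smooth_series(v, window=10)
        # centered window: 4 left, 5 right neighbors, clipped at edges
        expected = [np.mean(v[max(0, i - 4):min(10, i + 6)]) for i in range(10)]
        np.testing.assert_allclose(out, expected)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50),
           st.integers(min_value=1, max_value=12))
    @settings(max_examples=60, deadline=None)
    def test_output_within_input_range_and_same_length(self, values, window):
        out = smooth_series(values, window)
        assert len(out) == len(values)
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9


class TestPoreLining:
    def make_peptide_frame(self, tilts_deg, z_center=5.0):
        """Peptides as 26-bead rods at given tilt angles through the midplane."""
        names, resnames, resids, pos = [], [], [], []
        rid = 1
        for tilt in tilts_deg:
            t = np.radians(tilt)
            for i in range(26):
                s = (i - 12.5) * 0.15
                names.append(f"BB{i + 1}")
                resnames.append("MEL")
                resids.append(rid)
                pos.append((3.0 + rid + s * np.cos(t), 5.0, z_center + s * np.sin(t)))
            rid += 1
        # midplane markers
        for bead in ("C4A", "C4B"):
            names.append(bead)
            resnames.append("POPC")
            resids.append(rid)
            pos.append((1.0, 1.0, z_center))
        return make_frame(names, resnames, pos, box=(20, 20, 10), resids=resids)

    def test_no_backbone_in_window_gives_zero(self):
        frame = self.make_peptide_frame([])
        assert pore_lining_count(frame, reference_density=6.0).value == 0.0

    def test_three_inserted_peptides_count_as_three(self):
        ref = reference_lining_density()
        frame = self.make_peptide_frame([90, 90, 90])
        result = pore_lining_count(frame, reference_density=ref)
        assert result.value == pytest.approx(3.0)
        assert result.rounded == 3

    def test_adsorbed_peptides_do_not_count(self):
        frame = self.make_peptide_frame([0.0], z_center=5.0)
        # move the flat peptide 2 nm above the midplane
        bb = frame.residue_names.astype(str) == "MEL"
        frame.positions[bb, 2] += 2.0
        assert pore_lining_count(frame, reference_density=6.0).value == 0.0

    def test_reference_density_counts_central_residues(self):
        # 26 residues at 0.15 nm rise: indices within +-0.5 nm of the middle
        assert reference_lining_density() == 6.0

    def test_tilt_angles_trivial_orientations(self):
        frame = self.make_peptide_frame([90, 0, 45])
        records = tilt_angles(frame)
        angles = sorted(r.angle for r in records)
        assert angles[0] == pytest.approx(0.0, abs=1e-6)
        assert angles[1] == pytest.approx(45.0, abs=1e-6)
        assert angles[2] == pytest.approx(90.0, abs=1e-6)

    def test_pore_lining_flag_set_for_transmembrane_peptide(self):
        frame = self.make_peptide_frame([90, 0])
        records = {round(r.angle): r.pore_lining for r in tilt_angles(frame)}
        assert records[90] is True
        assert records[0] is True  # flat at the midplane still contributes beads
        # a flat peptide far above does not
        frame2 = self.make_peptide_frame([0])
        bb = frame2.residue_names.astype(str) == "MEL"
        frame2.positions[bb, 2] += 2.0
        assert tilt_angles(frame2)[0].pore_lining is False


class TestAreaPerLipid:
    def test_static_box_arithmetic(self):
        frames = []
        for _ in range(3):
            names, resnames, resids, tags, pos = [], [], [], [], []
            for r in range(125):
                names.append("PO4")
                resnames.append("POPC")
                resids.append(r + 1)
                tags.append("upper")
                pos.append((r % 10, r // 10, 7.0))
            frames.append(make_frame(names, resnames, pos, resids=resids, tags=tags))
        series = AnalysisFrameSeries(frames=frames, times=np.arange(3.0))
        assert area_per_lipid(series) == pytest.approx(100.0 / 125)

    def test_cholesterol_counts_toward_upper_leaflet(self, rbc_membrane):
        from xipore import build_membrane, rbc_spec

        chol = build_membrane(rbc_spec(chol_fraction=0.5), seed=2)
        series = AnalysisFrameSeries(frames=[chol], times=[0.0])
        tags = chol.leaflet_tags.astype(str)
        res = chol.residue_names.astype(str)
        n_upper = len(np.unique(chol.residue_ids[tags == "upper"]))
        n_upper_chol = len(np.unique(chol.residue_ids[(tags == "upper") & (res == "CHOL")]))
        assert n_upper_chol > 0
        assert area_per_lipid(series) == pytest.approx(100.0 / n_upper, rel=1e-6)


class TestBilayerThickness:
    def test_delta_layers_recovered_within_a_bin(self):
        pos = [(x, y, 1.0) for x in range(3) for y in range(3)]
        pos += [(x, y, 5.0) for x in range(3) for y in range(3)]
        frame = make_frame(["PO4"] * 18, ["POPC"] * 18, pos, box=(10, 10, 10))
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        assert bilayer_thickness(series) == pytest.approx(4.0, abs=0.05)

    def test_translation_invariance(self):
        pos = [(x, y, 2.0) for x in range(3) for y in range(3)]
        pos += [(x, y, 6.0) for x in range(3) for y in range(3)]
        frame = make_frame(["PO4"] * 18, ["POPC"] * 18, pos, box=(10, 10, 12))
        shifted = frame.with_positions(frame.positions + np.array([0, 0, 1.5]))
        a = bilayer_thickness(AnalysisFrameSeries(frames=[frame], times=[0.0]))
        b = bilayer_thickness(AnalysisFrameSeries(frames=[shifted], times=[0.0]))
        assert a == pytest.approx(b, abs=0.061)  # one bin width of play

    def test_generator_head_separation_recovered(self, rbc_membrane):
        params = ToyTrajectoryParams()
        traj = simulate_toy_trajectory(rbc_membrane, params, n_frames=60, seed=3)
        series = AnalysisFrameSeries.from_trajectory(traj)
        assert bilayer_thickness(series) == pytest.approx(3.9, abs=0.15)

    def test_unimodal_profile_rejected(self):
        pos = [(x, y, 5.0) for x in range(4) for y in range(4)]
        frame = make_frame(["PO4"] * 16, ["POPC"] * 16, pos)
        with pytest.raises(PeakDetectionError):
            bilayer_thickness(AnalysisFrameSeries(frames=[frame], times=[0.0]))


class TestAreaCompressibility:
    def test_known_variance_inverts_to_known_modulus(self):
        params = ToyTrajectoryParams(area_mean=100.0, area_variance=2.0)
        areas = sample_area_series(params, 100000, seed=8)
        ka = area_compressibility_from_areas(areas, temperature=310.0)
        expected = 1.380649e-2 * 310.0 * 100.0 / 2.0  # = 214.0 mN/m
        assert ka == pytest.approx(expected, rel=0.05)

    def test_doubling_variance_halves_modulus(self):
        rng = np.random.default_rng(3)
        base = 100.0 + rng.normal(0, 1.0, size=50000)
        # scale fluctuations about the sample mean so only the variance changes
        double = base.mean() + (base - base.mean()) * np.sqrt(2.0)
        ka1 = area_compressibility_from_areas(base)
        ka2 = area_compressibility_from_areas(double)
        assert ka2 == pytest.approx(ka1 / 2.0, rel=1e-6)

    def test_independent_seeds_agree_within_noise(self):
        params = ToyTrajectoryParams()
        ka = [
            area_compressibility_from_areas(sample_area_series(params, 20000, seed=s))
            for s in (1, 2)
        ]
        # var estimate rel-SE ~ sqrt(2/n); 3-sigma band on the ratio
        assert abs(ka[0] / ka[1] - 1.0) < 3 * 2 * np.sqrt(2.0 / 20000)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            area_compressibility_from_areas(np.full(200, 100.0))


class TestLipidFractions:
    def test_single_species_is_unity(self):
        frame = bilayer_frame(species="POPC")
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        fractions = lipid_fraction_near_pore(series, radius=5.0)
        assert fractions == {"POPC": 1.0}

    def test_constructed_three_to_one_split(self):
        pos = [(5.2, 5.0, 3.0), (4.8, 5.0, 3.0), (5.0, 5.2, 3.0), (5.0, 4.8, 3.0)]
        frame = make_frame(["PO4"] * 4, ["POPS", "POPS", "POPS", "POPC"], pos)
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        fractions = lipid_fraction_near_pore(series, radius=1.0)
        assert fractions["POPS"] == pytest.approx(0.75)
        assert fractions["POPC"] == pytest.approx(0.25)

    def test_fractions_sum_to_one_on_random_frames(self, rbc_membrane):
        series = AnalysisFrameSeries(frames=[rbc_membrane], times=[0.0])
        fractions = lipid_fraction_near_pore(series, radius=2.5)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_region_rejected(self):
        frame = make_frame(["PO4"], ["POPS"], [(0.2, 0.2, 5.0)], box=(20, 20, 10))
        series = AnalysisFrameSeries(frames=[frame], times=[0.0],
                                     pore_center_xy=np.array([10.0, 10.0]))
        with pytest.raises(EmptyRegionError):
            lipid_fraction_near_pore(series, radius=0.5)


class TestEnrichmentRadius:
    def test_uniform_density_matches_closed_form(self):
        rng = np.random.default_rng(4)
        n = 400
        box = 20.0
        pos = np.column_stack([rng.uniform(0, box, n), rng.uniform(0, box, n),
                               np.full(n, 5.0)])
        frame = make_frame(["PO4"] * n, ["POPC"] * n, pos, box=(box, box, 10))
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        target = 30
        r = choose_enrichment_radius(series, target_count=target)
        rho = n / box**2
        r_expected = np.sqrt(target / (np.pi * rho))
        assert abs(r - r_expected) <= 0.3

    def test_target_one_with_central_lipid(self):
        frame = make_frame(["PO4"], ["POPC"], [(5.0, 5.0, 5.0)])
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        assert choose_enrichment_radius(series, target_count=1) == pytest.approx(0.1)

    def test_radius_monotone_in_target(self, rbc_membrane):
        series = AnalysisFrameSeries(frames=[rbc_membrane], times=[0.0])
        radii = [choose_enrichment_radius(series, target_count=t) for t in (5, 15, 30)]
        assert radii == sorted(radii)

    def test_unreachable_target_raises(self):
        frame = make_frame(["PO4"], ["POPC"], [(5.0, 5.0, 5.0)])
        series = AnalysisFrameSeries(frames=[frame], times=[0.0])
        with pytest.raises(ValueError, match="not reachable"):
            choose_enrichment_radius(series, target_count=50)


class TestOrderParameter:
    def test_vectors_along_z_give_one(self):
        pos = [(5, 5, 1), (5, 5, 2), (6, 6, 3), (6, 6, 4)]
        frame = make_frame(["C1", "C2", "C1", "C2"], ["X"] * 4, pos)
        s = order_parameter(frame, [[(0, 1), (2, 3)]])
        assert s[0] == pytest.approx(1.0)

    def test_in_plane_vectors_give_minus_half(self):
        pos = [(5, 5, 1), (6, 5, 1), (3, 3, 2), (3, 4, 2)]
        frame = make_frame(["C1", "C2", "C1", "C2"], ["X"] * 4, pos)
        s = order_parameter(frame, [[(0, 1), (2, 3)]])
        assert s[0] == pytest.approx(-0.5)

    def test_isotropic_vectors_average_to_zero(self):
        rng = np.random.default_rng(5)
        n = 100000
        v = rng.normal(size=(n, 3))
        origin = np.zeros((n, 3))
        pos = np.vstack([origin, origin + v])
        frame = make_frame(["A"] * n + ["B"] * n, ["X"] * (2 * n), pos % 10.0)
        # pair i with i+n; positions were wrapped, so rebuild vectors directly
        frame.positions[:n] = 0.0
        frame.positions[n:] = v
        s = order_parameter(frame, [[(i, i + n) for i in range(n)]])
        se = 1.0 / np.sqrt(n)  # variance of (3cos^2-1)/2 is 1/5; 3 sigma with margin
        assert abs(s[0]) < 3 * se

    def test_zero_length_vector_rejected(self):
        pos = [(5, 5, 5), (5, 5, 5)]
        frame = make_frame(["A", "B"], ["X", "X"], pos)
        with pytest.raises(ValueError, match="zero-length"):
            order_parameter(frame, [[(0, 1)]])


def test_metrics_table_columns(rbc_membrane):
    series = AnalysisFrameSeries(frames=[rbc_membrane], times=[0.0])
    table = metrics_table(series)
    assert list(table.columns) == ["time_ns", "flip_flop_fraction",
                                   "near_pore_count", "area_nm2"]
    assert len(table) == 1
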