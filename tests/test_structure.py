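import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvmech import structure, synthetic
from hvmech.model import BeadFrame, BeadTopology, MoleculeKind, Trajectory
from hvmech.structure import DensityProfile, MembraneMap
from tests.conftest import make_trajectory


def bulk_topology(n, kind=MoleculeKind.LIPID, name="C1"):
    masses = np.full(n, 72.0)
    return BeadTopology(
        bead_names=np.array([name] * n, dtype=object),
        molecule_ids=np.arange(n),
        molecule_kinds=np.array([kind] * n, dtype=object),
        masses=masses,
        weights=masses.copy(),
    )


class TestThickness:
    def test_arithmetic_on_constructed_box(self):
        topo = bulk_topology(6000, kind=MoleculeKind.WATER, name="W")
        frame = BeadFrame(np.zeros((6000, 3)) + 5.0, box=[10, 10, 10])
        res = structure.membrane_thickness(frame, topo, water_bead_volume=0.1)
        assert res.h == pytest.approx(4.0)
        assert res.v_water == pytest.approx(600.0)

    def test_no_water_gives_box_height(self):
        topo = bulk_topology(10)
        frame = BeadFrame(np.zeros((10, 3)) + 1.0, box=[5, 5, 7])
        assert structure.membrane_thickness(frame, topo).h == pytest.approx(7.0)

    def test_water_filling_box_raises(self):
        topo = bulk_topology(100, kind=MoleculeKind.WATER, name="W")
        frame = BeadFrame(np.zeros((100, 3)) + 0.5, box=[1, 1, 1])
        with pytest.raises(ValueError, match="non-positive"):
            structure.membrane_thickness(frame, topo, water_bead_volume=0.1)

    def test_generator_bimodal_mean(self, bimodal_bilayer):
        topo, frame, truth = bimodal_bilayer
        res = structure.membrane_thickness(frame, topo, water_bead_volume=0.12)
        assert res.h == pytest.approx(5.5, abs=0.01)


class TestAreaPerMolecule:
    def test_paper_scale_value(self):
        frame = BeadFrame(np.zeros((1, 3)) + 1, box=[12.54, 12.54, 10.0])
        apm = structure.area_per_molecule(frame, 250)
        assert apm == pytest.approx(0.629, abs=0.001)
        assert 0.627 <= apm <= 0.681  # experimental POPC range

    def test_single_molecule(self):
        frame = BeadFrame(np.zeros((1, 3)) + 1, box=[10, 10, 5])
        assert structure.area_per_molecule(frame, 1) == pytest.approx(100.0)

    def test_quadratic_box_scaling(self):
        f1 = BeadFrame(np.zeros((1, 3)) + 1, box=[10, 10, 5])
        f2 = BeadFrame(np.zeros((1, 3)) + 1, box=[20, 20, 5])
        assert structure.area_per_molecule(f2, 7) == pytest.approx(
            4 * structure.area_per_molecule(f1, 7)
        )

    def test_zero_count_raises(self):
        frame = BeadFrame(np.zeros((1, 3)) + 1, box=[10, 10, 5])
        with pytest.raises(ValueError):
            structure.area_per_molecule(frame, 0)


class TestDensityProfile:
    def test_uniform_gas_is_flat(self):
        rng = np.random.default_rng(50)
        n = 100_000
        topo = bulk_topology(n)
        coords = rng.uniform(0, 10, (n, 3))
        traj = Trajectory([BeadFrame(coords, [10, 10, 10])])
        prof = structure.density_profile(traj, topo, n_slices=20)
        mean = np.mean(prof.values)
        assert np.max(np.abs(prof.values - mean)) / mean < 0.05

    def test_point_mass_occupies_single_slice(self):
        topo = bulk_topology(100)
        coords = np.zeros((100, 3)) + 5.0
        traj = Trajectory([BeadFrame(coords, [10, 10, 10])])
        prof = structure.density_profile(traj, topo, n_slices=200)
        assert np.count_nonzero(prof.values) == 1

    def test_conservation_of_total_weight(self, bimodal_bilayer):
        topo, frame, truth = bimodal_bilayer
        prof = structure.density_profile(Trajectory([frame]), topo, n_slices=200)
        assert prof.total_weight == pytest.approx(float(np.sum(topo.masses)), rel=1e-12)

    def test_symmetric_bilayer_profile_is_even(self, bimodal_bilayer):
        topo, frame, truth = bimodal_bilayer
        prof = structure.density_profile(Trajectory([frame]), topo, n_slices=40)
        asym = np.max(np.abs(prof.values - prof.values[::-1])) / np.max(prof.values)
        assert asym < 0.02  # waters mirrored, membrane symmetric by construction

    def test_component_filter_selects_subset(self, flat_bilayer):
        topo, frame, truth = flat_bilayer
        prof = structure.density_profile(
            Trajectory([frame]), topo, component_filter=[MoleculeKind.WATER], n_slices=50
        )
        n_water = np.sum(topo.kind_mask(MoleculeKind.WATER))
        assert prof.total_weight == pytest.approx(72.0 * n_water, rel=1e-12)

    def test_empty_selection_raises(self, flat_bilayer):
        topo, frame, truth = flat_bilayer
        with pytest.raises(ValueError, match="no beads"):
            structure.density_profile(
                Trajectory([frame]), topo, component_filter=[MoleculeKind.PEPTIDE]
            )


def two_gaussian_profile(peak_z, z_lo, z_hi, sigma=0.3, step=0.01):
    z = np.arange(z_lo, z_hi + step / 2, step)
    v = np.exp(-((z - peak_z) ** 2) / (2 * sigma**2)) + np.exp(
        -((z + peak_z) ** 2) / (2 * sigma**2)
    )
    return DensityProfile(z, v, len(z), "mass", 1.0)


class TestPeakToPeak:
    def test_lipid_scale_separation(self):
        # peaks at +-1.845 nm: the 36.9 A head-to-head distance scale
        prof = two_gaussian_profile(1.845, -4.995, 4.995)
        assert structure.peak_to_peak(prof) == pytest.approx(3.69, abs=1e-9)

    def test_polymersome_scale_separation(self):
        prof = two_gaussian_profile(5.3, -8.0, 8.0)
        assert structure.peak_to_peak(prof) == pytest.approx(10.6, abs=1e-9)

    def test_unimodal_profile_raises(self):
        z = np.arange(-5, 5, 0.01)
        v = np.exp(-(z**2) / 0.5)
        prof = DensityProfile(z, v, len(z), "mass", 1.0)
        with pytest.raises(ValueError, match="unimodal|maxima"):
            structure.peak_to_peak(prof)


class TestOrderParameter:
    def _traj_with_bonds(self, vecs, box=20.0):
        vecs = np.asarray(vecs, dtype=float)
        n = len(vecs)
        coords = np.zeros((1, 2 * n, 3)) + box / 2
        coords[0, 1::2] = coords[0, 0::2] + vecs
        bonds = np.column_stack([np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)])
        return make_trajectory(coords, box=(box, box, box)), bonds

    def test_bonds_along_z_give_one(self):
        traj, bonds = self._traj_with_bonds([[0, 0, 0.47]] * 10)
        assert structure.order_parameter(traj, bonds).mean_s == pytest.approx(1.0)

    def test_bonds_in_plane_give_minus_half(self):
        traj, bonds = self._traj_with_bonds([[0.47, 0, 0], [0, 0.47, 0]] * 5)
        assert structure.order_parameter(traj, bonds).mean_s == pytest.approx(-0.5)

    def test_isotropic_bonds_give_zero(self):
        rng = np.random.default_rng(60)
        v = rng.normal(size=(100_000, 3))
        v = 0.3 * v / np.linalg.norm(v, axis=1, keepdims=True)
        traj, bonds = self._traj_with_bonds(v, box=100.0)
        assert abs(structure.order_parameter(traj, bonds).mean_s) < 0.01

    def test_invariant_under_rotation_about_z(self):
        rng = np.random.default_rng(61)
        v = 0.4 * rng.normal(size=(200, 3))
        traj, bonds = self._traj_with_bonds(v)
        s0 = structure.order_parameter(traj, bonds).mean_s
        phi = 1.1
        rot = np.array(
            [[np.cos(phi), -np.sin(phi), 0], [np.sin(phi), np.cos(phi), 0], [0, 0, 1]]
        )
        traj2, bonds2 = self._traj_with_bonds(v @ rot.T)
        assert structure.order_parameter(traj2, bonds2).mean_s == pytest.approx(s0)

    def test_zero_length_bonds_excluded_with_warning(self):
        traj, bonds = self._traj_with_bonds([[0, 0, 0.47], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero-length"):
            res = structure.order_parameter(traj, bonds)
        assert res.mean_s == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_hold_for_arbitrary_directions(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(20, 3)) * 0.3
        v[np.linalg.norm(v, axis=1) < 1e-6] = [0, 0, 0.1]
        traj, bonds = self._traj_with_bonds(v)
        res = structure.order_parameter(traj, bonds)
        assert np.all(res.per_bond_s >= -0.5 - 1e-12)
        assert np.all(res.per_bond_s <= 1.0 + 1e-12)
        assert -0.5 <= res.mean_s <= 1.0


class TestThicknessMap:
    def test_bimodal_map_reproduces_construction(self, bimodal_bilayer):
        topo, frame, truth = bimodal_bilayer
        mmap = structure.thickness_map(
            frame, topo, ["PO4", "EO1"], grid_edge=0.8
        )
        assert np.allclose(np.sort(np.unique(np.round(mmap.values, 6))), [4.0, 7.0])
        assert structure.thin_fraction(mmap, 5.0) == pytest.approx(0.5)

    def test_flat_map_is_constant(self, flat_bilayer):
        topo, frame, truth = flat_bilayer
        mmap = structure.thickness_map(frame, topo, ["PO4", "EO1"], grid_edge=0.8)
        assert np.allclose(mmap.values, 4.0)
        assert structure.thin_fraction(mmap, 5.0) == 1.0

    def test_map_mean_matches_global_thickness(self, bimodal_bilayer):
        topo, frame, truth = bimodal_bilayer
        mmap = structure.thickness_map(frame, topo, ["PO4", "EO1"], grid_edge=0.8)
        assert np.mean(mmap.values) == pytest.approx(truth.expected_mean_thickness, abs=0.05)


class TestMapFill:
    def grid_map(self, values):
        return MembraneMap(np.asarray(values, dtype=float), 0.5, "thickness")

    def test_constant_field_fill(self):
        v = np.full((3, 3), 4.0)
        v[1, 1] = np.nan
        filled = structure.map_smooth_fill(self.grid_map(v))
        assert filled.values[1, 1] == pytest.approx(4.0)
        assert filled.fill_mask[1, 1] and filled.fill_mask.sum() == 1

    def test_equidistant_neighbors_average(self):
        v = np.full((1, 3), np.nan)
        v[0, 0], v[0, 2] = 4.0, 6.0
        filled = structure.map_smooth_fill(self.grid_map(v))
        assert filled.values[0, 1] == pytest.approx(5.0)

    def test_linear_field_recovered_within_two_percent(self):
        # isolated interior gaps: each empty cell keeps its full symmetric
        # neighborhood, where kernel regression on a linear field is unbiased
        nx = ny = 12
        x = (np.arange(nx) + 0.5) * 0.5
        field = np.tile(x[:, None], (1, ny)) + 2.0
        holes = np.zeros((nx, ny), dtype=bool)
        for i, j in [(2, 2), (2, 7), (5, 4), (7, 9), (9, 2), (4, 9), (8, 6)]:
            holes[i, j] = True
        v = field.copy()
        v[holes] = np.nan
        filled = structure.map_smooth_fill(
            MembraneMap(v, 0.5, "thickness"), bandwidth=0.5
        )
        rel = np.abs(filled.values - field) / field
        assert np.max(rel[holes]) < 0.02

    def test_partially_empty_map_values_within_neighbor_hull(self, flat_bilayer):
        topo, frame, truth = flat_bilayer
        mmap = structure.thickness_map(frame, topo, ["PO4", "EO1"], grid_edge=0.8)
        v = mmap.values.copy()
        rng = np.random.default_rng(71)
        holes = rng.random(v.shape) < 0.3
        v[holes] = np.nan
        filled = structure.map_smooth_fill(MembraneMap(v, 0.8, "thickness"))
        assert not np.isnan(filled.values).any()
        lo, hi = np.nanmin(v), np.nanmax(v)
        assert np.all(filled.values[holes] >= lo - 1e-9)
        assert np.all(filled.values[holes] <= hi + 1e-9)

    def test_all_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            structure.map_smooth_fill(self.grid_map(np.full((2, 2), np.nan)))


class TestThinFraction:
    def test_constructed_half_and_half(self):
        v = np.concatenate([np.full(50, 4.0), np.full(50, 7.0)]).reshape(10, 10)
        mmap = MembraneMap(v, 0.5, "thickness", np.zeros((10, 10), bool))
        assert structure.thin_fraction(mmap, 5.0) == pytest.approx(0.5)

    def test_uniform_thin_map(self):
        mmap = MembraneMap(np.full((5, 5), 4.0), 0.5, "thickness")
        assert structure.thin_fraction(mmap, 5.0) == 1.0

    def test_twenty_percent_layout(self):
        rng = np.random.default_rng(72)
        v = np.full(400, 7.0)
        v[rng.permutation(400)[:80]] = 4.0
        mmap = MembraneMap(v.reshape(20, 20), 0.5, "thickness")
        assert structure.thin_fraction(mmap, 5.0) == pytest.approx(0.20)

    def test_non_thickness_map_rejected(self):
        mmap = MembraneMap(np.ones((3, 3)), 0.5, "density")
        with pytest.raises(ValueError, match="thickness"):
            structure.thin_fraction(mmap)

    def test_map_with_holes_rejected(self):
        v = np.ones((3, 3))
        v[0, 0] = np.nan
        with pytest.raises(ValueError, match="empty"):
            structure.thin_fraction(MembraneMap(v, 0.5, "thickness"))
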