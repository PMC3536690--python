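import math

import numpy as np
import pytest

from comfa3d import field_engine as fe
from comfa3d.params import COULOMB_CONSTANT, VDW_PARAMS


PROBE = fe.ProbeSpec()
C_RADIUS, C_EPS = VDW_PARAMS["C"]


def oracle_steric(point, mol, probe, cutoff=30.0):
    """Brute-force per-atom Lennard-Jones sum, independent of the engine."""
    total = 0.0
    for pos, radius, eps in zip(mol.coords, mol.vdw_radius, mol.well_depth):
        r = math.dist(point, pos)
        r = max(r, 1e-12)
        rij = radius + probe.radius
        eij = math.sqrt(eps * probe.well_depth)
        total += eij * ((rij / r) ** 12 - 2.0 * (rij / r) ** 6)
    return min(total, cutoff)


def oracle_electrostatic(point, mol, probe, cutoff=30.0):
    total = 0.0
    for pos, q in zip(mol.coords, mol.charges):
        r = max(math.dist(point, pos), 1e-12)
        total += COULOMB_CONSTANT * q * probe.charge / r**2
    return min(max(total, -cutoff), cutoff)


class TestBuildGrid:
    def test_single_atom_default_margins(self, point_molecule_factory):
        grid = fe.build_grid([point_molecule_factory([[0, 0, 0]])], spacing=2.0, margin=4.0)
        assert grid.counts == (5, 5, 5)
        assert grid.n_points == 125
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_zero_margin_degenerate_box(self, point_molecule_factory):
        grid = fe.build_grid([point_molecule_factory([[1, 1, 1]])], spacing=2.0, margin=0.0)
        assert grid.counts == (1, 1, 1)

    def test_two_atom_x_extension(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0], [2, 0, 0]])
        grid = fe.build_grid([mol], spacing=2.0, margin=4.0)
        assert grid.counts == (6, 5, 5)

    def test_empty_set_rejected(self):
        with pytest.raises(fe.FieldEngineError):
            fe.build_grid([])

    def test_points_raster_order_k_fastest(self, point_molecule_factory):
        grid = fe.GridSpec(origin=(0, 0, 0), spacing=1.0, counts=(2, 2, 2))
        pts = grid.points()
        assert np.allclose(pts[0], [0, 0, 0])
        assert np.allclose(pts[1], [0, 0, 1])  # k fastest
        assert np.allclose(pts[2], [0, 1, 0])
        assert np.allclose(pts[4], [1, 0, 0])


class TestStericEnergy:
    def test_asymptotic_zero(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]])
        assert abs(fe.steric_energy_at([50.0, 0, 0], mol, PROBE)) < 1e-6

    def test_minimum_at_contact_distance(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]])
        rij = C_RADIUS + PROBE.radius
        eij = math.sqrt(C_EPS * PROBE.well_depth)
        assert fe.steric_energy_at([rij, 0, 0], mol, PROBE) == pytest.approx(-eij, rel=1e-12)

    def test_coincident_probe_truncated(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]])
        assert fe.steric_energy_at([0.0, 0, 0], mol, PROBE) == 30.0

    def test_monotone_increase_inside_contact(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]])
        rij = C_RADIUS + PROBE.radius
        radii = np.linspace(rij, 0.3, 40)
        energies = [fe.steric_energy_at([r, 0, 0], mol, PROBE) for r in radii]
        assert all(b >= a - 1e-12 for a, b in zip(energies, energies[1:]))


class TestElectrostaticEnergy:
    def test_zero_charges(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]], charges=[0.0])
        assert fe.electrostatic_energy_at([1.0, 0, 0], mol, PROBE) == 0.0

    def test_closed_form_value(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]], charges=[0.25])
        e = fe.electrostatic_energy_at([2.0, 0, 0], mol, PROBE)
        assert e == pytest.approx(332.0 * 0.25 / 4.0, rel=1e-12)
        assert e == pytest.approx(20.75, rel=1e-12)

    def test_clipped_at_cutoff(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]], charges=[1.0])
        assert fe.electrostatic_energy_at([1.0, 0, 0], mol, PROBE) == 30.0

    def test_missing_charges_rejected(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]])
        with pytest.raises(fe.FieldEngineError):
            fe.electrostatic_energy_at([1.0, 0, 0], mol, PROBE)


class TestComputeFieldTable:
    def test_shape_contract(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]], charges=[0.1])
        grid = fe.build_grid([mol], spacing=2.0, margin=4.0)
        table = fe.compute_field_table([mol], grid, PROBE)
        assert table.data.shape == (1, 250)

    def test_duplicate_molecules_identical_rows(self, point_molecule_factory):
        a = point_molecule_factory([[0, 0, 0], [1.5, 0, 0]], charges=[0.2, -0.2], compound_id="a")
        b = point_molecule_factory([[0, 0, 0], [1.5, 0, 0]], charges=[0.2, -0.2], compound_id="b")
        grid = fe.build_grid([a, b], spacing=2.0, margin=4.0)
        table = fe.compute_field_table([a, b], grid, PROBE)
        assert np.array_equal(table.data[0], table.data[1])

    @pytest.mark.parametrize("excluded", ["raw", "mean"])
    def test_matches_bruteforce_oracle(self, point_molecule_factory, excluded):
        mol = point_molecule_factory(
            [[0.3, -0.2, 0.1], [1.4, 0.8, -0.6]],
            charges=[0.31, -0.12],
            elements=["N", "C"],
            compound_id="toy",
        )
        grid = fe.build_grid([mol], spacing=2.0, margin=4.0)
        table = fe.compute_field_table([mol], grid, PROBE, excluded_electrostatic=excluded)
        pts = grid.points()
        p = grid.n_points
        for j, point in enumerate(pts):
            s = oracle_steric(point, mol, PROBE)
            assert table.data[0, j] == pytest.approx(s, rel=1e-10, abs=1e-10)
            if excluded == "raw":
                e = oracle_electrostatic(point, mol, PROBE)
                assert table.data[0, p + j] == pytest.approx(e, rel=1e-10, abs=1e-10)

    def test_excluded_point_electrostatic_column_mean(self, point_molecule_factory):
        # molecule b sits on a lattice point -> steric truncation there;
        # its electrostatic entry must become the mean over non-excluded rows
        a = point_molecule_factory([[2.0, 0, 0]], charges=[0.05], compound_id="a")
        b = point_molecule_factory([[0.0, 0, 0]], charges=[0.40], compound_id="b")
        grid = fe.GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, counts=(3, 3, 3))
        table = fe.compute_field_table([a, b], grid, PROBE, excluded_electrostatic="mean")
        pts = grid.points()
        j = int(np.argmin(np.linalg.norm(pts, axis=1)))  # the origin point
        p = grid.n_points
        assert table.data[1, j] == 30.0  # b truncated at its own position
        assert table.data[0, j] < 30.0
        expected = oracle_electrostatic(pts[j], a, PROBE)
        assert table.data[1, p + j] == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self, point_molecule_factory):
        mol = point_molecule_factory([[0.2, 0.4, -0.3]], charges=[0.2])
        grid = fe.build_grid([mol], spacing=2.0, margin=4.0)
        table = fe.compute_field_table([mol], grid, PROBE)
        shift = np.array([3.7, -1.2, 0.5])
        mol2 = mol.with_coords(mol.coords + shift)
        grid2 = fe.GridSpec(
            origin=tuple(np.asarray(grid.origin) + shift),
            spacing=grid.spacing,
            counts=grid.counts,
        )
        table2 = fe.compute_field_table([mol2], grid2, PROBE)
        assert np.abs(table.data - table2.data).max() <= 1e-9

    def test_atoms_outside_hull_rejected(self, point_molecule_factory):
        mol = point_molecule_factory([[0, 0, 0]], charges=[0.0])
        grid = fe.GridSpec(origin=(1.0, 1.0, 1.0), spacing=1.0, counts=(2, 2, 2))
        with pytest.raises(fe.FieldEngineError, match="outside"):
            fe.compute_field_table([mol], grid, PROBE)


def toy_table(data, n_points=None):
    n_points = n_points or data.shape[1] // 2
    grid_counts = (n_points, 1, 1)
    grid = fe.GridSpec(origin=(0, 0, 0), spacing=1.0, counts=grid_counts)
    return fe.FieldTable(
        ids=[f"m{i}" for i in range(data.shape[0])],
        data=np.asarray(data, dtype=float),
        grid=grid,
        probe=PROBE,
    )


class TestFilterColumns:
    def test_constant_column_masked(self):
        data = np.array([[1.0, 5.0, 0.0, 1.0], [1.0, -5.0, 0.0, 8.0], [1.0, 5.0, 0.0, -8.0]])
        table = fe.filter_columns(toy_table(data), min_sigma=2.0)
        assert not table.mask[0] and not table.mask[2]
        assert table.mask[1] and table.mask[3]

    def test_zero_threshold_keeps_all(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        table = fe.filter_columns(toy_table(data, n_points=1), min_sigma=0.0)
        assert table.mask.all()

    def test_mask_equals_direct_sd(self):
        rng = np.random.default_rng(0)
        data = rng.normal(scale=3.0, size=(8, 10))
        table = fe.filter_columns(toy_table(data), min_sigma=2.5)
        expected = data.std(axis=0, ddof=1) >= 2.5
        assert np.array_equal(table.mask, expected)

    def test_all_masked_rejected(self):
        data = np.ones((4, 4))
        with pytest.raises(fe.FieldEngineError, match="no variance"):
            fe.filter_columns(toy_table(data), min_sigma=2.0)


class TestScaleComfaStd:
    def test_block_variances_equalized(self):
        rng = np.random.default_rng(1)
        data = np.hstack([rng.normal(scale=5, size=(10, 6)), rng.normal(scale=0.5, size=(10, 6))])
        table = fe.scale_comfa_std(fe.filter_columns(toy_table(data), min_sigma=0.0))
        scaled = table.masked_scaled()
        labels = table.field_labels[table.mask]
        var_s = scaled[:, labels == "steric"].var(axis=0, ddof=1).sum()
        var_e = scaled[:, labels == "electrostatic"].var(axis=0, ddof=1).sum()
        assert var_s == pytest.approx(var_e, abs=1e-9)
        assert var_s == pytest.approx(1.0, abs=1e-9)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        data = rng.normal(scale=3, size=(9, 8))
        table = fe.scale_comfa_std(fe.filter_columns(toy_table(data), min_sigma=0.0))
        back = table.inverse_transform(table.masked_scaled())
        assert np.abs(back - table.masked_data()).max() <= 1e-9

    def test_one_block_reduces_to_unit_total_variance(self):
        rng = np.random.default_rng(3)
        steric = rng.normal(scale=4, size=(10, 5))
        data = np.hstack([steric, np.zeros((10, 5))])  # flat electrostatic block
        table = fe.filter_columns(toy_table(data), min_sigma=0.1)
        assert not table.mask[5:].any()
        table = fe.scale_comfa_std(table)
        scaled = table.masked_scaled()
        assert np.abs(scaled.mean(axis=0)).max() <= 1e-9
        assert scaled.var(axis=0, ddof=1).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_block_rejected(self):
        data = np.hstack([np.random.default_rng(4).normal(size=(6, 3)), np.ones((6, 3))])
        table = toy_table(data)  # keep constant columns unmasked on purpose
        with pytest.raises(fe.FieldEngineError, match="electrostatic"):
            fe.scale_comfa_std(table)


class TestApplyScaling:
    def test_projects_new_rows_like_training_rows(self):
        rng = np.random.default_rng(5)
        data = rng.normal(scale=3, size=(10, 8))
        table = fe.scale_comfa_std(fe.filter_columns(toy_table(data), min_sigma=0.0))
        projected = fe.apply_scaling(table, data)
        assert np.abs(projected - table.masked_scaled()).max() <= 1e-12

    def test_width_mismatch_rejected(self):
        data = np.random.default_rng(6).normal(size=(5, 8))
        table = fe.scale_comfa_std(fe.filter_columns(toy_table(data), min_sigma=0.0))
        with pytest.raises(fe.FieldEngineError, match="width"):
            fe.apply_scaling(table, data[:, :4])


class TestPackagedRunBounds:
    def test_truncation_bounds_hold(self, pipeline_result):
        table = pipeline_result.table
        p = table.n_points
        steric = table.data[:, :p]
        elec = table.data[:, p:]
        assert steric.max() <= 30.0 + 1e-12
        assert elec.min() >= -30.0 - 1e-12 and elec.max() <= 30.0 + 1e-12
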