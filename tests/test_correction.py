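"""Finite-size-effect removal: r-clean, Q-clean and the analytic references."""

import math

import numpy as np
import pytest

import mdscatter as m
from mdscatter.correction import (BoxSpec, cuboid_amplitude,
                                  effective_scattering_lengths,
                                  sphere_amplitude)
from mdscatter.species import FM_TO_ANGSTROM


class TestCuboidAmplitude:
    def test_q_zero_is_rho_times_volume(self):
        box = BoxSpec.create((10, 20, 30), (0, 0, 0), 2e-5)
        F = cuboid_amplitude(box, np.zeros(3))
        assert complex(F) == pytest.approx(2e-5 * 6000, rel=1e-12)

    def test_zero_at_axis_harmonic(self):
        box = BoxSpec.create(20.0, (0, 0, 0), 1e-5)
        F = cuboid_amplitude(box, np.array([2 * np.pi / 20.0, 0, 0]))
        assert abs(F) == pytest.approx(0.0, abs=1e-15)

    def test_worked_modulus(self):
        box = BoxSpec.create(20.0, (10, 10, 10), 6.646e-5)
        F = cuboid_amplitude(box, np.array([0.1, 0.0, 0.0]))
        expected = 6.646e-5 * 8000 * np.sin(1.0) / 1.0
        assert abs(F) == pytest.approx(abs(expected), rel=1e-12)
        assert abs(F) == pytest.approx(0.4474, abs=5e-4)

    def test_against_numerical_integration(self):
        # Riemann sum of rho * exp(iQ.R) over the cuboid as an independent check
        box = BoxSpec.create((8.0, 12.0, 5.0), (1.0, -2.0, 3.0), 3e-5)
        qv = np.array([0.4, -0.25, 0.6])
        n = 120
        axes = [np.linspace(c - e / 2, c + e / 2, n, endpoint=False) + e / (2 * n)
                for c, e in zip(box.center, box.edges)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        phases = qv[0] * gx + qv[1] * gy + qv[2] * gz
        dv = box.volume / n**3
        numeric = box.sld * np.exp(1j * phases).sum() * dv
        analytic = complex(cuboid_amplitude(box, qv))
        assert analytic == pytest.approx(numeric, rel=1e-3)

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            BoxSpec.create((0.0, 1.0, 1.0), (0, 0, 0), 1e-5)


class TestSolventSLD:
    def test_single_unit_atom(self):
        traj = m.Trajectory(labels=np.array(["X"], dtype=object),
                            frames=np.zeros((1, 1, 3)),
                            box=np.array([[1.0] * 3]), wrapped=True)
        table = m.SpeciesTable()
        table.add(m.AtomSpecies("X", 1.0, 0.0, (0,) * 4, (0,) * 4, 0.0,
                                (3 / (4 * math.pi)) ** (1 / 3)))
        sel = m.select_atoms(traj, "all")
        sld = m.solvent_sld(traj, sel, table)
        assert sld.value == pytest.approx(1e-5, rel=1e-9)

    def test_toy_solvent_cell_volume(self, toy_traj, toy_table):
        sel = m.select_atoms(toy_traj, "species:V")
        sld = m.solvent_sld(toy_traj, sel, toy_table, method="cell-volume",
                            cell_volume=1.0)
        assert sld.value == pytest.approx(6.646e-5, rel=1e-12)
        assert sld.n_atoms_used == 7448

    def test_three_water_molecules_vdw_brute_force(self, default_table):
        # 3 x (O + 2H); sum b = 3(5.803 - 2*3.739) fm, sum V from Bondi radii
        labels = np.array(["O", "H", "H"] * 3, dtype=object)
        traj = m.Trajectory(labels=labels, frames=np.zeros((1, 9, 3)),
                            box=np.array([[10.0] * 3]), wrapped=True)
        sld = m.solvent_sld(traj, m.select_atoms(traj, "all"), default_table)
        v_o = 4 / 3 * math.pi * 1.52**3
        v_h = 4 / 3 * math.pi * 1.20**3
        expected = (3 * (5.803 + 2 * -3.7390) * 1e-5) / (3 * (v_o + 2 * v_h))
        assert sld.value == pytest.approx(expected, rel=1e-9)

    def test_empty_selection_and_bad_method(self, toy_traj, toy_table):
        sel = m.AtomSelection(np.array([], dtype=int), "empty")
        with pytest.raises(ValueError, match="empty"):
            m.solvent_sld(toy_traj, sel, toy_table)
        with pytest.raises(ValueError, match="cell_volume"):
            m.solvent_sld(toy_traj, m.select_atoms(toy_traj, "all"),
                          toy_table, method="cell-volume")


class TestRClean:
    def test_zero_sld_identical_to_naive_bitwise(self, toy_traj, toy_table):
        # a zero-b solvent species gives rho_sol = 0, hence unchanged lengths
        table = m.SpeciesTable(dict(toy_table.entries), "test")
        table.add(m.AtomSpecies("W", 0.0, 0.0, (0,) * 4, (0,) * 4, 0.0, 0.62))
        labels = np.array(["W"] * toy_traj.n_atoms, dtype=object)
        labels[:100] = "V"
        traj = m.Trajectory(labels=labels, frames=toy_traj.frames,
                            box=toy_traj.box, wrapped=True)
        grid = m.make_qgrid(0.05, 0.5, 4, 8, seed=6)
        sel = m.select_atoms(traj, "species:W")
        rc = m.diffractogram_rclean(traj, grid, table, sel)
        naive = m.diffractogram_naive(traj, grid, table.b_coh_array(labels))
        np.testing.assert_array_equal(rc.S, naive.S)

    def test_homogeneous_solvent_completely_masked(self):
        # vdW volumes tile the box exactly -> effective lengths all zero
        traj, table = m.make_homogeneous_lattice(10, 1, b=6.646)
        grid = m.make_qgrid(0.0, 1.0, 5, 10, seed=2)
        sel = m.select_atoms(traj, "all")
        rc = m.diffractogram_rclean(traj, grid, table, sel,
                                    sld_method="cell-volume", cell_volume=1.0)
        np.testing.assert_allclose(rc.S, 0.0, atol=1e-18)

    def test_effective_lengths_formula(self):
        b_eff = effective_scattering_lengths(
            np.array([6.646]), np.array([1.0]), 6.646e-5)
        assert b_eff[0] == pytest.approx(0.0, abs=1e-12)

    def test_toy_small_angle_matches_solute_reference_after_scale(
            self, toy_traj, toy_table):
        # after masking the solvent, the small-angle curve should be the
        # (discrete) sphere's, up to the documented global intensity shift
        grid = m.make_qgrid(0.0, 0.6, 61, 60, seed=12)
        sel = m.select_atoms(toy_traj, "species:V")
        rc = m.diffractogram_rclean(toy_traj, grid, toy_table, sel,
                                    sld_method="cell-volume", cell_volume=1.0)
        solute = m.select_atoms(toy_traj, "species:U")
        coords = toy_traj.frames[0][solute.indices]
        ref = m.debye_oracle(coords, np.full(len(solute), -3.739),
                             grid.q_values) / toy_traj.n_atoms
        s = m.fit_scale_factor(grid.q_values, rc.D, grid.q_values, ref,
                               (0.0, 0.4))
        resid = rc.D - s * ref
        mask = grid.q_values <= 0.4
        assert np.sqrt(np.mean(resid[mask] ** 2)) < 0.05 * np.max(s * ref)


class TestQClean:
    def test_zero_sld_identical_to_naive_bitwise(self, toy_traj, toy_table):
        b = toy_table.b_coh_array(toy_traj.labels)
        grid = m.make_qgrid(0.0, 0.5, 6, 10, seed=4)
        box = BoxSpec.create(20.0, (10, 10, 10), 0.0)
        qc = m.diffractogram_qclean(toy_traj, grid, b, box)
        naive = m.diffractogram_naive(toy_traj, grid, b)
        np.testing.assert_array_equal(qc.S, naive.S)

    def test_homogeneous_lattice_small_angle_suppressed(self):
        traj, table = m.make_homogeneous_lattice(20, 1, b=1.0)
        b = table.b_coh_array(traj.labels)
        grid = m.make_qgrid(0.1, 0.2, 2, 30, seed=5)
        naive = m.diffractogram_naive(traj, grid, b)
        box = BoxSpec.create(20.0, (10, 10, 10), 1.0e-5)
        qc = m.diffractogram_qclean(traj, grid, b, box)
        assert np.all(naive.S / qc.S > 100.0)

    def test_wide_angle_untouched_random_box(self):
        rng = np.random.default_rng(7)
        n, edge = 1000, 46.0
        coords = rng.uniform(0, edge, (n, 3))
        traj = m.Trajectory(labels=np.full(n, "O", dtype=object),
                            frames=coords[None],
                            box=np.array([[edge] * 3]), wrapped=True)
        b = np.full(n, 5.803)
        grid = m.make_qgrid(5.0, 10.0, 11, 100, seed=9)
        naive = m.diffractogram_naive(traj, grid, b)
        rho = n * 5.803e-5 / edge**3
        box = BoxSpec.create(edge, (edge / 2,) * 3, rho)
        qc = m.diffractogram_qclean(traj, grid, b, box)
        rel = np.abs(qc.S - naive.S) / naive.S
        assert rel.mean() < 0.01

    def test_box_cell_mismatch_guard(self, toy_traj, toy_table):
        b = toy_table.b_coh_array(toy_traj.labels)
        grid = m.make_qgrid(0.0, 0.2, 2, 4, seed=0)
        box = BoxSpec.create(25.0, (10, 10, 10), 1e-5)
        with pytest.raises(ValueError, match="differ from trajectory cell"):
            m.diffractogram_qclean(toy_traj, grid, b, box)
        m.diffractogram_qclean(toy_traj, grid, b, box, force=True)

    def test_amplitude_level_phase_consistency(self):
        # rigid shift of system + box commutes with the subtraction
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 12, (40, 3))
        b = rng.uniform(1, 4, 40)
        shift = np.array([2.3, -1.1, 0.7])
        qv = np.array([[0.31, -0.12, 0.55], [1.4, 0.2, -0.3]])
        box = BoxSpec.create(12.0, (6, 6, 6), 2e-5)
        box_shifted = BoxSpec.create(12.0, tuple(np.array(box.center) + shift),
                                     2e-5)
        lhs = (m.scattering_amplitude(coords + shift, b, qv)
               - cuboid_amplitude(box_shifted, qv) / FM_TO_ANGSTROM)
        phase = np.exp(1j * (qv @ shift))
        rhs = phase * (m.scattering_amplitude(coords, b, qv)
                       - cuboid_amplitude(box, qv) / FM_TO_ANGSTROM)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)


class TestSphereReference:
    def test_q_zero_intensity(self):
        r, drho = 5.0, -3.941e-5
        vol = 4 / 3 * math.pi * r**3
        i0 = m.sphere_form_factor(r, drho, 0.0)
        assert i0[0] == pytest.approx((drho * vol / FM_TO_ANGSTROM) ** 2,
                                      rel=1e-12)

    def test_first_zero_at_4p4934(self):
        r = 5.0
        q = np.linspace(0.80, 1.0, 2001)
        amp = sphere_amplitude(r, 1e-5, q)
        sign_change = np.where(np.diff(np.sign(amp)))[0]
        q_zero = q[sign_change[0]]
        assert q_zero * r == pytest.approx(4.4934, abs=2e-3)

    def test_worked_amplitude(self):
        # R = 5 A sphere with the toy's effective solute SLD
        amp = sphere_amplitude(5.0, -3.941e-5, 0.0)
        assert amp[0] == pytest.approx(-3.941e-5 * 523.599, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sphere_amplitude(-1.0, 1e-5, 0.1)
        with pytest.raises(ValueError):
            sphere_amplitude(1.0, 1e-5, -0.1)


class TestEffectiveSphereSLD:
    def test_toy_reference_parameterisation(self, toy_traj, toy_table):
        sel = m.select_atoms(toy_traj, "species:U")
        sld = m.effective_sphere_sld(toy_traj, sel, 5.0, (10, 10, 10),
                                     toy_table)
        assert sld / 1e-5 == pytest.approx(-3.941, abs=0.005)

    def test_radius_below_nearest_site_is_empty(self, toy_traj, toy_table):
        sel = m.select_atoms(toy_traj, "species:U")
        with pytest.raises(ValueError, match="no solute atoms"):
            m.effective_sphere_sld(toy_traj, sel, 0.4, (10, 10, 10),
                                   toy_table)
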