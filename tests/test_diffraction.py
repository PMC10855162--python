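"""Scattering amplitudes, orientation-averaged S(Q) and the Debye oracle."""

import numpy as np
import pytest

import mdscatter as m
from mdscatter.diffraction import sinc


def _random_system(n, edge, seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, edge, (n, 3))
    b = rng.uniform(1, 5, n)
    traj = m.Trajectory(labels=np.full(n, "V", dtype=object),
                        frames=coords[None], box=np.array([[edge] * 3]),
                        wrapped=True)
    return traj, coords, b


class TestAmplitude:
    def test_q_zero_is_total_scattering_length(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (50, 3))
        b = rng.uniform(-4, 7, 50)
        F = m.scattering_amplitude(coords, b, np.zeros(3))
        assert complex(F) == pytest.approx(b.sum(), rel=1e-12)

    def test_single_atom_at_origin(self):
        F = m.scattering_amplitude(np.zeros((1, 3)), np.array([2.5]),
                                   np.array([0.3, -0.1, 0.9]))
        assert complex(F) == pytest.approx(2.5, rel=1e-12)

    def test_two_atom_closed_form(self):
        d = 3.0
        coords = np.array([[0.0, 0, 0], [0, 0, d]])
        b = np.ones(2)
        for q in (0.2, 1.0, np.pi / d):
            F = m.scattering_amplitude(coords, b, np.array([0, 0, q]))
            expected = 1 + np.exp(1j * q * d)
            assert complex(F) == pytest.approx(expected, rel=1e-12)
            assert abs(F) ** 2 == pytest.approx(2 + 2 * np.cos(q * d),
                                                abs=1e-12)

    def test_linear_in_b(self):
        coords = np.random.default_rng(1).uniform(0, 5, (10, 3))
        b = np.arange(1.0, 11.0)
        qv = np.array([0.7, 0.1, -0.4])
        F1 = m.scattering_amplitude(coords, b, qv)
        F2 = m.scattering_amplitude(coords, 3.0 * b, qv)
        assert complex(F2) == pytest.approx(3.0 * complex(F1), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            m.scattering_amplitude(np.zeros((3, 3)), np.ones(2), np.zeros(3))


class TestDiffractogramNaive:
    def test_single_atom_is_flat_b_squared(self):
        traj = m.Trajectory(labels=np.array(["O"], dtype=object),
                            frames=np.zeros((1, 1, 3)) + 2.0,
                            box=np.array([[5.0] * 3]), wrapped=True)
        grid = m.make_qgrid(0.0, 2.0, 5, 16, seed=0)
        d = m.diffractogram_naive(traj, grid, np.array([5.803]))
        np.testing.assert_allclose(d.S, 5.803**2, rtol=1e-12)

    def test_matches_debye_oracle_within_mc_error(self):
        traj, coords, b = _random_system(200, 15.0, seed=11)
        grid = m.make_qgrid(0.1, 2.0, 10, 400, seed=3)
        d = m.diffractogram_naive(traj, grid, b)
        oracle = m.debye_oracle(coords, b, grid.q_values)
        z = np.abs(d.S - oracle) / d.stderr
        assert np.all(z < 3.0)

    def test_translation_invariance(self):
        traj, coords, b = _random_system(60, 10.0, seed=5)
        grid = m.make_qgrid(0.2, 3.0, 6, 20, seed=9)
        s0 = m.diffractogram_naive(traj, grid, b).S
        shifted = m.Trajectory(labels=traj.labels,
                               frames=traj.frames + np.array([3.1, -2.0, 7.7]),
                               box=traj.box, wrapped=False)
        s1 = m.diffractogram_naive(shifted, grid, b, force=True).S
        np.testing.assert_allclose(s1, s0, rtol=1e-10)

    def test_doubling_orientations_halves_variance(self):
        # variance of the orientational MC estimate scales as 1/n_orient
        traj, coords, b = _random_system(50, 8.0, seed=2)
        q = np.array([1.0])
        est = {40: [], 80: []}
        seed = 100
        for rep in range(20):
            for no in (40, 80):
                seed += 1
                grid = m.QGrid(q_values=q,
                               orientations=m.make_qgrid(0.5, 1.0, 2, no,
                                                         seed=seed).orientations,
                               seed=seed)
                est[no].append(m.diffractogram_naive(traj, grid, b).S[0])
        ratio = np.var(est[40]) / np.var(est[80])
        assert 1.0 < ratio < 3.0


class TestDebyeOracle:
    def test_single_atom(self):
        s = m.debye_oracle(np.zeros((1, 3)), np.array([3.0]), [0.5, 1.0])
        np.testing.assert_allclose(s, 9.0)

    def test_two_atoms_at_sinc_zero(self):
        d = 4.0
        coords = np.array([[0.0, 0, 0], [0, 0, d]])
        s = m.debye_oracle(coords, np.ones(2), [np.pi / d])
        assert s[0] == pytest.approx(2.0, abs=1e-12)

    def test_sinc_convention(self):
        assert sinc(0.0) == 1.0
        assert sinc(np.pi) == pytest.approx(0.0, abs=1e-15)
        assert sinc(1.0) == pytest.approx(np.sin(1.0), rel=1e-12)


class TestNormalization:
    def test_modes(self):
        S = np.array([8.0, 4.0])
        b = np.array([2.0, 2.0])
        np.testing.assert_allclose(
            m.normalize_diffractogram(S, "per-atom", 2, b), [4.0, 2.0])
        np.testing.assert_allclose(
            m.normalize_diffractogram(S, "per-b2", 2, b), [1.0, 0.5])
        np.testing.assert_allclose(
            m.normalize_diffractogram(S, "none", 2, b), S)

    def test_per_b2_single_species_q0_equals_n(self):
        n = 7
        b = np.full(n, 3.0)
        S0 = (b.sum()) ** 2          # coherent amplitude at Q=0
        D = m.normalize_diffractogram(np.array([S0]), "per-b2", n, b)
        assert D[0] == pytest.approx(n)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown normalization"):
            m.normalize_diffractogram(np.ones(3), "weird", 1, None)


class TestScaleFactor:
    def test_identical_curves(self):
        q = np.linspace(0, 1, 50)
        c = np.exp(-q)
        assert m.fit_scale_factor(q, c, q, c, (0.1, 0.9)) == pytest.approx(1.0)

    def test_doubled_reference(self):
        q = np.linspace(0, 1, 50)
        c = 1.0 + q**2
        assert m.fit_scale_factor(q, c, q, 2 * c, (0, 1)) == pytest.approx(0.5)

    def test_empty_overlap(self):
        q = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="overlap"):
            m.fit_scale_factor(q, q, q, q, (5.0, 6.0))
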