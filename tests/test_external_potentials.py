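"""Uniaxial compression (V_ext = k/2 Σ z²), pulling force, and composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechpes.backends import BeadSpringFlex, HarmonicDiatomic, fd_gradient
from mechpes.external import (LinearTilt, ModifiedPES, PullingForce,
                              UniaxialCompression, compose_modified_pes,
                              pulling_energy, uniaxial_energy, uniaxial_force)
from mechpes.geometry import Geometry
from mechpes.optimize import OptimizationSettings, minimize
from mechpes.units import ANGSTROM_TO_BOHR

AVOGADRO = 6.02214076e23
CAL = 4.184


def random_geometry(n, seed, spread=4.0):
    rng = np.random.default_rng(seed)
    return Geometry(("C",) * n, rng.uniform(-spread, spread, (n, 3)))


class TestUniaxialEnergy:
    def test_zero_coupling(self):
        assert uniaxial_energy(random_geometry(5, 1), 0.0) == 0.0

    def test_planar_geometry_costs_nothing(self):
        coords = np.array([[1.0, 2.0, 0.0], [-3.0, 0.5, 0.0]])
        assert uniaxial_energy(Geometry(("H", "H"), coords), 50.0) == 0.0

    def test_two_atoms_at_one_angstrom_hand_conversion(self):
        # 2 × (50/2 N/m) × (1e-10 m)² = 5.0e-19 J → × N_A / 4184 kcal/mol
        geom = Geometry(("H", "H"), np.array([[0, 0, 1.0], [0, 0, -1.0]]))
        expected = 5.0e-19 * AVOGADRO / (CAL * 1000.0)
        assert uniaxial_energy(geom, 50.0) == pytest.approx(expected, rel=1e-6)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            UniaxialCompression(-1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.floats(0.0, 2 * np.pi),
           st.floats(-10.0, 10.0), st.floats(-10.0, 10.0))
    def test_invariant_under_z_rotation_and_xy_translation(self, seed, angle, tx, ty):
        geom = random_geometry(6, seed)
        e0 = uniaxial_energy(geom, 25.0)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = geom.with_coords(geom.coords @ rot.T + np.array([tx, ty, 0.0]))
        assert uniaxial_energy(moved, 25.0) == pytest.approx(e0, abs=1e-10)

    def test_strictly_increasing_in_atom_height(self):
        energies = [uniaxial_energy(
            Geometry(("H",), np.array([[0.0, 0.0, z]])), 30.0)
            for z in (0.1, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(energies) > 0)

    def test_zero_iff_in_plane(self):
        geom = random_geometry(4, 3)
        assert uniaxial_energy(geom, 10.0) > 0
        flat = geom.with_coords(np.column_stack([geom.coords[:, :2],
                                                 np.zeros(4)]))
        assert uniaxial_energy(flat, 10.0) == 0.0


class TestUniaxialForce:
    def test_in_plane_atom_feels_nothing(self):
        geom = Geometry(("H",), np.array([[2.0, -1.0, 0.0]]))
        assert np.all(uniaxial_force(geom, 40.0) == 0.0)

    def test_force_is_minus_k_z_exactly(self):
        term = UniaxialCompression(50.0)
        x = np.array([0.0, 0.0, 1.0])  # one atom at z = 1 bohr
        f = term.force(x)
        assert f[0, 2] == -term.k_au
        assert f[0, 0] == 0.0 and f[0, 1] == 0.0

    def test_matches_finite_differences_of_energy(self):
        term = UniaxialCompression(35.0)
        x = random_geometry(10, 5).coords.ravel() * ANGSTROM_TO_BOHR
        g_fd = fd_gradient(term.energy, x, 1e-5)
        assert np.max(np.abs(term.gradient(x) - g_fd)) < 1e-8


class TestPullingForce:
    def test_zero_force_zero_energy(self):
        assert pulling_energy(random_geometry(3, 9), 0.0, (0, 2)) == 0.0

    def test_two_angstrom_one_nanonewton_hand_conversion(self):
        # −(1e-9 N × 2e-10 m) = −2e-19 J per molecule → kcal/mol
        geom = Geometry(("H", "H"), np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                        attachment_pair=(0, 1))
        expected = -2.0e-19 * AVOGADRO / (CAL * 1000.0)
        assert pulling_energy(geom, 1.0) == pytest.approx(expected, rel=1e-6)

    def test_gradient_support_restricted_to_pair_and_antiparallel(self):
        term = PullingForce(2.0, (1, 3))
        x = random_geometry(5, 13).coords.ravel() * ANGSTROM_TO_BOHR
        g = term.gradient(x).reshape(-1, 3)
        assert np.all(g[[0, 2, 4]] == 0.0)
        assert np.allclose(g[1], -g[3], atol=1e-14)
        r = x.reshape(-1, 3)
        axis = (r[1] - r[3]) / np.linalg.norm(r[1] - r[3])
        cross = np.cross(g[1], axis)
        assert np.max(np.abs(cross)) < 1e-12

    def test_gradient_matches_finite_differences(self):
        term = PullingForce(3.0, (0, 4))
        x = random_geometry(6, 17).coords.ravel() * ANGSTROM_TO_BOHR
        g_fd = fd_gradient(term.energy, x, 1e-5)
        assert np.max(np.abs(term.gradient(x) - g_fd)) < 1e-8

    def test_coincident_attachment_atoms_rejected(self):
        term = PullingForce(1.0, (0, 1))
        x = np.zeros(6)
        with pytest.raises(ValueError, match="coincide"):
            term.energy(x)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            PullingForce(-0.5, (0, 1))


class TestComposition:
    def test_empty_terms_is_identity(self, flex):
        pes = compose_modified_pes(flex, [])
        geom = flex.reference_reactant()
        assert pes.energy(geom) == flex.energy(geom)

    def test_planar_geometry_unaffected_by_compression(self):
        base = HarmonicDiatomic()
        geom = base.reference_geometry(axis=0)  # bond in the plane
        pes = compose_modified_pes(base, [UniaxialCompression(50.0)])
        assert pes.energy(geom) == pytest.approx(base.energy(geom), abs=1e-15)

    def test_additivity_of_terms(self, flex):
        geom = flex.reference_reactant()
        x = flex.to_internal(geom)
        pull = PullingForce(2.0, (0, 2))
        comp = UniaxialCompression(20.0)
        pes = compose_modified_pes(flex, [pull, comp])
        total = flex._energy(x) + pull.energy(x) + comp.energy(x)
        assert pes._energy(x) == pytest.approx(total, abs=1e-12)
        g_total = flex._gradient(x) + pull.gradient(x) + comp.gradient(x)
        assert np.max(np.abs(pes._gradient(x) - g_total)) < 1e-12

    def test_modified_pes_satisfies_backend_contract(self, flex):
        pes = compose_modified_pes(flex, [UniaxialCompression(10.0)])
        x = flex.to_internal(flex.reference_reactant())
        g_fd = fd_gradient(pes._energy, x, 1e-4)
        assert np.max(np.abs(pes._gradient(x) - g_fd)) < 1e-6

    def test_zero_strength_terms_recover_unperturbed_stationary_points(self, flex):
        settings = OptimizationSettings(gradient_convergence=1e-9)
        start = flex.reference_reactant()
        plain = minimize(start, flex, settings)
        modified = compose_modified_pes(
            flex, [UniaxialCompression(0.0), PullingForce(0.0, (0, 2))])
        perturbed = minimize(start, modified, settings)
        dx = (perturbed.geometry.coords - plain.geometry.coords) * ANGSTROM_TO_BOHR
        assert np.max(np.abs(dx)) < 1e-5
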