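"""Scan drivers: tilted-well oracle equivalence, continuation, flex contrast."""

import numpy as np
import pytest

from mechpes.backends import HarmonicDiatomic, QuarticDoubleWell
from mechpes.external import LinearTilt
from mechpes.optimize import OptimizationSettings, dimer_ts_search, minimize
from mechpes.scans import (DEFAULT_FORCE_GRID_NN, DEFAULT_K_GRID_NPM,
                           ScanError, ScanResult, activation_energy,
                           scan_pulling_force, scan_uniaxial_k)
from mechpes.units import HARTREE_TO_KCALMOL, NN_TO_AU_FORCE

from oracles import tilted_double_well_barrier


def tilt_factory(f_nn):
    return [LinearTilt(f_nn * NN_TO_AU_FORCE, atom=0, axis=0)]


@pytest.fixture(scope="module")
def tilted_scan(qdw):
    settings = OptimizationSettings(gradient_convergence=1e-9)
    return scan_pulling_force(qdw.geometry(-qdw.minimum_x), qdw.geometry(0.05),
                              qdw, settings=settings, term_factory=tilt_factory)


class TestTiltedDoubleWellOracle:
    def test_barriers_match_cubic_root_finding_across_grid(self, qdw, tilted_scan):
        table = tilted_scan.table
        assert tilted_scan.all_converged()
        for _, row in table.iterrows():
            f_au = row["strength"] * NN_TO_AU_FORCE
            _, _, barrier = tilted_double_well_barrier(qdw.a, qdw.b, f_au)
            assert row["e_ts"] - row["e_reactant"] == pytest.approx(barrier, abs=1e-8)

    def test_zero_force_row_equals_unperturbed_barrier(self, qdw, tilted_scan):
        va0 = tilted_scan.table.iloc[0]
        assert va0["strength"] == 0.0
        assert va0["e_ts"] - va0["e_reactant"] == pytest.approx(qdw.barrier, abs=1e-9)

    def test_rows_sorted_and_activation_consistent(self, tilted_scan):
        table = tilted_scan.table
        assert np.all(np.diff(table["strength"]) > 0)
        recomputed = (table["e_ts"] - table["e_reactant"]) * HARTREE_TO_KCALMOL
        assert np.allclose(table["activation_kcal"], recomputed, rtol=0, atol=0)

    def test_continuation_matches_cold_start(self, qdw, tilted_scan):
        settings = OptimizationSettings(gradient_convergence=1e-9)
        cold = scan_pulling_force(qdw.geometry(-qdw.minimum_x),
                                  qdw.geometry(0.05), qdw, settings=settings,
                                  term_factory=tilt_factory, cold_start=True)
        dv = cold.activation_energies - tilted_scan.activation_energies
        assert np.max(np.abs(dv)) < 1e-6


class TestUniaxialScan:
    def test_two_atom_closed_form_across_grid(self):
        hd = HarmonicDiatomic()
        settings = OptimizationSettings(gradient_convergence=1e-8)
        result = scan_uniaxial_k(hd.reference_geometry(axis=2), None, hd,
                                 settings=settings, align="none")
        for _, row in result.table.iterrows():
            assert row["e_reactant"] == pytest.approx(
                hd.compressed_energy(row["strength"]), abs=1e-8)
            assert row["reactant_converged"]

    def test_flex_activation_energy_strictly_decreases_with_k(self, flex):
        result = scan_uniaxial_k(flex.reference_reactant(),
                                 flex.reference_ts_guess(), flex)
        assert result.all_converged()
        va = result.activation_energies
        assert np.all(np.diff(va) < 0)
        assert list(result.strengths) == list(DEFAULT_K_GRID_NPM)

    def test_flex_reactant_flattens_monotonically(self, flex):
        result = scan_uniaxial_k(flex.reference_reactant(),
                                 flex.reference_ts_guess(), flex)
        z2 = result.table["reactant_sum_z2"].to_numpy()
        assert np.all(np.diff(z2) <= 1e-8)

    def test_k_zero_row_reproduces_unperturbed_barrier(self, flex):
        settings = OptimizationSettings(gradient_convergence=1e-6)
        result = scan_uniaxial_k(flex.reference_reactant(),
                                 flex.reference_ts_guess(), flex,
                                 grid=[0.0], settings=settings)
        r = minimize(flex.reference_reactant(), flex, settings)
        t = dimer_ts_search(flex.reference_ts_guess(), flex, settings)
        va_direct = activation_energy(r, t)
        assert result.activation_energies[0] == pytest.approx(va_direct, abs=1e-6)


class TestPullingScanOnFlex:
    def test_activation_energy_nearly_flat_under_attachment_pulling(self, flex):
        # pulling across A–C is orthogonal to the payload-release coordinate:
        # the barrier must stay within 5% of its zero-force value
        result = scan_pulling_force(flex.reference_reactant(),
                                    flex.reference_ts_guess(), flex)
        assert result.all_converged()
        va = result.activation_energies
        assert np.max(np.abs(va - va[0])) < 0.05 * va[0]
        assert list(result.strengths) == list(DEFAULT_FORCE_GRID_NN)

    def test_force_zero_row_reproduces_unperturbed_barrier(self, flex):
        settings = OptimizationSettings(gradient_convergence=1e-6)
        result = scan_pulling_force(flex.reference_reactant(),
                                    flex.reference_ts_guess(), flex,
                                    grid=[0.0], settings=settings)
        r = minimize(flex.reference_reactant(), flex, settings)
        t = dimer_ts_search(flex.reference_ts_guess(), flex, settings)
        assert result.activation_energies[0] == pytest.approx(
            activation_energy(r, t), abs=1e-6)


class TestActivationEnergy:
    def test_identical_points_give_zero(self, qdw):
        point = minimize(qdw.geometry(1.2), qdw)
        assert activation_energy(point, point) == 0.0

    def test_quartic_barrier_in_kcal(self, qdw):
        settings = OptimizationSettings(gradient_convergence=1e-8)
        r = minimize(qdw.geometry(1.2), qdw, settings)
        t = dimer_ts_search(qdw.geometry(0.2), qdw, settings)
        # b²/4a = 1 hartree = 627.5095 kcal/mol
        assert activation_energy(r, t) == pytest.approx(627.5095, abs=1e-3)

    def test_muller_brown_lowest_barrier_matches_oracle(self, mb, mb_oracle):
        settings = OptimizationSettings(gradient_convergence=1e-6)

        def exy(p):
            return mb._energy(np.array([p[0], p[1], 0.0]))

        minima_e = [exy(p) for p in mb_oracle["minima"]]
        global_min = mb_oracle["minima"][int(np.argmin(minima_e))]
        # the saddle adjacent to the global minimum (left-most saddle)
        saddle = mb_oracle["saddles"][0]
        oracle_barrier = (exy(saddle) - min(minima_e)) * HARTREE_TO_KCALMOL
        r = minimize(mb.geometry(*global_min), mb, settings)
        t = dimer_ts_search(mb.geometry(*saddle), mb, settings)
        assert activation_energy(r, t) == pytest.approx(oracle_barrier, abs=1e-5)

    def test_mismatched_surfaces_rejected(self, qdw, flex):
        a = minimize(qdw.geometry(1.2), qdw)
        b = minimize(flex.reference_reactant(), flex)
        with pytest.raises(ScanError, match="invalid"):
            activation_energy(a, b)


class TestScanResultIO:
    def test_csv_round_trip(self, tmp_path, tilted_scan):
        path = tmp_path / "scan.csv"
        tilted_scan.to_csv(path)
        back = ScanResult.from_csv(path)
        assert back.metadata["backend"] == tilted_scan.metadata["backend"]
        assert back.metadata["grid"] == tilted_scan.metadata["grid"]
        for col in ("strength", "e_reactant", "e_ts", "activation_kcal"):
            assert np.allclose(back.table[col], tilted_scan.table[col],
                               rtol=0, atol=1e-12)
        assert list(back.table["row_valid"]) == list(tilted_scan.table["row_valid"])
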