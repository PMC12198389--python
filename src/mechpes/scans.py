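"""Activation-energy scan drivers.

A scan increases the strength of one external perturbation stepwise — the
pulling force in increments of 0.5 nN up to 4.0 nN, or the uniaxial
compression force constant in increments of 10 N m⁻¹ with finer steps below
20 N m⁻¹ — and at each strength re-optimizes the reactant minimum and the
transition state on the modified surface, warm-starting both from the
previous step's converged structures (continuation).  The tabulated
activation energy is V_A = E(TS) − E(reactant) in kcal mol⁻¹.

A transition state that stops being a first-order saddle at some strength
(its negative eigenvalue lost or a second one gained) marks that row
invalid rather than being reported silently; failed convergence likewise
flags the row and the scan continues.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .backends import PotentialBackend
from .external import ExternalTerm, PullingForce, UniaxialCompression, compose_modified_pes
from .geometry import Geometry, align_to_frame
from .optimize import OptimizationSettings, StationaryPoint, dimer_ts_search, minimize
from .units import HARTREE_TO_KCALMOL

#: pulling-force grid: 0 → 4.0 nN in 0.5 nN increments
DEFAULT_FORCE_GRID_NN: Tuple[float, ...] = tuple(np.arange(0.0, 4.01, 0.5))

#: compression grid: 10 N m⁻¹ increments, refined {2.5, 5, 10, 15} below 20
DEFAULT_K_GRID_NPM: Tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)

_COLUMNS = ["strength", "unit", "e_reactant", "e_ts", "activation_kcal",
            "reactant_converged", "ts_converged", "ts_classification", "row_valid",
            "reactant_sum_z2"]


class ScanError(RuntimeError):
    pass


def activation_energy(reactant: StationaryPoint, ts: StationaryPoint) -> float:
    """V_A = E(TS) − E(reactant) in kcal mol⁻¹, on one and the same PES.

    Raises when the two points were converged on differently-perturbed
    surfaces — energies across different external potentials are not
    comparable.
    """
    if reactant.pes_name != ts.pes_name:
        raise ScanError(
            "activation energy across different surfaces is invalid: "
            f"reactant on {reactant.pes_name!r}, TS on {ts.pes_name!r}"
        )
    return (ts.energy - reactant.energy) * HARTREE_TO_KCALMOL


@dataclass
class ScanResult:
    """Activation-energy table plus the metadata to reproduce it."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def strengths(self) -> np.ndarray:
        return self.table["strength"].to_numpy()

    @property
    def activation_energies(self) -> np.ndarray:
        """V_A per row in kcal mol⁻¹ (NaN for reactant-only scans)."""
        return self.table["activation_kcal"].to_numpy()

    def all_converged(self) -> bool:
        ok = self.table["reactant_converged"].all()
        if self.table["e_ts"].notna().any():
            ok = ok and self.table["row_valid"].all()
        return bool(ok)

    def to_csv(self, path) -> None:
        """CSV with '#'-prefixed metadata header lines."""
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key} = {json.dumps(value)}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScanResult":
        metadata = {}
        body = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].partition("=")
                    metadata[key.strip()] = json.loads(value.strip())
                else:
                    body.append(line)
        table = pd.read_csv(io.StringIO("".join(body)))
        return cls(table=table, metadata=metadata)


def _optimize_pair(reactant_start: Geometry, ts_start: Optional[Geometry],
                   pes, settings: OptimizationSettings):
    r_point = minimize(reactant_start, pes, settings)
    t_point = None
    if ts_start is not None:
        t_point = dimer_ts_search(ts_start, pes, settings)
    return r_point, t_point


def run_scan(reactant: Geometry, ts_guess: Optional[Geometry],
             pes_base: PotentialBackend,
             term_factory: Callable[[float], Sequence[ExternalTerm]],
             grid: Iterable[float], unit: str,
             settings: Optional[OptimizationSettings] = None,
             cold_start: bool = False,
             metadata: Optional[dict] = None) -> ScanResult:
    """Generic scan engine: one row per perturbation strength, sorted.

    ``term_factory`` maps a strength to the list of external terms for that
    row.  With ``cold_start=True`` every row starts from the original
    structures instead of the previous row's converged ones (an audit mode
    for continuation artifacts).  ``ts_guess=None`` scans the reactant only.
    """
    settings = settings or OptimizationSettings()
    rows = []
    r_start, t_start = reactant, ts_guess
    for strength in sorted(float(v) for v in grid):
        pes = compose_modified_pes(pes_base, term_factory(strength))
        r_point, t_point = _optimize_pair(r_start, t_start, pes, settings)
        row = {
            "strength": strength,
            "unit": unit,
            "e_reactant": r_point.energy,
            "e_ts": t_point.energy if t_point is not None else np.nan,
            "activation_kcal": (activation_energy(r_point, t_point)
                                if t_point is not None else np.nan),
            "reactant_converged": bool(r_point.converged),
            "ts_converged": bool(t_point.converged) if t_point is not None else True,
            "ts_classification": (t_point.classification
                                  if t_point is not None else ""),
            "reactant_sum_z2": r_point.geometry.sum_z_squared(),
        }
        row["row_valid"] = bool(
            row["reactant_converged"] and row["ts_converged"]
            and (t_point is None or t_point.classification == "first_order_saddle")
        )
        rows.append(row)
        if not cold_start:
            if r_point.converged:
                r_start = r_point.geometry
            if t_point is not None and row["row_valid"]:
                t_start = t_point.geometry
    table = pd.DataFrame(rows, columns=_COLUMNS)
    meta = {
        "backend": pes_base.name,
        "unit": unit,
        "grid": [float(v) for v in sorted(grid)],
        "cold_start": cold_start,
        "seed": settings.seed,
        "gradient_convergence": settings.gradient_convergence,
    }
    meta.update(metadata or {})
    failures = table.index[~table["row_valid"]].tolist()
    if failures:
        meta["failed_rows"] = [float(table.loc[i, "strength"]) for i in failures]
    return ScanResult(table=table, metadata=meta)


def scan_pulling_force(reactant: Geometry, ts_guess: Optional[Geometry],
                       pes_base: PotentialBackend,
                       grid: Optional[Iterable[float]] = None,
                       settings: Optional[OptimizationSettings] = None,
                       attachment_pair: Optional[Tuple[int, int]] = None,
                       term_factory: Optional[Callable] = None,
                       cold_start: bool = False) -> ScanResult:
    """V_A as a function of constant pulling force (nN), FMPES convention.

    The default grid steps the force by 0.5 nN up to 4.0 nN.  The pulled
    atoms default to the reactant's ``attachment_pair``.  A custom
    ``term_factory(F_nN) -> [terms]`` substitutes a different coupling (for
    instance a linear tilt on a 1-D benchmark surface).
    """
    grid = DEFAULT_FORCE_GRID_NN if grid is None else tuple(grid)
    if term_factory is None:
        pair = attachment_pair or reactant.attachment_pair
        if pair is None:
            raise ScanError("scan_pulling_force needs an attachment_pair")
        term_factory = lambda f: [PullingForce(f, pair)]  # noqa: E731
    return run_scan(reactant, ts_guess, pes_base, term_factory, grid, "nN",
                    settings, cold_start, metadata={"scan": "pulling_force"})


def scan_uniaxial_k(reactant: Geometry, ts_guess: Optional[Geometry],
                    pes_base: PotentialBackend,
                    grid: Optional[Iterable[float]] = None,
                    settings: Optional[OptimizationSettings] = None,
                    align: str = "auto",
                    cold_start: bool = False) -> ScanResult:
    """V_A as a function of the uniaxial compression force constant (N m⁻¹).

    Structures are aligned into the compression frame once at the start and
    the frame is held fixed across the scan.  ``align`` is an
    :func:`~mechpes.geometry.align_to_frame` mode, or ``"auto"``:
    attachment_in_plane when the reactant has an attachment pair, else
    principal_axes.
    """
    grid = DEFAULT_K_GRID_NPM if grid is None else tuple(grid)
    mode = align
    if mode == "auto":
        mode = ("attachment_in_plane" if reactant.attachment_pair is not None
                else "principal_axes")
    if pes_base.molecular and mode != "none":
        reactant = align_to_frame(reactant, mode)
        if ts_guess is not None:
            ts_guess = align_to_frame(ts_guess, mode)
    result = run_scan(reactant, ts_guess, pes_base,
                      lambda k: [UniaxialCompression(k)], grid, "N/m",
                      settings, cold_start,
                      metadata={"scan": "uniaxial_k", "alignment": mode})
    return result
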