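"""Deterministic toy-geometry fixtures with oracle sidecars.

Each fixture is a geometry plus a dict of reference values computed from
the package's own closed forms, so demos and smoke tests can verify
themselves.  ``seed`` controls an optional Gaussian jitter of the
coordinates (useful for starting optimizations off the exact reference
structure); ``jitter=0`` gives the pristine geometry.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from .backends import BeadSpringFlex, HarmonicDiatomic
from .external import uniaxial_energy
from .geometry import Geometry
from .units import HARTREE_TO_KCALMOL

FIXTURE_NAMES = ("bead_spring_flex_reactant", "bead_spring_flex_ts_guess",
                 "two_atom_dimer", "planar_ring")


def generate_fixture(name: str, params: Optional[dict] = None,
                     seed: int = 0) -> Tuple[Geometry, Dict]:
    """Return ``(geometry, expected_values)`` for a named fixture.

    Unknown names raise with the list of available fixtures.  Identical
    ``(name, params, seed)`` always produce identical output.
    """
    params = dict(params or {})
    jitter = float(params.pop("jitter", 0.0))
    rng = np.random.default_rng(seed)

    if name == "bead_spring_flex_reactant":
        backend = BeadSpringFlex(**params)
        geom = backend.reference_reactant()
        sidecar = {
            "backend": backend.name,
            "closed_form_barrier_kcal": backend.barrier * HARTREE_TO_KCALMOL,
            "reactant_well_hartree": -backend.barrier,
        }
    elif name == "bead_spring_flex_ts_guess":
        backend = BeadSpringFlex(**params)
        geom = backend.reference_ts_guess()
        sidecar = {
            "backend": backend.name,
            "ts_energy_hartree": 0.0,  # all terms relax to zero at the saddle
            "closed_form_barrier_kcal": backend.barrier * HARTREE_TO_KCALMOL,
        }
    elif name == "two_atom_dimer":
        backend = HarmonicDiatomic(**params)
        geom = backend.reference_geometry(axis=2)
        k_probe = 50.0
        sidecar = {
            "backend": backend.name,
            "uniaxial_energy_kcal_at_50Nm": uniaxial_energy(geom, k_probe),
            "compressed_bond_length_bohr_at_50Nm": backend.compressed_bond_length(k_probe),
            "compressed_energy_hartree_at_50Nm": backend.compressed_energy(k_probe),
        }
    elif name == "planar_ring":
        n = int(params.pop("n_atoms", 6))
        radius = float(params.pop("radius", 1.4))
        angles = 2.0 * math.pi * np.arange(n) / n
        coords = np.column_stack([radius * np.cos(angles),
                                  radius * np.sin(angles),
                                  np.zeros(n)])
        geom = Geometry(("C",) * n, coords, comment=f"planar ring n={n}")
        sidecar = {"uniaxial_energy_kcal_at_any_k": 0.0}
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")

    if jitter > 0.0:
        geom = geom.with_coords(geom.coords + jitter * rng.standard_normal(geom.coords.shape))
    return geom, sidecar
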