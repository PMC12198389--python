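"""External mechanical perturbations and the force-modified PES.

Two perturbations are provided:

* :class:`UniaxialCompression` — the generalized-FMPES harmonic compression
  potential V_ext = (k/2) Σᵢ zᵢ², pressing every atom towards the xy-plane
  of the working frame; k is given in N m⁻¹ and converted to hartree/bohr²
  internally.  The external force on atom i is its negative derivative,
  (0, 0, −k·zᵢ).
* :class:`PullingForce` — the constant-force FMPES (EFEI) convention: a
  collinear force pair of magnitude F across the two attachment atoms with
  energy −F·d, d being the instantaneous attachment-pair distance.

:class:`ModifiedPES` composes a base backend with any number of such terms
additively; the result satisfies the :class:`~mechpes.backends.PotentialBackend`
contract and is accepted by every optimizer and scan driver.

A :class:`LinearTilt` term (−F·xᵢ on one coordinate of one atom) is included
for the 1-D benchmark surfaces, where a constant pulling force reduces to a
linear tilt of the well.
"""

from __future__ import annotations

import abc
from typing import Optional, Sequence, Tuple

import numpy as np

from .backends import PotentialBackend, RIGID_MODES, fd_gradient
from .geometry import Geometry
from .units import (ANGSTROM_TO_BOHR, HARTREE_TO_KCALMOL, NEWTON_PER_METER_TO_AU,
                    NN_TO_AU_FORCE)


class ExternalTerm(abc.ABC):
    """An additive external-energy term on internal coordinates."""

    label: str = "term"

    @abc.abstractmethod
    def energy(self, x: np.ndarray) -> float:
        """Term energy (hartree) on flat internal coordinates."""

    @abc.abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Flat analytic gradient (hartree / internal length)."""

    def invariances(self) -> frozenset:
        """Rigid motions the term preserves (intersected into the PES)."""
        return RIGID_MODES


class UniaxialCompression(ExternalTerm):
    """Harmonic uniaxial compression towards the xy-plane.

    Parameters
    ----------
    k : float
        Compression force constant in N m⁻¹ (must be ≥ 0).
    """

    def __init__(self, k: float):
        if k < 0:
            raise ValueError(f"compression force constant must be non-negative, got {k}")
        self.k = float(k)
        self.k_au = self.k * NEWTON_PER_METER_TO_AU
        self.label = f"uniaxial(k={self.k:g}N/m)"

    def energy(self, x: np.ndarray) -> float:
        z = np.asarray(x).reshape(-1, 3)[:, 2]
        return 0.5 * self.k_au * float(np.sum(z * z))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(np.asarray(x, dtype=float))
        g[2::3] = self.k_au * np.asarray(x)[2::3]
        return g

    def force(self, x: np.ndarray) -> np.ndarray:
        """External force −∂V/∂r: (0, 0, −k·zᵢ) on each atom, a.u."""
        return -self.gradient(x).reshape(-1, 3)

    def invariances(self) -> frozenset:
        # xy-translations and rotation about z survive; z-motion does not
        # (k = 0 is zero coupling: every rigid motion survives)
        if self.k == 0.0:
            return RIGID_MODES
        return frozenset({"tx", "ty", "rz"})


class PullingForce(ExternalTerm):
    """Constant collinear pulling-force pair across the attachment atoms.

    Energy −F·d with d the attachment-pair distance; the gradient has
    support only on the two attachment atoms and is antiparallel along
    their connecting vector (each atom pulled outward with magnitude F).

    Parameters
    ----------
    magnitude : float
        Force in nN (must be ≥ 0).
    attachment_pair : (int, int)
        0-based indices of the two pulled atoms.
    """

    MIN_SEPARATION_BOHR = 1e-6 * ANGSTROM_TO_BOHR

    def __init__(self, magnitude: float, attachment_pair: Tuple[int, int]):
        if magnitude < 0:
            raise ValueError(f"pulling force must be non-negative, got {magnitude}")
        i, j = (int(v) for v in attachment_pair)
        if i == j:
            raise ValueError("attachment_pair must name two distinct atoms")
        self.magnitude = float(magnitude)
        self.f_au = self.magnitude * NN_TO_AU_FORCE
        self.pair = (i, j)
        self.label = f"pulling(F={self.magnitude:g}nN,pair={i}-{j})"

    def _separation(self, x: np.ndarray):
        r = np.asarray(x).reshape(-1, 3)
        i, j = self.pair
        v = r[i] - r[j]
        d = float(np.linalg.norm(v))
        if d < self.MIN_SEPARATION_BOHR:
            raise ValueError(
                f"attachment atoms {self.pair} coincide (d={d:.2e} bohr); "
                "pulling direction undefined"
            )
        return v, d

    def energy(self, x: np.ndarray) -> float:
        _, d = self._separation(x)
        return -self.f_au * d

    def gradient(self, x: np.ndarray) -> np.ndarray:
        v, d = self._separation(x)
        g = np.zeros_like(np.asarray(x, dtype=float)).reshape(-1, 3)
        i, j = self.pair
        u = v / d
        g[i] = -self.f_au * u
        g[j] = +self.f_au * u
        return g.ravel()

    def invariances(self) -> frozenset:
        # −F·d depends only on an interatomic distance: fully rigid-invariant
        return RIGID_MODES


class LinearTilt(ExternalTerm):
    """−F·x on a single coordinate — the 1-D limit of a pulling force."""

    def __init__(self, f_au: float, atom: int = 0, axis: int = 0):
        self.f_au = float(f_au)
        self.atom = int(atom)
        self.axis = int(axis)
        self.label = f"tilt(F={self.f_au:g}au,atom={self.atom},axis={self.axis})"

    def energy(self, x: np.ndarray) -> float:
        return -self.f_au * float(np.asarray(x)[3 * self.atom + self.axis])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(np.asarray(x, dtype=float))
        g[3 * self.atom + self.axis] = -self.f_au
        return g

    def invariances(self) -> frozenset:
        return frozenset()


class ModifiedPES(PotentialBackend):
    """Base backend plus additive external terms (the force-modified PES)."""

    def __init__(self, base: PotentialBackend, terms: Sequence[ExternalTerm] = ()):
        self.base = base
        self.terms = tuple(terms)
        self.molecular = base.molecular
        self.expected_atoms = base.expected_atoms
        self.analytic_gradient_available = base.analytic_gradient_available
        self.fd_grad_step = base.fd_grad_step
        self.fd_hess_step = base.fd_hess_step
        self.name = base.name + "".join(f"+{t.label}" for t in self.terms)

    def invariances(self) -> frozenset:
        inv = self.base.invariances()
        for t in self.terms:
            inv = inv & t.invariances()
        return inv

    def _energy(self, x: np.ndarray) -> float:
        e = self.base._energy(x)
        for t in self.terms:
            e += t.energy(x)
        return e

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        if self.base.analytic_gradient_available:
            g = np.asarray(self.base._gradient(x), dtype=float).copy()
        else:
            g = fd_gradient(self.base._energy, x, self.fd_grad_step)
        for t in self.terms:
            g = g + t.gradient(x)
        return g


def compose_modified_pes(base: PotentialBackend,
                         terms: Sequence[ExternalTerm] = ()) -> ModifiedPES:
    """Compose a base backend with external terms into a modified PES."""
    return ModifiedPES(base, terms)


# ---------------------------------------------------------------------------
# user-facing worked-value helpers (Å / nN / N m⁻¹ in, kcal mol⁻¹ out)
# ---------------------------------------------------------------------------

def uniaxial_energy(geom: Geometry, k: float) -> float:
    """Compression energy (k/2)·Σ zᵢ² in kcal mol⁻¹ for k in N m⁻¹, z in Å."""
    term = UniaxialCompression(k)
    x = np.asarray(geom.coords, dtype=float).ravel() * ANGSTROM_TO_BOHR
    return term.energy(x) * HARTREE_TO_KCALMOL


def uniaxial_force(geom: Geometry, k: float) -> np.ndarray:
    """External compression force (0, 0, −k·zᵢ) per atom in a.u."""
    term = UniaxialCompression(k)
    x = np.asarray(geom.coords, dtype=float).ravel() * ANGSTROM_TO_BOHR
    return term.force(x)


def pulling_energy(geom: Geometry, magnitude: float,
                   attachment_pair: Optional[Tuple[int, int]] = None) -> float:
    """Pulling energy −F·d in kcal mol⁻¹ for F in nN and d in Å."""
    pair = attachment_pair if attachment_pair is not None else geom.attachment_pair
    if pair is None:
        raise ValueError("pulling_energy needs an attachment_pair")
    term = PullingForce(magnitude, pair)
    x = np.asarray(geom.coords, dtype=float).ravel() * ANGSTROM_TO_BOHR
    return term.energy(x) * HARTREE_TO_KCALMOL
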