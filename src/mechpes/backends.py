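"""Base-potential backend contract and built-in analytic surfaces.

A :class:`PotentialBackend` supplies the unperturbed ("Born–Oppenheimer")
energy and gradient of a geometry.  In production use this is an external
electronic-structure engine wrapped to this contract; the package ships
three analytic surfaces so that every optimizer, scan driver and test runs
self-contained at desk scale:

* :class:`QuarticDoubleWell` — V(x) = a·x⁴ − b·x², the textbook 1-D barrier
  with closed-form minima, saddle and barrier height b²/(4a).
* :class:`MullerBrown` — the standard 2-D optimizer benchmark with three
  minima and two first-order saddles.
* :class:`BeadSpringFlex` — a 3-D four-bead "flex mechanophore": harmonic
  bonds and angles plus one reactive bond whose cleavage is coupled to the
  tilt of the payload bead, so that uniaxial compression lowers the barrier
  while in-plane pulling barely touches it.

Internally everything is in Hartree atomic units.  Molecular backends
(``molecular=True``) read geometry coordinates as Å and convert to bohr;
the low-dimensional benchmark surfaces are "pseudo-atom" systems whose
coordinate values are used as-is (already in model/atomic units) with the
unused components ignored — gradients along them are exactly zero.
"""

from __future__ import annotations

import abc
import math
from typing import Callable, Optional

import numpy as np

from .geometry import Geometry
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

RIGID_MODES = frozenset({"tx", "ty", "tz", "rx", "ry", "rz"})


class BackendError(RuntimeError):
    """Raised for backend/geometry mismatches or non-finite energies."""


# ---------------------------------------------------------------------------
# finite-difference fallbacks (internal coordinates)
# ---------------------------------------------------------------------------

def fd_gradient(energy: Callable[[np.ndarray], float], x: np.ndarray,
                step: float = 1e-4) -> np.ndarray:
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        g[i] = (energy(xp) - energy(xm)) / (2.0 * step)
    return g


def fd_hessian(gradient: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
               step: float = 1e-3) -> np.ndarray:
    """Central finite differences of a gradient; symmetrized on return."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.empty((n, n))
    for i in range(n):
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        h[:, i] = (gradient(xp) - gradient(xm)) / (2.0 * step)
    return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# backend contract
# ---------------------------------------------------------------------------

class PotentialBackend(abc.ABC):
    """Energy/gradient contract every optimizer in the package consumes.

    Subclasses implement ``_energy`` (and optionally ``_gradient`` /
    ``_hessian``) on the flat internal coordinate vector.  Missing
    derivatives fall back to central finite differences (gradient step
    ``fd_grad_step``, Hessian step ``fd_hess_step``, internal units).
    """

    name: str = "backend"
    molecular: bool = True
    analytic_gradient_available: bool = False
    expected_atoms: Optional[int] = None
    fd_grad_step: float = 1e-4
    fd_hess_step: float = 1e-3

    # -- geometry plumbing ---------------------------------------------------
    def invariances(self) -> frozenset:
        """Rigid motions that leave the energy unchanged."""
        return RIGID_MODES if self.molecular else frozenset()

    def validate(self, geom: Geometry) -> None:
        if self.expected_atoms is not None and geom.n_atoms != self.expected_atoms:
            raise BackendError(
                f"backend {self.name!r} expects {self.expected_atoms} atom(s); "
                f"geometry has shape ({geom.n_atoms}, 3)"
            )

    def to_internal(self, geom: Geometry) -> np.ndarray:
        """Flat internal coordinates (bohr for molecular backends)."""
        self.validate(geom)
        x = np.array(geom.coords, dtype=float).ravel()
        return x * ANGSTROM_TO_BOHR if self.molecular else x

    def geometry_with_internal(self, geom: Geometry, x: np.ndarray) -> Geometry:
        coords = np.reshape(np.asarray(x, dtype=float), (-1, 3))
        if self.molecular:
            coords = coords * BOHR_TO_ANGSTROM
        return geom.with_coords(coords)

    # -- public evaluation ---------------------------------------------------
    def energy(self, geom: Geometry) -> float:
        """Energy in hartree."""
        e = float(self._energy(self.to_internal(geom)))
        if not math.isfinite(e):
            raise BackendError(f"backend {self.name!r} returned non-finite energy {e!r}")
        return e

    def gradient(self, geom: Geometry) -> np.ndarray:
        """(N, 3) gradient in hartree per internal length unit."""
        return np.asarray(self._gradient(self.to_internal(geom))).reshape(-1, 3)

    def hessian(self, geom: Geometry) -> np.ndarray:
        """(3N, 3N) symmetric Hessian in internal units."""
        h = np.asarray(self._hessian(self.to_internal(geom)))
        return 0.5 * (h + h.T)

    # -- internal contract ---------------------------------------------------
    @abc.abstractmethod
    def _energy(self, x: np.ndarray) -> float:
        ...

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        return fd_gradient(self._energy, x, self.fd_grad_step)

    def _hessian(self, x: np.ndarray) -> np.ndarray:
        return fd_hessian(self._gradient, x, self.fd_hess_step)


# module-level operation surface -------------------------------------------

def evaluate_energy(geom: Geometry, backend: PotentialBackend) -> float:
    return backend.energy(geom)


def evaluate_gradient(geom: Geometry, backend: PotentialBackend) -> np.ndarray:
    return backend.gradient(geom)


def evaluate_hessian(geom: Geometry, backend: PotentialBackend) -> np.ndarray:
    return backend.hessian(geom)


# ---------------------------------------------------------------------------
# built-in analytic surfaces
# ---------------------------------------------------------------------------

class QuarticDoubleWell(PotentialBackend):
    """V(x) = a·x⁴ − b·x² on the x-coordinate of a single pseudo-atom.

    Minima at x = ±sqrt(b/2a), saddle at x = 0, barrier b²/(4a).  y and z
    are ignored (zero gradient).  Coordinates and energies are atomic units.
    """

    molecular = False
    analytic_gradient_available = True
    expected_atoms = 1

    def __init__(self, a: float = 1.0, b: float = 2.0):
        if a <= 0:
            raise ValueError("quartic coefficient a must be positive")
        self.a = float(a)
        self.b = float(b)
        self.name = f"quartic_double_well(a={self.a:g},b={self.b:g})"

    @property
    def minimum_x(self) -> float:
        return math.sqrt(self.b / (2.0 * self.a))

    @property
    def barrier(self) -> float:
        """Closed-form barrier V(0) − V(±x_min) = b²/(4a) in hartree."""
        return self.b**2 / (4.0 * self.a)

    def _energy(self, x: np.ndarray) -> float:
        v = x[0]
        return self.a * v**4 - self.b * v**2

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(3)
        g[0] = 4.0 * self.a * x[0] ** 3 - 2.0 * self.b * x[0]
        return g

    def _hessian(self, x: np.ndarray) -> np.ndarray:
        h = np.zeros((3, 3))
        h[0, 0] = 12.0 * self.a * x[0] ** 2 - 2.0 * self.b
        return h

    def geometry(self, x: float) -> Geometry:
        return Geometry(("X",), np.array([[x, 0.0, 0.0]]))


class MullerBrown(PotentialBackend):
    """The Müller–Brown 2-D benchmark surface (one pseudo-atom, x–y plane).

    Sum of four Gaussians with the standard constants; three minima and two
    first-order saddle points.  z is ignored.
    """

    molecular = False
    analytic_gradient_available = True
    expected_atoms = 1
    name = "muller_brown"

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, x: float, y: float) -> np.ndarray:
        dx = x - self.x0
        dy = y - self.y0
        return self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2)

    def _energy(self, xvec: np.ndarray) -> float:
        return float(np.sum(self._terms(xvec[0], xvec[1])))

    def _gradient(self, xvec: np.ndarray) -> np.ndarray:
        x, y = xvec[0], xvec[1]
        t = self._terms(x, y)
        dx = x - self.x0
        dy = y - self.y0
        g = np.zeros(3)
        g[0] = float(np.sum(t * (2.0 * self.a * dx + self.b * dy)))
        g[1] = float(np.sum(t * (self.b * dx + 2.0 * self.c * dy)))
        return g

    def geometry(self, x: float, y: float) -> Geometry:
        return Geometry(("X",), np.array([[x, y, 0.0]]))


class BeadSpringFlex(PotentialBackend):
    """Five-bead flex-mechanophore toy with an angle-coupled reactive bond.

    Atoms 0–1–2 (A–B–C) form a bent scaffold lying in the xy-plane; the
    polymer attachment points are A and C.  Atom 3 (D, the payload) is bound
    to B by the reactive bond, pointing out of the scaffold plane.  Atom 4
    (E) is an in-plane anchor arm on B opposite the scaffold bulge; its only
    job is to give the planar scaffold enough lateral extent that the
    molecule cannot evade uniaxial compression by rigidly rotating the
    payload into the plane (the escape the monofunctional control enjoys).

    Energy terms (hartree, bohr internally)::

        V = k_bond/2 [(r_AB − r0)² + (r_BC − r0)² + (r_BE − r_e)²]
          + k_angle/2 [(cos θ_ABC − cos θ0)²
                       + (cos φ_ABE − cos φ0)² + (cos φ_CBE − cos φ0)²]
          + a q⁴ − b q²                                  (q = r_BD − r_ref)
          + k_orient/2 [(cos ω₁ − c0(q))² + (cos ω₂ − c0(q))²]
          + k_improper/2 (cos χ − c0(q)/cos(θ0/2))²

    where ω₁ = ∠(A,B,D), ω₂ = ∠(C,B,D), χ = ∠(D,B,E) fix the payload (and
    arm) orientation, and the
    equilibrium tilt target c0(q) switches smoothly (logistic in q) from a
    nearly-upright payload in the reactant to a strongly tilted, almost
    in-plane payload at the transition state.  Consequences by construction:

    * the bare barrier is the closed form b²/(4a) (all other terms relax to
      zero at both stationary points);
    * in-plane pulling across A–C deforms only in-plane coordinates, which
      the payload-tilt terms barely sense — V_A(F) is nearly flat;
    * uniaxial z-compression penalizes the upright reactant payload far more
      than the already-tilted transition state — V_A(k) decreases with k.

    The analytic gradient is generated symbolically (sympy) once per
    parameter set and cached.
    """

    molecular = True
    analytic_gradient_available = True
    expected_atoms = 5
    name = "bead_spring_flex"

    #: default geometry parameters (Å / degrees)
    R0_ANG = 1.5          # scaffold bond length
    R_ARM_ANG = 2.2       # anchor-arm bond length
    THETA0_DEG = 150.0    # scaffold angle at B
    R_REACT_ANG = 1.4     # reactant B–D bond length
    R_REF_ANG = 1.9       # reactive-bond reference (TS) length
    TILT_REACTANT_DEG = 15.0
    TILT_TS_DEG = 75.0

    def __init__(self, k_bond: float = 0.3, k_angle: float = 1.0,
                 k_orient: float = 0.3, k_improper: float = 0.05,
                 a: float = 0.07, b: float = 0.125, gamma: float = 8.0):
        self.k_bond = float(k_bond)
        self.k_angle = float(k_angle)
        self.k_orient = float(k_orient)
        self.k_improper = float(k_improper)
        self.a = float(a)
        self.b = float(b)
        self.gamma = float(gamma)
        self.r0 = self.R0_ANG * ANGSTROM_TO_BOHR
        self.r_arm = self.R_ARM_ANG * ANGSTROM_TO_BOHR
        self.r_ref = self.R_REF_ANG * ANGSTROM_TO_BOHR
        self.cos_theta0 = math.cos(math.radians(self.THETA0_DEG))
        # arm along the interior bisector: cos φ0 = BA·BE/(r0·r_e) = cos(θ0/2)
        self.cos_phi0 = math.cos(math.radians(self.THETA0_DEG / 2.0))
        # payload tilt targets expressed as cos ω; sin(θ0/2-complement)
        # factor h/r0 = cos(θ0/2) projects the tilt onto the scaffold bonds
        h_over_r = math.cos(math.radians(self.THETA0_DEG / 2.0))
        self.c_reactant = h_over_r * math.sin(math.radians(self.TILT_REACTANT_DEG))
        self.c_ts = h_over_r * math.sin(math.radians(self.TILT_TS_DEG))
        # logistic switch midway between reactant q and TS q=0
        self.q_mid = -0.5 * math.sqrt(self.b / (2.0 * self.a))
        self._funcs = None

    # -- reference structures ------------------------------------------------
    @property
    def barrier(self) -> float:
        """Unperturbed closed-form barrier b²/(4a) in hartree."""
        return self.b**2 / (4.0 * self.a)

    def _scaffold(self):
        half = math.radians(self.THETA0_DEG / 2.0)
        d = self.R0_ANG * math.sin(half)
        h = self.R0_ANG * math.cos(half)
        return d, h

    def _reference(self, tilt_deg: float, r_bd: float, comment: str) -> Geometry:
        d, h = self._scaffold()
        tilt = math.radians(tilt_deg)
        coords = np.array([
            [-d, 0.0, 0.0],
            [0.0, h, 0.0],
            [d, 0.0, 0.0],
            [0.0, h - r_bd * math.sin(tilt), r_bd * math.cos(tilt)],
            [0.0, h - self.R_ARM_ANG, 0.0],
        ])
        return Geometry(("C", "C", "C", "O", "N"), coords, attachment_pair=(0, 2),
                        comment=comment)

    def reference_reactant(self) -> Geometry:
        """Starting guess near the reactant minimum (payload upright)."""
        return self._reference(self.TILT_REACTANT_DEG, self.R_REACT_ANG,
                               "bead_spring_flex reactant guess")

    def reference_ts_guess(self) -> Geometry:
        """Starting guess near the saddle (stretched, tilted payload)."""
        return self._reference(self.TILT_TS_DEG, self.R_REF_ANG,
                               "bead_spring_flex ts guess")

    # -- symbolic energy/gradient -------------------------------------------
    def _build(self):
        import sympy as sp

        xs = sp.symbols("x0:15")
        A = sp.Matrix(xs[0:3])
        B = sp.Matrix(xs[3:6])
        C = sp.Matrix(xs[6:9])
        D = sp.Matrix(xs[9:12])
        E = sp.Matrix(xs[12:15])
        rba, rbc, rbd, rbe = A - B, C - B, D - B, E - B
        r1 = sp.sqrt(rba.dot(rba))
        r2 = sp.sqrt(rbc.dot(rbc))
        rd = sp.sqrt(rbd.dot(rbd))
        re = sp.sqrt(rbe.dot(rbe))
        cos_t = rba.dot(rbc) / (r1 * r2)
        cos_w1 = rba.dot(rbd) / (r1 * rd)
        cos_w2 = rbc.dot(rbd) / (r2 * rd)
        cos_p1 = rba.dot(rbe) / (r1 * re)
        cos_p2 = rbc.dot(rbe) / (r2 * re)
        cos_chi = rbd.dot(rbe) / (rd * re)
        q = rd - self.r_ref
        sig = 1 / (1 + sp.exp(-self.gamma * (q - self.q_mid)))
        c0 = self.c_reactant + (self.c_ts - self.c_reactant) * sig
        # χ = ∠(D,B,E) pins the arm against out-of-plane flapping (bonds and
        # in-plane angles are only quartic in z_E); its target follows the
        # same payload-tilt path as the ω terms: cos χ = sin ψ = c0/cos(θ0/2)
        chi0 = c0 / math.cos(math.radians(self.THETA0_DEG / 2.0))
        v = (self.k_bond / 2 * ((r1 - self.r0) ** 2 + (r2 - self.r0) ** 2
                                + (re - self.r_arm) ** 2)
             + self.k_angle / 2 * ((cos_t - self.cos_theta0) ** 2
                                   + (cos_p1 - self.cos_phi0) ** 2
                                   + (cos_p2 - self.cos_phi0) ** 2)
             + self.a * q**4 - self.b * q**2
             + self.k_orient / 2 * ((cos_w1 - c0) ** 2 + (cos_w2 - c0) ** 2)
             + self.k_improper / 2 * (cos_chi - chi0) ** 2)
        grad = [sp.diff(v, x) for x in xs]
        f_e = sp.lambdify(xs, v, modules="math", cse=True)
        f_g = sp.lambdify(xs, grad, modules="math", cse=True)
        return f_e, f_g

    def _ensure(self):
        if self._funcs is None:
            self._funcs = self._build()
        return self._funcs

    def _energy(self, x: np.ndarray) -> float:
        f_e, _ = self._ensure()
        return float(f_e(*x))

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        _, f_g = self._ensure()
        return np.array(f_g(*x), dtype=float)


class HarmonicDiatomic(PotentialBackend):
    """Two beads with a single harmonic bond, V = k_bond/2 (r − r0)².

    Oriented along z under uniaxial compression k this has a closed-form
    minimum: with the centroid pinned to the plane, the bond contracts to
    r* = k_bond·r0 / (k_bond + k/2).
    """

    molecular = True
    analytic_gradient_available = True
    expected_atoms = 2

    def __init__(self, k_bond: float = 0.5, r0_angstrom: float = 2.0):
        self.k_bond = float(k_bond)
        self.r0 = float(r0_angstrom) * ANGSTROM_TO_BOHR
        self.name = f"harmonic_diatomic(k={self.k_bond:g},r0={r0_angstrom:g}A)"

    def reference_geometry(self, axis: int = 2) -> Geometry:
        coords = np.zeros((2, 3))
        half = 0.5 * self.r0 * BOHR_TO_ANGSTROM
        coords[0, axis] = +half
        coords[1, axis] = -half
        return Geometry(("H", "H"), coords, attachment_pair=(0, 1))

    def compressed_bond_length(self, k_npm: float) -> float:
        """Closed-form equilibrium bond length (bohr) under compression
        along the bond axis with the centroid in the plane."""
        from .units import NEWTON_PER_METER_TO_AU
        k_au = k_npm * NEWTON_PER_METER_TO_AU
        return self.k_bond * self.r0 / (self.k_bond + 0.5 * k_au)

    def compressed_energy(self, k_npm: float) -> float:
        """Closed-form minimum energy (hartree) of bond + compression."""
        from .units import NEWTON_PER_METER_TO_AU
        k_au = k_npm * NEWTON_PER_METER_TO_AU
        r = self.compressed_bond_length(k_npm)
        return 0.5 * self.k_bond * (r - self.r0) ** 2 + 0.25 * k_au * r**2

    def _energy(self, x: np.ndarray) -> float:
        r = np.reshape(x, (2, 3))
        d = float(np.linalg.norm(r[0] - r[1]))
        return 0.5 * self.k_bond * (d - self.r0) ** 2

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        r = np.reshape(x, (2, 3))
        v = r[0] - r[1]
        d = float(np.linalg.norm(v))
        g = np.zeros((2, 3))
        if d > 1e-14:
            u = v / d
            g[0] = self.k_bond * (d - self.r0) * u
            g[1] = -g[0]
        return g.ravel()
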