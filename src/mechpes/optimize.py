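"""Location and characterization of stationary points.

Minima are found with a BFGS quasi-Newton minimizer (Wolfe line search,
max-gradient-component convergence criterion, default 1.0e-4 a.u.).
First-order saddle points are found with the dimer method: two closely
spaced replicas estimate the lowest-curvature mode, the dimer is rotated
into it (Fourier-interpolated rotation), and the translation follows the
force with the component along the mode inverted, stepped by a
conjugate-gradient walker with a Newton-on-force line step.

Converged points are characterized by the eigenvalues of the Hessian:
positive definite (after removing zero modes) → minimum; exactly one
negative eigenvalue → first-order saddle.  Zero modes are projected out
according to the rigid-motion invariances the active PES actually has —
all six for an unperturbed molecular backend, only xy-translations and the
z-rotation once the uniaxial compression term is active — and any residual
eigenvalue below the curvature tolerance is likewise excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .backends import PotentialBackend
from .geometry import Geometry


class NotAStationaryPointError(ValueError):
    """classify() was handed a point with a clearly nonzero gradient."""


@dataclass
class OptimizationSettings:
    """Knobs shared by the minimizer and the dimer search.

    gradient_convergence is the max-component threshold on the gradient in
    atomic units; 1.0e-4 a.u. is the production default.  zero_mode_tol is
    the curvature magnitude below which a Hessian eigenvalue is treated as
    a zero mode.  The dimer fields follow the standard formulation: image
    separation (bohr), rotational-force convergence and a cap on rotations
    per translation step; ``seed`` feeds the random initial dimer
    orientation used when no Hessian-based orientation is requested.
    """

    gradient_convergence: float = 1.0e-4
    max_steps: int = 1000
    max_step_size: float = 0.3
    seed: int = 0
    zero_mode_tol: float = 1.0e-6
    characterize: bool = True
    # dimer hyperparameters
    dimer_separation: float = 1.0e-3
    dimer_rotation_tol: float = 1.0e-4
    dimer_max_rotations: int = 15
    dimer_trial_step: float = 1.0e-2
    dimer_init: str = "hessian"  # or "random"

    def __post_init__(self):
        if self.gradient_convergence <= 0:
            raise ValueError("gradient_convergence must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be at least 1")


@dataclass
class StationaryPoint:
    """A converged (or honestly-flagged unconverged) optimization result."""

    geometry: Geometry
    energy: float  # hartree
    classification: str  # "minimum" | "first_order_saddle" | "other"
    hessian_eigenvalues: Optional[np.ndarray]
    converged: bool
    n_steps: int
    max_grad: float
    pes_name: str
    message: str = ""


# ---------------------------------------------------------------------------
# frozen-coordinate bookkeeping
# ---------------------------------------------------------------------------

class _Space:
    """Maps between the full internal vector and the free sub-vector."""

    def __init__(self, x0: np.ndarray, geom: Geometry):
        self.x0 = np.asarray(x0, dtype=float).copy()
        if geom.frozen_mask is not None:
            free_atoms = ~geom.frozen_mask
            self.free = np.repeat(free_atoms, 3)
        else:
            self.free = np.ones(self.x0.size, dtype=bool)

    def pack(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[self.free]

    def unpack(self, xf: np.ndarray) -> np.ndarray:
        x = self.x0.copy()
        x[self.free] = xf
        return x


# ---------------------------------------------------------------------------
# rigid-mode projection and classification
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def rigid_mode_basis(x: np.ndarray, invariances: frozenset) -> np.ndarray:
    """Orthonormal basis (3N, m) of the rigid modes the PES preserves."""
    r = np.asarray(x, dtype=float).reshape(-1, 3)
    n = r.shape[0]
    modes: List[np.ndarray] = []
    for name, ax in _AXES.items():
        if f"t{name}" in invariances:
            v = np.zeros((n, 3))
            v[:, ax] = 1.0
            modes.append(v.ravel())
    centered = r - r.mean(axis=0)
    for name, ax in _AXES.items():
        if f"r{name}" in invariances:
            e = np.zeros(3)
            e[ax] = 1.0
            v = np.cross(np.broadcast_to(e, centered.shape), centered)
            if np.linalg.norm(v) > 1e-10:  # vanishes for linear molecules
                modes.append(v.ravel())
    if not modes:
        return np.zeros((3 * n, 0))
    q, rdiag = np.linalg.qr(np.column_stack(modes))
    keep = np.abs(np.diag(rdiag)) > 1e-10
    return q[:, keep]


def reduced_hessian_eigenvalues(hess: np.ndarray, x: np.ndarray,
                                invariances: frozenset) -> np.ndarray:
    """Eigenvalues of the Hessian restricted to the non-rigid subspace."""
    q = rigid_mode_basis(x, invariances)
    if q.shape[1] == 0:
        return np.linalg.eigvalsh(hess)
    u, _, _ = np.linalg.svd(q, full_matrices=True)
    comp = u[:, q.shape[1]:]
    return np.linalg.eigvalsh(comp.T @ hess @ comp)


def _characterize(x: np.ndarray, pes: PotentialBackend,
                  zero_mode_tol: float, max_grad: float = 0.0) -> Tuple[str, np.ndarray]:
    hess = np.asarray(pes._hessian(x))
    hess = 0.5 * (hess + hess.T)
    full_eigs = np.sort(np.linalg.eigvalsh(hess))
    red = reduced_hessian_eigenvalues(hess, x, pes.invariances())
    # eigenvalues below the residual-gradient scale are not resolvable at
    # the achieved convergence; treat them as zero modes
    tol = max(zero_mode_tol, max_grad)
    n_neg = int(np.sum(red < -tol))
    if n_neg == 0:
        label = "minimum"
    elif n_neg == 1:
        label = "first_order_saddle"
    else:
        label = "other"
    return label, full_eigs


def classify(point: StationaryPoint, pes: PotentialBackend,
             settings: Optional[OptimizationSettings] = None) -> str:
    """Re-derive the Hessian-signature classification of a stationary point.

    Raises :class:`NotAStationaryPointError` when the gradient is more than
    ten times the convergence threshold — the eigenvalue signature is only
    meaningful at (near-)zero gradient.
    """
    settings = settings or OptimizationSettings()
    x = pes.to_internal(point.geometry)
    g = np.asarray(pes._gradient(x))
    max_g = float(np.max(np.abs(g)))
    if max_g > 10.0 * settings.gradient_convergence:
        raise NotAStationaryPointError(
            f"max gradient component {max_g:.3e} a.u. exceeds 10× the "
            f"threshold {settings.gradient_convergence:.1e}; not a stationary point"
        )
    label, eigs = _characterize(x, pes, settings.zero_mode_tol, max_g)
    point.classification = label
    point.hessian_eigenvalues = eigs
    return label


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(geom: Geometry, pes: PotentialBackend,
             settings: Optional[OptimizationSettings] = None,
             trajectory: Optional[list] = None) -> StationaryPoint:
    """Quasi-Newton (BFGS) minimization to max|g| ≤ gradient_convergence.

    Frozen atoms never move.  When ``trajectory`` is a list, the accepted
    iterates are appended to it as geometries.
    """
    settings = settings or OptimizationSettings()
    x0 = pes.to_internal(geom)
    space = _Space(x0, geom)

    def fun(xf):
        return pes._energy(space.unpack(xf))

    def jac(xf):
        return np.asarray(pes._gradient(space.unpack(xf)))[space.free]

    def callback(xf):
        if trajectory is not None:
            trajectory.append(pes.geometry_with_internal(geom, space.unpack(xf)))

    res = _scipy_minimize(
        fun, space.pack(x0), jac=jac, method="BFGS", callback=callback,
        options={"gtol": settings.gradient_convergence, "norm": np.inf,
                 "maxiter": settings.max_steps},
    )
    x = space.unpack(res.x)
    g_free = np.asarray(pes._gradient(x))[space.free]
    max_grad = float(np.max(np.abs(g_free))) if g_free.size else 0.0
    converged = max_grad <= settings.gradient_convergence
    label, eigs = ("other", None)
    if settings.characterize:
        label, eigs = _characterize(x, pes, settings.zero_mode_tol, max_grad)
    return StationaryPoint(
        geometry=pes.geometry_with_internal(geom, x),
        energy=float(pes._energy(x)),
        classification=label,
        hessian_eigenvalues=eigs,
        converged=converged,
        n_steps=int(res.nit),
        max_grad=max_grad,
        pes_name=pes.name,
        message="" if converged else f"minimization not converged: {res.message}",
    )


# ---------------------------------------------------------------------------
# dimer method
# ---------------------------------------------------------------------------

def _rotate_dimer(x: np.ndarray, g0: np.ndarray, tau: np.ndarray,
                  grad, settings: OptimizationSettings) -> Tuple[np.ndarray, float]:
    """Rotate the dimer into the lowest-curvature mode (Fourier scheme)."""
    dr = settings.dimer_separation
    curv = 0.0
    for _ in range(settings.dimer_max_rotations):
        g1 = grad(x + dr * tau)
        dg = g1 - g0
        curv = float(dg @ tau) / dr
        f_rot = -2.0 * (dg - (dg @ tau) * tau)
        rot_force = float(np.linalg.norm(f_rot)) / (2.0 * dr)  # |H τ|_⊥
        if rot_force < settings.dimer_rotation_tol:
            break
        theta = f_rot / np.linalg.norm(f_rot)
        dcurv = 2.0 * float(dg @ theta) / dr  # dC/dθ at θ=0 (always ≤ 0)
        # Fourier series C(θ) = c + a1 cos 2θ + b1 sin 2θ through two points
        b1 = 0.5 * dcurv
        phi_t = 0.25 * math.pi
        tau_t = tau * math.cos(phi_t) + theta * math.sin(phi_t)
        tau_t /= np.linalg.norm(tau_t)
        g1t = grad(x + dr * tau_t)
        curv_t = float((g1t - g0) @ tau_t) / dr
        a1 = (curv - curv_t + b1 * math.sin(2 * phi_t)) / (1 - math.cos(2 * phi_t))
        phi = 0.5 * math.atan2(b1, a1)
        if a1 * math.cos(2 * phi) + b1 * math.sin(2 * phi) > 0:
            phi += 0.5 * math.pi  # landed on the curvature maximum
        if abs(phi) < 1e-12:
            break
        tau = tau * math.cos(phi) + theta * math.sin(phi)
        tau /= np.linalg.norm(tau)
    return tau, curv


def _initial_orientation(x: np.ndarray, pes: PotentialBackend, space: _Space,
                         settings: OptimizationSettings) -> np.ndarray:
    if settings.dimer_init == "hessian":
        hess = np.asarray(pes._hessian(x))
        hess = 0.5 * (hess + hess.T)
        hf = hess[np.ix_(space.free, space.free)]
        _, vecs = np.linalg.eigh(hf)
        tau = vecs[:, 0]
    else:
        rng = np.random.default_rng(settings.seed)
        tau = rng.standard_normal(int(np.sum(space.free)))
    return tau / np.linalg.norm(tau)


def dimer_ts_search(geom: Geometry, pes: PotentialBackend,
                    settings: Optional[OptimizationSettings] = None,
                    trajectory: Optional[list] = None) -> StationaryPoint:
    """Dimer-method search for a first-order saddle point.

    Start from a geometry in the barrier region (for example the midpoint
    between reactant and product, or a stretched reactant).  The converged
    point is re-characterized via the Hessian; convergence to something
    other than a first-order saddle is reported honestly in
    ``classification`` and ``message`` rather than raised.
    """
    settings = settings or OptimizationSettings()
    x = pes.to_internal(geom)
    space = _Space(x, geom)

    def grad_full(xfull):
        return np.asarray(pes._gradient(xfull))

    def grad_free(xf):
        return grad_full(space.unpack(xf))[space.free]

    xf = space.pack(x)
    tau = _initial_orientation(x, pes, space, settings)

    def grad_free_at(v):
        return grad_full(space.unpack(v))[space.free]

    d_prev = None
    f_prev = None
    n_steps = 0
    max_grad = math.inf
    for n_steps in range(1, settings.max_steps + 1):
        g = grad_free_at(xf)
        max_grad = float(np.max(np.abs(g))) if g.size else 0.0
        if max_grad <= settings.gradient_convergence:
            break
        tau, curv = _rotate_dimer(xf, g, tau, grad_free_at, settings)
        f = -g
        if curv < 0:
            f_mod = f - 2.0 * (f @ tau) * tau
        else:
            f_mod = -(f @ tau) * tau
        # conjugate-gradient direction on the modified force
        if d_prev is None:
            d = f_mod
        else:
            beta = max(0.0, float(f_mod @ (f_mod - f_prev)) / float(f_prev @ f_prev))
            d = f_mod + beta * d_prev
            if float(d @ f_mod) <= 0:
                d = f_mod  # reset when the direction turns uphill
        d_prev, f_prev = d, f_mod
        dn = np.linalg.norm(d)
        if dn < 1e-14:
            break
        u = d / dn
        # Newton step on the force component along u
        delta = settings.dimer_trial_step
        f1 = float(f_mod @ u)
        g2 = grad_free_at(xf + delta * u)
        f2v = -g2
        if curv < 0:
            f2m = f2v - 2.0 * (f2v @ tau) * tau
        else:
            f2m = -(f2v @ tau) * tau
        f2 = float(f2m @ u)
        slope = (f1 - f2) / delta
        if slope > 1e-14:
            step = f1 / slope
        else:
            step = math.copysign(settings.max_step_size, f1)
        step = max(-settings.max_step_size, min(settings.max_step_size, step))
        xf = xf + step * u
        if trajectory is not None:
            trajectory.append(pes.geometry_with_internal(geom, space.unpack(xf)))

    x_final = space.unpack(xf)
    g_free = grad_free_at(xf)
    max_grad = float(np.max(np.abs(g_free))) if g_free.size else 0.0
    converged = max_grad <= settings.gradient_convergence
    label, eigs = ("other", None)
    if settings.characterize:
        label, eigs = _characterize(x_final, pes, settings.zero_mode_tol, max_grad)
    message = ""
    if not converged:
        message = f"dimer search not converged in {settings.max_steps} steps"
    elif label != "first_order_saddle":
        message = f"converged to a {label}, not a first-order saddle"
    return StationaryPoint(
        geometry=pes.geometry_with_internal(geom, x_final),
        energy=float(pes._energy(x_final)),
        classification=label,
        hessian_eigenvalues=eigs,
        converged=converged,
        n_steps=n_steps,
        max_grad=max_grad,
        pes_name=pes.name,
        message=message,
    )
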