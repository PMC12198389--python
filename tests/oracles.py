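"""Independent oracles used by the test suite.

These deliberately avoid the package's optimizers: stationary points are
located by dense grid search plus Newton polishing on finite-difference
derivatives, barriers of tilted double wells come from root-finding on the
cubic V'(x) = 0, and gradients are checked against (Richardson-extrapolated)
central differences computed here.
"""

from __future__ import annotations

import numpy as np


def fd_gradient_richardson(energy, x, step=1e-4):
    """Central differences at steps h and h/2, Richardson-combined (O(h⁴))."""
    x = np.asarray(x, dtype=float)

    def central(h):
        g = np.empty_like(x)
        for i in range(x.size):
            xp = x.copy(); xp[i] += h
            xm = x.copy(); xm[i] -= h
            g[i] = (energy(xp) - energy(xm)) / (2.0 * h)
        return g

    g1 = central(step)
    g2 = central(step / 2.0)
    return (4.0 * g2 - g1) / 3.0


def fd_hessian_of_energy(energy, x, step=1e-3):
    """Hessian from second central differences of the energy."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.empty((n, n))
    e0 = energy(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += step; xpp[j] += step
            xpm = x.copy(); xpm[i] += step; xpm[j] -= step
            xmp = x.copy(); xmp[i] -= step; xmp[j] += step
            xmm = x.copy(); xmm[i] -= step; xmm[j] -= step
            h[i, j] = h[j, i] = (energy(xpp) - energy(xpm) - energy(xmp)
                                 + energy(xmm)) / (4.0 * step**2)
    return h


def newton_polish_2d(energy, xy, steps=60):
    """Newton iteration on FD gradient/Hessian of a 2-D scalar function."""
    xy = np.asarray(xy, dtype=float)

    def e3(v):
        return energy(np.array([v[0], v[1]]))

    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(steps):
            if not np.all(np.isfinite(xy)) or np.max(np.abs(xy)) > 10.0:
                break
            g = fd_gradient_richardson(e3, xy, 1e-5)
            if not np.all(np.isfinite(g)):
                break
            h = fd_hessian_of_energy(e3, xy, 1e-4)
            try:
                delta = np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                break
            xy = xy - delta
            if np.max(np.abs(g)) < 1e-11:
                break
    return xy


def muller_brown_stationary_points(energy_xy):
    """All stationary points of a 2-D surface by grid scan + Newton polish.

    Returns (minima, saddles) as arrays of (x, y), sorted by x, classified
    by the FD Hessian eigenvalues at the polished points.
    """
    xs = np.linspace(-1.8, 1.2, 121)
    ys = np.linspace(-0.5, 2.3, 113)
    found = []
    # local minima of |grad| on the grid as candidates
    for x in xs[::4]:
        for y in ys[::4]:
            pt = newton_polish_2d(energy_xy, (x, y))
            if not (-2.0 < pt[0] < 1.5 and -1.0 < pt[1] < 2.5):
                continue
            g = fd_gradient_richardson(lambda v: energy_xy(v), pt, 1e-5)
            if np.max(np.abs(g)) > 1e-8:
                continue
            if not any(np.linalg.norm(pt - q) < 1e-4 for q, _ in found):
                h = fd_hessian_of_energy(lambda v: energy_xy(v), pt, 1e-4)
                eigs = np.linalg.eigvalsh(h)
                found.append((pt, eigs))
    minima = sorted((p for p, e in found if np.all(e > 0)), key=lambda p: p[0])
    saddles = sorted((p for p, e in found if e[0] < 0 < e[1]), key=lambda p: p[0])
    return np.array(minima), np.array(saddles)


def tilted_double_well_barrier(a, b, f):
    """Closed-form barrier of V(x) = a x⁴ − b x² − f x via the cubic roots.

    Returns (x_reactant, x_saddle, barrier): the reactant is the minimum at
    negative x (the well the force pulls away from), the saddle the middle
    root of V'(x) = 4a x³ − 2b x − f = 0.
    """
    roots = np.roots([4.0 * a, 0.0, -2.0 * b, -f])
    real = np.sort(roots[np.abs(roots.imag) < 1e-12].real)
    if real.size != 3:
        raise ValueError(f"force f={f} beyond the fold; wells merged")

    def v(x):
        return a * x**4 - b * x**2 - f * x

    x_reactant, x_saddle = real[0], real[1]
    return x_reactant, x_saddle, v(x_saddle) - v(x_reactant)
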