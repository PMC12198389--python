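# Methods

## Scope and model

`mechpes` implements mechanics on force-modified potential energy surfaces
(PES).  A base potential V₀ — in production an electronic-structure engine
wrapped into the `PotentialBackend` contract, here analytic model surfaces —
is modified additively by external terms:

* **Pulling** (constant-force FMPES/EFEI convention): V = V₀ − F·d, where d
  is the distance between the two polymer attachment atoms.  The gradient
  has support only on those two atoms and is antiparallel along their
  connecting vector.  This term is invariant under all rigid motions.
* **Uniaxial compression** (generalized FMPES): V_ext = (k/2) Σᵢ zᵢ², every
  atom pressed harmonically toward the xy-plane of the working frame.  The
  external force on atom i is (0, 0, −k·zᵢ).  Only xy-translations and the
  rotation about z survive as symmetries; k = 0 is treated as zero coupling
  with all six rigid modes intact.

Because the compression plane is fixed in the laboratory frame, molecular
orientation matters.  `align_to_frame` provides the conventions:
`attachment_in_plane` (default when an attachment pair exists) rotates the
attachment vector into the xy-plane after moving the centroid to the
origin; `principal_axes` puts the inertia eigenframe (unit masses — the
compression term weighs atoms equally) with the long axis along x;
`none` leaves the input untouched.  In a compression scan alignment is
applied once at the start and the frame held fixed.

## Units

Hartree atomic units internally; Å, kcal mol⁻¹, nN and N m⁻¹ at the user
boundary.  Constants (CODATA 2018, in `mechpes.units`):
1 hartree = 627.5095 kcal mol⁻¹; 1 bohr = 0.529177 Å;
1 hartree/bohr = 82.387 nN; 1 N m⁻¹ = 6.42306 × 10⁻⁴ hartree/bohr².
Low-dimensional benchmark surfaces are "pseudo-atom" systems whose
coordinates are used as-is (model/atomic units, no Å→bohr conversion);
unused components carry exactly zero gradient.

## Optimizers

* **Minimization**: BFGS quasi-Newton with Wolfe line search
  (scipy.optimize) under the package's convergence contract — the maximum
  gradient component must fall below the threshold, default
  1.0 × 10⁻⁴ a.u.  Frozen atoms are removed from the variable space
  exactly.  Accepted steps decrease the energy monotonically.
* **Dimer method** for first-order saddles: two images separated by
  1 × 10⁻³ bohr estimate the lowest-curvature mode; rotations use the
  two-point Fourier interpolation of the curvature with convergence on the
  rotational force (default 1 × 10⁻⁴ a.u., at most 15 rotations per step);
  translation follows the force with the component along the mode inverted
  (full reversal when the curvature is negative, mode-only otherwise),
  stepped by a Polak–Ribière conjugate-gradient walker with a
  Newton-on-force line step clamped to 0.3 internal units.  The initial
  orientation is the lowest Hessian eigenvector when a Hessian is
  affordable (always, for the analytic surfaces), else a seeded random
  unit vector.  All paths are deterministic for fixed settings and seed.

Convergence to something other than a first-order saddle is reported in
the result's classification and message, never raised away or hidden.

## Characterization

Stationary points are classified by the eigenvalues of the (symmetrized,
finite-difference) Hessian after projecting out the rigid modes the active
surface actually preserves: all six (five for linear molecules) with no
external term or pulling only; xy-translations and z-rotation under
compression.  Remaining eigenvalues with magnitude below the curvature
tolerance (default 1 × 10⁻⁶ a.u.) count as zero modes.  The tolerance is
widened to the achieved residual-gradient norm when that is larger:
curvatures smaller than the gradient noise at a loosely converged point are
not resolvable, and pretending otherwise produced spurious "higher-order
saddle" labels for soft rotational modes.  `classify` refuses points whose
gradient exceeds ten times the convergence threshold.

## Scans

`scan_pulling_force` steps F over 0, 0.5, …, 4.0 nN;
`scan_uniaxial_k` steps k over 0, 2.5, 5, 10, 15, 20, 30, 40, 50 N m⁻¹
(10 N m⁻¹ increments with a finer {2.5, 5, 10, 15} sub-grid below
20 N m⁻¹; the sub-grid is configurable since only "finer below 20" is
prescribed).  Each row re-optimizes reactant and TS on the modified
surface, warm-started from the previous row (continuation; a cold-start
audit mode exists and agrees to 1 × 10⁻⁶ kcal mol⁻¹ on the analytic
surfaces).  V_A = E(TS) − E(reactant) is converted to kcal mol⁻¹ once per
row.  After each step the TS classification is re-verified; a saddle that
collapses invalidates the row instead of being reported silently, and
failed rows are listed in the metadata while the scan continues.

## Built-in surfaces and what the toys do (not) show

* `QuarticDoubleWell` (a x⁴ − b x²): closed-form minima ±√(b/2a), saddle at
  0, barrier b²/(4a).  With a linear tilt −F·x it is the 1-D limit of a
  pulling scan, and the exact barrier follows from the roots of the cubic
  V′(x) = 0 — the oracle for scan correctness to 1 × 10⁻⁸ hartree.
* `MullerBrown`: the standard 2-D benchmark (3 minima, 2 saddles) for
  minimizer/dimer robustness on a stiff, anisotropic surface.
* `BeadSpringFlex`: a five-bead flex mechanophore.  A bent three-bead
  scaffold (A–B–C, bond 1.5 Å, angle 150°, harmonic bonds k = 0.3 and
  cosine-harmonic angles k = 1.0 hartree) carries the attachment points A
  and C; the payload D sits on the central bead perpendicular to the
  scaffold plane, bound by the reactive potential a q⁴ − b q²
  (q = r_BD − 1.9 Å; a = 0.07, b = 0.125) with the closed-form bare
  barrier b²/(4a) = 35.02 kcal mol⁻¹; an in-plane arm bead E (bond 2.2 Å)
  gives the scaffold enough lateral extent that compression cannot be
  evaded by rigid rotation of the payload into the plane — the escape
  channel that makes an unanchored (monofunctional-like) motif
  compression-inert.  The payload orientation terms
  (k_orient = 0.3 on cos ∠ABD/∠CBD, k_improper = 0.05 on cos ∠DBE) have a
  q-dependent equilibrium that swings from nearly upright in the reactant
  to strongly tilted at the TS via a logistic switch (γ = 8 bohr⁻¹) —
  the bond breaks *through* an angle distortion.  Consequences, each
  verified by the suite: in-plane pulling decouples from the release
  coordinate (V_A flat to ≲ 0.1 kcal mol⁻¹ over 0–4 nN; the documented
  acceptance bound is 5% of the bare barrier), while compression
  destabilizes the upright reactant against the pre-tilted TS
  (V_A strictly decreasing, 35.0 → 7.5 kcal mol⁻¹ over the default grid).
  Stiffnesses were fixed at design time so the compression work saturates
  below the bare barrier across the default grid (V_A stays positive).

The toys demonstrate that the machinery — composition, optimization,
characterization, continuation — behaves correctly and that the
qualitative compression-vs-pulling contrast of flex activation is
reproduced by construction.  They do not emulate an ab initio surface:
absolute barriers, force constants and the quantitative shape of V_A(k)
for a real oxanorbornadiene-type mechanophore require an
electronic-structure backend, hours-scale optimizations, and carry no
meaning here.  Reported activation energies are bare potential-energy
differences without zero-point correction throughout.

## Acoustics

Probe sonication: I = (E/t_on)/(πr²); pulsed duty cycles (for example
2 s on / 1 s off) give t_on = total × on/(on+off).  Linear sinusoidal
approximation: I = p_RMS²/(ρc), p_peak = √2 p_RMS.  Mechanical index:
MI = p⁻/√f (MPa, MHz), with the peak negative pressure taken equal to the
peak pressure in the linear approximation.  The printed I–p relation
reproduces the published MI values only when p in I = p²/ρc is read as the
RMS pressure and the MI uses the peak pressure; the peak convention is
therefore the default, with both exposed.  Water defaults
ρ = 998 kg m⁻³, c = 1482 m s⁻¹ (20 °C): across 20–37 °C water properties
the MI changes by under 0.02, invisible at the one-decimal reporting
precision.  No derating/attenuation is applied.

## Numerical choices and limitations

* Finite differences: gradient step 1 × 10⁻⁴ bohr (central), Hessian step
  1 × 10⁻³ bohr (central differences of the gradient, symmetrized);
  both configurable per backend.
* `BeadSpringFlex` energy and gradient are generated symbolically (sympy)
  once per parameter set and cached — one code path, machine-precision
  derivatives.
* Scans assume the TS remains continuously connected along the grid;
  discontinuous switches of mechanism would need re-seeded guesses.
* The dimer walker is tuned for smooth analytic surfaces; on noisy
  gradients (tight DFT grids not converged) the Newton-on-force line step
  would need damping.
* Atom indices are 0-based in configs and APIs, 1-based only in
  human-readable reports.
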