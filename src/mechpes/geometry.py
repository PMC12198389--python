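"""Molecular geometry container, XYZ I/O, and frame alignment.

Coordinates of molecular systems are stored in Å.  Pseudo-atom geometries
used by the low-dimensional benchmark surfaces reuse the same container;
their coordinate values are interpreted by the owning backend (see
:mod:`mechpes.backends`).

The uniaxial-compression potential is defined relative to the laboratory
xy-plane, so the orientation of a molecule matters.  :func:`align_to_frame`
provides the documented conventions for placing a molecule into that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np


class GeometryError(ValueError):
    """Raised for invalid geometries or malformed geometry files."""


@dataclass(frozen=True)
class Geometry:
    """Atoms, Cartesian coordinates and mechanochemistry annotations.

    Parameters
    ----------
    elements
        Element symbols, one per atom.
    coords
        (N, 3) Cartesian coordinates in Å (molecular systems).
    attachment_pair
        Optional ordered pair of 0-based atom indices carrying the external
        pulling force (the polymer attachment points).
    frozen_mask
        Optional per-atom boolean; ``True`` atoms are held fixed during
        optimization.
    comment
        Free-text comment (second line of an XYZ file).
    """

    elements: Tuple[str, ...]
    coords: np.ndarray
    attachment_pair: Optional[Tuple[int, int]] = None
    frozen_mask: Optional[np.ndarray] = None
    comment: str = ""

    def __post_init__(self) -> None:
        elements = tuple(str(e) for e in self.elements)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (N, 3), got {coords.shape}")
        if len(elements) != coords.shape[0]:
            raise GeometryError(
                f"{len(elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if len(elements) < 1:
            raise GeometryError("geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")
        coords = coords.copy()
        coords.flags.writeable = False
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "coords", coords)
        if self.attachment_pair is not None:
            i, j = (int(k) for k in self.attachment_pair)
            n = len(elements)
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise GeometryError(
                    f"attachment_pair {self.attachment_pair} invalid for {n} atoms"
                )
            object.__setattr__(self, "attachment_pair", (i, j))
        if self.frozen_mask is not None:
            mask = np.asarray(self.frozen_mask, dtype=bool)
            if mask.shape != (len(elements),):
                raise GeometryError(
                    f"frozen_mask shape {mask.shape} does not match {len(elements)} atoms"
                )
            mask = mask.copy()
            mask.flags.writeable = False
            object.__setattr__(self, "frozen_mask", mask)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        """Copy of this geometry with new coordinates (annotations kept)."""
        return replace(self, coords=np.asarray(coords, dtype=float))

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def sum_z_squared(self) -> float:
        """Σ z_i² in Å² — the flatness measure penalized by compression."""
        return float(np.sum(self.coords[:, 2] ** 2))


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def _format_comment(geom: Geometry) -> str:
    tokens = []
    if geom.comment:
        tokens.append(geom.comment)
    if geom.attachment_pair is not None:
        i, j = geom.attachment_pair
        tokens.append(f"attachment_pair={i},{j}")
    if geom.frozen_mask is not None and geom.frozen_mask.any():
        idx = ",".join(str(i) for i in np.flatnonzero(geom.frozen_mask))
        tokens.append(f"frozen={idx}")
    return " ".join(tokens)


def _parse_comment(line: str, n_atoms: int):
    attachment = None
    frozen = None
    plain = []
    for token in line.split():
        if token.startswith("attachment_pair="):
            i, j = (int(v) for v in token.split("=", 1)[1].split(","))
            attachment = (i, j)
        elif token.startswith("frozen="):
            frozen = np.zeros(n_atoms, dtype=bool)
            for v in token.split("=", 1)[1].split(","):
                frozen[int(v)] = True
        else:
            plain.append(token)
    return " ".join(plain), attachment, frozen


def write_xyz(geom: Geometry, path, precision: int = 8) -> None:
    """Write a geometry as standard XYZ (metadata on the comment line)."""
    fmt = f"{{:s}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        fh.write(f"{geom.n_atoms}\n")
        fh.write(_format_comment(geom) + "\n")
        for el, (x, y, z) in zip(geom.elements, geom.coords):
            fh.write(fmt.format(el, x, y, z))


def read_xyz(path) -> Geometry:
    """Read a standard XYZ file, recovering comment-line metadata."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise GeometryError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GeometryError(f"{path}: line 1: expected atom count, got {lines[0]!r}")
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise GeometryError(
            f"{path}: count line declares {n} atoms but body has {len(body)} rows"
        )
    elements = []
    coords = np.empty((n, 3))
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: line {k + 3}: expected 'El x y z', got {ln!r}")
        elements.append(parts[0])
        try:
            coords[k] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise GeometryError(f"{path}: line {k + 3}: cannot parse coordinates in {ln!r}")
    comment_line = lines[1].strip() if len(lines) > 1 else ""
    comment, attachment, frozen = _parse_comment(comment_line, n)
    return Geometry(tuple(elements), coords, attachment_pair=attachment,
                    frozen_mask=frozen, comment=comment)


# ---------------------------------------------------------------------------
# Frame alignment
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-14:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


ALIGN_MODES = ("principal_axes", "attachment_in_plane", "none")


def align_to_frame(geom: Geometry, mode: str = "attachment_in_plane") -> Geometry:
    """Place a molecule into the compression working frame (xy-plane at z=0).

    Modes
    -----
    ``none``
        Identity: the geometry is used exactly as given.
    ``attachment_in_plane``
        Centroid to the origin, then the attachment vector is rotated into
        the xy-plane (its z-component vanishes).  Requires an attachment
        pair.
    ``principal_axes``
        Centroid to the origin, axes rotated to the inertia-tensor
        eigenframe with unit atom masses; the smallest-moment (long) axis
        maps to x and the largest-moment axis to z, so the molecular
        extension lies in the xy-plane.
    """
    if mode not in ALIGN_MODES:
        raise ValueError(f"unknown alignment mode {mode!r}; choose from {ALIGN_MODES}")
    if mode == "none":
        return geom
    coords = geom.coords - geom.centroid()
    if mode == "attachment_in_plane":
        if geom.attachment_pair is None:
            raise GeometryError("attachment_in_plane alignment requires an attachment_pair")
        i, j = geom.attachment_pair
        v = coords[j] - coords[i]
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise GeometryError("attachment atoms coincide; alignment direction undefined")
        target = np.array([v[0], v[1], 0.0])
        if np.linalg.norm(target) < 1e-10:
            target = np.array([1.0, 0.0, 0.0])  # vector along z: rotate onto x
        rot = _rotation_between(v / norm, target / np.linalg.norm(target))
        return geom.with_coords(coords @ rot.T)
    # principal_axes: unit masses (the compression term treats atoms equally)
    inertia = np.einsum("ni,nj->ij", coords, coords)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    _, vecs = np.linalg.eigh(inertia)  # ascending moments: long axis first
    frame = vecs  # columns: x <- smallest moment, z <- largest
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    return geom.with_coords(coords @ frame)
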