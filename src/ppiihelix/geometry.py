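"""Backbone dihedral geometry and PPII-window classification.

The polyproline II (PPII) helix is an extended, left-handed backbone
conformation without intramolecular hydrogen bonds, characterised purely by
its dihedral angles: phi near -75 deg and psi near +150 deg.  This module
computes phi/psi from backbone coordinates and classifies residue
conformations against a rectangular window in (phi, psi) space,
phi = -75 +/- 20 deg, psi = +150 +/- 20 deg by default, with boundary
membership inclusive and distances measured on the circle.

Angles are in degrees throughout, in the interval (-180, 180]; undefined
angles (chain termini) are represented as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BackboneCoordinates",
    "DihedralPair",
    "PPIIWindow",
    "DegenerateGeometryError",
    "compute_dihedral",
    "chain_dihedrals",
    "is_ppii",
    "circular_difference",
    "wrap_angle",
]

_COLLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined because three points are collinear."""


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees onto (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Signed circular difference a - b in degrees, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class DihedralPair:
    """A residue's (phi, psi) in degrees; NaN marks an undefined terminus angle."""

    phi: float
    psi: float

    @property
    def phi_defined(self) -> bool:
        return not math.isnan(self.phi)

    @property
    def psi_defined(self) -> bool:
        return not math.isnan(self.psi)


@dataclass(frozen=True)
class PPIIWindow:
    """Rectangular (phi, psi) acceptance window for PPII classification.

    Defaults encode phi = -75 +/- 20 deg and psi = +150 +/- 20 deg.
    Membership is inclusive at the boundary and uses circular distance, so
    windows whose edges straddle +/-180 deg behave correctly.
    """

    phi_center: float = -75.0
    psi_center: float = 150.0
    half_width: float = 20.0

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")
        for name in ("phi_center", "psi_center"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name}={v} outside (-180, 180]")

    def contains(self, phi: float | np.ndarray, psi: float | np.ndarray) -> bool | np.ndarray:
        """Vectorised membership test; NaN angles are never members."""
        dphi = np.abs(circular_difference(phi, self.phi_center))
        dpsi = np.abs(circular_difference(psi, self.psi_center))
        inside = (dphi <= self.half_width) & (dpsi <= self.half_width)
        # NaN comparisons are already False, but be explicit about the contract
        inside = inside & ~np.isnan(np.asarray(phi, dtype=float))
        inside = inside & ~np.isnan(np.asarray(psi, dtype=float))
        if np.ndim(phi) == 0 and np.ndim(psi) == 0:
            return bool(inside)
        return inside

    @property
    def area_fraction(self) -> float:
        """Fraction of the (phi, psi) torus covered by the window."""
        return (2.0 * self.half_width / 360.0) ** 2


def is_ppii(d: DihedralPair, window: PPIIWindow | None = None) -> bool:
    """True iff both angles are defined and lie inside the PPII window."""
    w = window if window is not None else PPIIWindow()
    if not (d.phi_defined and d.psi_defined):
        return False
    return bool(w.contains(d.phi, d.psi))


@dataclass
class BackboneCoordinates:
    """N/CA/C coordinates of one chain in one model (frame).

    ``n``, ``ca`` and ``c`` are (n_residues, 3) arrays in Angstrom; residues
    are peptide-bonded in list order.
    """

    chain_id: str
    residue_names: list[str]
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    model_index: int = 0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        nres = len(self.residue_names)
        for name, arr in (("n", self.n), ("ca", self.ca), ("c", self.c)):
            if arr.shape != (nres, 3):
                raise ValueError(
                    f"backbone array {name!r} has shape {arr.shape}, expected ({nres}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"backbone array {name!r} contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residue_names)


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (eclipsed) = 0 deg, trans (anti) = 180 deg; sign is positive for a
    clockwise rotation of p4 relative to p1 when viewed from p2 towards p3.
    Returns a value in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))

    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3

    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("central atoms p2 and p3 coincide")
    b1u = b1 / nb1

    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    scale = max(np.linalg.norm(b0), nb1, np.linalg.norm(b2), 1.0)
    if np.linalg.norm(v) < _COLLINEAR_TOL * scale:
        raise DegenerateGeometryError("atoms p1, p2, p3 are collinear; torsion undefined")
    if np.linalg.norm(w) < _COLLINEAR_TOL * scale:
        raise DegenerateGeometryError("atoms p2, p3, p4 are collinear; torsion undefined")

    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def chain_dihedrals(coords: BackboneCoordinates) -> list[DihedralPair]:
    """Backbone (phi, psi) for every residue of a chain.

    phi_i is the C(i-1)-N(i)-CA(i)-C(i) torsion and psi_i the
    N(i)-CA(i)-C(i)-N(i+1) torsion; the first residue has no phi and the
    last no psi (NaN members).
    """
    nres = len(coords)
    if nres < 2:
        raise ValueError("chain_dihedrals requires at least 2 residues")

    pairs: list[DihedralPair] = []
    for i in range(nres):
        if i == 0:
            phi = math.nan
        else:
            phi = compute_dihedral(coords.c[i - 1], coords.n[i], coords.ca[i], coords.c[i])
        if i == nres - 1:
            psi = math.nan
        else:
            psi = compute_dihedral(coords.n[i], coords.ca[i], coords.c[i], coords.n[i + 1])
        pairs.append(DihedralPair(phi=phi, psi=psi))
    return pairs
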