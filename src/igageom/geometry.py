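"""Directed centroid axes, least-squares planes, bend/tilt, superposition.

The two inter-Fc statistics used to describe dimeric IgA geometry are

* **bend** — the angle between the *directed* centroid axes of the two Fc
  regions, in [0, 180]°.  Each axis is the first principal component of the
  Cα coordinates of an Fc selection, with its sign fixed by an orienting pair
  of selections (conventionally C_H2 → C_H3), because the observed bends
  (97–98°) exceed 90° and an undirected line angle could not represent them.
* **tilt** — the acute dihedral between the least-squares planes fitted to
  the same selections, in [0, 90]°.

Superposition is the standard least-squares rigid fit (Kabsch); pairing is
by atom order, with a residue-matched Cα convenience wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomSet, Structure

__all__ = [
    "DirectedAxis",
    "FitPlane",
    "RigidTransform",
    "DegenerateSelectionError",
    "centroid_axis",
    "centroid_plane",
    "bend_angle",
    "tilt_angle",
    "superpose",
    "superpose_ca_by_resnum",
    "atom_distance",
]

_UNIT_TOL = 1e-9


class DegenerateSelectionError(ValueError):
    """Selection too degenerate (collinear/coincident) for an axis or plane fit."""


@dataclass(frozen=True)
class DirectedAxis:
    """origin (selection centroid, Å) + sign-fixed unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, float)
        direction = np.asarray(self.direction, float)
        n = np.linalg.norm(direction)
        if abs(n - 1.0) > 1e-6:
            direction = direction / n
        if abs(np.linalg.norm(direction) - 1.0) > _UNIT_TOL:
            raise ValueError("axis direction must be a unit vector")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)


@dataclass(frozen=True)
class FitPlane:
    """origin (selection centroid, Å) + unit normal of a least-squares plane."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, float)
        normal = np.asarray(self.normal, float)
        n = np.linalg.norm(normal)
        if abs(n - 1.0) > 1e-6:
            normal = normal / n
        if abs(np.linalg.norm(normal) - 1.0) > _UNIT_TOL:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "normal", normal)


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, proper rotation only."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _coords_of(atoms) -> np.ndarray:
    if isinstance(atoms, AtomSet):
        return atoms.coords
    return np.asarray(atoms, float)


def _principal_components(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centroid, eigenvalues desc, eigenvectors as rows) of the covariance."""
    coords = np.asarray(coords, float)
    if coords.shape[0] < 3:
        raise DegenerateSelectionError("need at least 3 atoms for an axis/plane fit")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return centroid, evals[order], evecs[:, order].T


def centroid_axis(atoms, orient_from, orient_to) -> DirectedAxis:
    """First principal axis of a selection, sign-fixed by two orienting selections.

    The direction is chosen so that it has positive dot product with the
    vector from ``orient_from``'s centroid to ``orient_to``'s centroid (for an
    Fc: from the C_H2 half toward the C_H3 half).
    """
    coords = _coords_of(atoms)
    centroid, evals, evecs = _principal_components(coords)
    if evals[0] < 1e-12:
        raise DegenerateSelectionError("coincident atoms: no principal axis")
    direction = evecs[0]
    orient = _coords_of(orient_to).mean(axis=0) - _coords_of(orient_from).mean(axis=0)
    norm = np.linalg.norm(orient)
    if norm == 0:
        raise DegenerateSelectionError("orienting selections have coincident centroids")
    proj = float(direction @ (orient / norm))
    if abs(proj) < 1e-6:
        raise DegenerateSelectionError(
            "orienting vector is perpendicular to the principal axis; "
            "supply an explicit orientation"
        )
    if proj < 0:
        direction = -direction
    return DirectedAxis(origin=centroid, direction=direction)


def centroid_plane(atoms) -> FitPlane:
    """Least-squares plane: origin = centroid, normal = smallest-variance PC."""
    coords = _coords_of(atoms)
    centroid, evals, evecs = _principal_components(coords)
    # collinear clouds have no defined plane: second-largest variance ~ 0
    if evals[1] <= max(evals[0], 1.0) * 1e-10:
        raise DegenerateSelectionError("collinear selection: plane fit is degenerate")
    return FitPlane(origin=centroid, normal=evecs[2])


def bend_angle(a: DirectedAxis, b: DirectedAxis) -> float:
    """Directed angle between two axes in degrees, in [0, 180] (not folded)."""
    c = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def tilt_angle(p: FitPlane, q: FitPlane) -> float:
    """Acute dihedral between two planes in degrees, in [0, 90]."""
    c = float(np.clip(abs(p.normal @ q.normal), 0.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``reference``.

    Pairing is strictly by atom order; counts must match.  Returns the
    transform mapping mobile coordinates onto the reference frame and the
    post-fit RMSD in Å.  Reflections are never produced.
    """
    mob = _coords_of(mobile)
    ref = _coords_of(reference)
    if mob.shape != ref.shape:
        raise ValueError(
            f"superpose: atom count mismatch (mobile {mob.shape[0]}, "
            f"reference {ref.shape[0]})"
        )
    if mob.shape[0] < 3:
        raise ValueError("superpose needs at least 3 paired atoms")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return RigidTransform(R, rc - R @ mc), rmsd


def superpose_ca_by_resnum(
    mobile: AtomSet, reference: AtomSet
) -> tuple[RigidTransform, float, int]:
    """Superpose on Cα atoms paired by (chain, residue number, icode).

    Residues present on only one side are dropped symmetrically (count
    reported); returns (transform, rmsd, n_pairs).
    """

    def ca_map(sel: AtomSet) -> dict[tuple, np.ndarray]:
        s = sel.structure
        out = {}
        for i in sel.indices:
            if s.atom_names[i] == "CA" and not s.is_hydrogen[i]:
                out[(s.chain_ids[i], int(s.res_seqs[i]), s.icodes[i])] = s.coords[i]
        return out

    mob_map, ref_map = ca_map(mobile), ca_map(reference)
    common = sorted(set(mob_map) & set(ref_map))
    dropped = (len(mob_map) - len(common)) + (len(ref_map) - len(common))
    if dropped:
        warnings.warn(f"superpose: dropped {dropped} unmatched Cα residues", stacklevel=2)
    if len(common) < 3:
        raise ValueError("fewer than 3 matched Cα residues")
    mob = np.array([mob_map[k] for k in common])
    ref = np.array([ref_map[k] for k in common])
    tr, rmsd = superpose(mob, ref)
    return tr, rmsd, len(common)


def atom_distance(
    structure: Structure,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance (Å) between two atoms addressed as (chain, res, name)."""
    ia = structure.find_atom(a[0], a[1], a[2])
    ib = structure.find_atom(b[0], b[1], b[2])
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))
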