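"""Rigid-body Fab conformational search on a Fibonacci spherical lattice.

A Fab's placement is summarised by its *Fab vector*: from the pivot atom (the
backbone N of the amino-terminal residue of C_H2, where the Fab joins the Fc)
to the centre of mass of its CDR atoms.  The search rotates the whole Fab
about the fixed pivot so that the Fab-vector tip visits each of ``n`` points
of a Fibonacci spherical lattice (a deterministic, quasi-uniform golden-angle
spiral on the sphere), and at each lattice direction additionally spins the
Fab about its own pivot→CDR axis in steps of γ.  With the defaults n = 1000
and γ = 45° this enumerates 8000 candidate placements per Fab.

Placements are screened with a hard-sphere clash rule against an environment
(the Fc/JC/SC core): a conformer is rejected when at least ``min_clash_atoms``
of its non-linker atoms have any environment atom within ``distance_cutoff``
(defaults: 8 atoms within 1 Å — roughly one amino acid's worth of heavy
atoms).  The linker is excluded because it is assumed flexible.  Accepted
placements are summarised by φ, the angle between the Fab vector and a
reference axis lying in the Fc_AB plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DirectedAxis, RigidTransform, centroid_axis, centroid_plane
from .structure_io import AtomSet, DomainMap, Structure, select

__all__ = [
    "FabModel",
    "LatticeParams",
    "ClashParams",
    "ConformerSet",
    "Histogram",
    "fibonacci_lattice",
    "generate_conformers",
    "clash_filter",
    "phi_angles",
    "phi_histogram",
    "phi_reference_axis",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class FabModel:
    """A rigid Fab with annotated pivot, CDR and linker atoms.

    ``atoms`` is the full Fab; ``pivot_index`` addresses the single pivot atom
    within it; ``cdr_indices``/``linker_indices`` index into ``atoms.indices``.
    """

    atoms: AtomSet
    pivot_index: int
    cdr_indices: np.ndarray
    linker_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdr_indices", np.asarray(self.cdr_indices, int))
        object.__setattr__(self, "linker_indices", np.asarray(self.linker_indices, int))
        n = len(self.atoms)
        if self.cdr_indices.size == 0:
            raise ValueError("FabModel requires a non-empty CDR atom set")
        for name, idx in (("cdr", self.cdr_indices), ("linker", self.linker_indices)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} indices out of range for the Fab atom set")
        if not (0 <= self.pivot_index < n):
            raise ValueError("pivot index out of range")

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coords

    @property
    def pivot(self) -> np.ndarray:
        return self.coords[self.pivot_index]

    @property
    def cdr_com(self) -> np.ndarray:
        return self.coords[self.cdr_indices].mean(axis=0)

    @property
    def fab_vector(self) -> np.ndarray:
        """pivot → CDR centre-of-mass (not normalised)."""
        return self.cdr_com - self.pivot

    def nonlinker_mask(self) -> np.ndarray:
        mask = np.ones(len(self.atoms), dtype=bool)
        mask[self.linker_indices] = False
        return mask

    @classmethod
    def from_domains(
        cls, structure: Structure, domains: DomainMap, fab_name: str
    ) -> "FabModel":
        """Build a FabModel from a Fab domain entry with pivot/cdr/linker roles."""
        spec = domains[fab_name]
        full = select(structure, spec, atom_filter="heavy")
        pos = {int(i): k for k, i in enumerate(full.indices)}

        def role_positions(role: str) -> np.ndarray:
            ranges = spec.ranges_with_role(role)
            if not ranges:
                return np.empty(0, int)
            sub = select(structure, replace(spec, selections=ranges,
                                            roles=tuple("core" for _ in ranges)), "heavy")
            return np.array([pos[int(i)] for i in sub.indices], int)

        pivot_ranges = spec.ranges_with_role("pivot")
        chain, res, _ = pivot_ranges[0]
        pivot_global = structure.find_atom(chain, res, "N")
        if pivot_global not in pos:
            raise ValueError(f"pivot atom of {fab_name!r} not inside the Fab selection")
        return cls(
            atoms=full,
            pivot_index=pos[pivot_global],
            cdr_indices=role_positions("cdr"),
            linker_indices=role_positions("linker"),
        )


@dataclass(frozen=True)
class LatticeParams:
    """Lattice size and axial-spin interval; construction is deterministic."""

    n_points: int = 1000
    gamma: float = 45.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.gamma <= 0 or abs(360.0 / self.gamma - round(360.0 / self.gamma)) > 1e-9:
            raise ValueError("gamma must divide 360 evenly")

    @property
    def n_spins(self) -> int:
        return int(round(360.0 / self.gamma))


@dataclass(frozen=True)
class ClashParams:
    distance_cutoff: float = 1.0
    min_clash_atoms: int = 8
    exclude_linker: bool = True
    strict_greater: bool = False  # reject only at count > min_clash_atoms

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if self.min_clash_atoms < 1:
            raise ValueError("min_clash_atoms must be >= 1")

    def rejects(self, clash_count: np.ndarray | int):
        if self.strict_greater:
            return np.asarray(clash_count) > self.min_clash_atoms
        return np.asarray(clash_count) >= self.min_clash_atoms


@dataclass
class ConformerSet:
    """Candidate Fab placements: one rigid transform per (lattice i, spin k)."""

    transforms: list[RigidTransform]
    lattice_index: np.ndarray
    spin_index: np.ndarray
    params: LatticeParams
    accepted_mask: np.ndarray | None = None
    clash_counts: np.ndarray | None = None
    phi: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.transforms)

    @property
    def n_accepted(self) -> int:
        if self.accepted_mask is None:
            raise ValueError("clash filter has not been run")
        return int(self.accepted_mask.sum())

    def accepted_transforms(self) -> list[RigidTransform]:
        if self.accepted_mask is None:
            raise ValueError("clash filter has not been run")
        return [t for t, ok in zip(self.transforms, self.accepted_mask) if ok]


# ---------------------------------------------------------------------------
# Lattice and conformer generation
# ---------------------------------------------------------------------------

def fibonacci_lattice(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors via the golden-angle (Fibonacci) spiral.

    Deterministic; the i-th point has z = 1 - (2i+1)/n and azimuth
    i · (golden angle).  Returns an (n, 3) array of unit vectors.
    """
    if n < 1:
        raise ValueError("lattice size must be >= 1")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = GOLDEN_ANGLE * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _minimal_rotation(v0: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v0 onto unit vector d by the
    smallest angle; the antipodal case uses a deterministic perpendicular axis."""
    c = float(np.clip(v0 @ d, -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° turn: axis = any unit vector ⊥ v0, chosen from the least-aligned
        # coordinate basis vector for determinism
        basis = np.eye(3)[np.argmin(np.abs(v0))]
        axis = np.cross(v0, basis)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    axis = np.cross(v0, d)
    axis /= np.linalg.norm(axis)
    return _axis_angle(axis, np.arccos(c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_conformers(fab: FabModel, lattice: LatticeParams) -> ConformerSet:
    """Enumerate all n_points × (360/γ) rigid placements of the Fab.

    Each transform is a pure rotation about the (fixed) pivot: the minimal
    rotation carrying the original unit Fab vector onto lattice direction i,
    composed with a k·γ spin about that direction.
    """
    v = fab.fab_vector
    norm = float(np.linalg.norm(v))
    if norm < 1e-9:
        raise ValueError("pivot and CDR centre of mass coincide: Fab vector undefined")
    v0 = v / norm
    pivot = fab.pivot
    dirs = fibonacci_lattice(lattice.n_points)
    gamma_rad = np.radians(lattice.gamma)

    transforms: list[RigidTransform] = []
    lat_idx, spin_idx = [], []
    for i, d in enumerate(dirs):
        R_align = _minimal_rotation(v0, d)
        for k in range(lattice.n_spins):
            R = _axis_angle(d, k * gamma_rad) @ R_align
            transforms.append(RigidTransform(R, pivot - R @ pivot))
            lat_idx.append(i)
            spin_idx.append(k)
    return ConformerSet(
        transforms=transforms,
        lattice_index=np.array(lat_idx, int),
        spin_index=np.array(spin_idx, int),
        params=lattice,
    )


# ---------------------------------------------------------------------------
# Clash filtering
# ---------------------------------------------------------------------------

def clash_counts(
    conformers: ConformerSet,
    fab: FabModel,
    environment_coords: np.ndarray,
    cutoff: float,
    exclude_linker: bool = True,
) -> np.ndarray:
    """Per-conformer count of (non-linker) Fab atoms with any environment atom
    within ``cutoff``.  KD-tree accelerated; contractually identical to an
    all-pairs search."""
    mask = fab.nonlinker_mask() if exclude_linker else np.ones(len(fab.atoms), bool)
    base = fab.coords[mask]
    env = np.asarray(environment_coords, float)
    n_conf = len(conformers)
    if env.shape[0] == 0:
        return np.zeros(n_conf, dtype=int)
    tree = cKDTree(env)
    rots = np.stack([t.rotation for t in conformers.transforms])  # (M,3,3)
    trans = np.stack([t.translation for t in conformers.transforms])  # (M,3)
    counts = np.empty(n_conf, dtype=int)
    # chunk over conformers to bound the stacked-query memory
    chunk = max(1, 2_000_000 // max(base.shape[0], 1))
    for lo in range(0, n_conf, chunk):
        hi = min(lo + chunk, n_conf)
        moved = np.einsum("mij,aj->mai", rots[lo:hi], base) + trans[lo:hi, None, :]
        d, _ = tree.query(
            moved.reshape(-1, 3), k=1, distance_upper_bound=cutoff * 1.0000001
        )
        counts[lo:hi] = (d.reshape(hi - lo, base.shape[0]) <= cutoff).sum(axis=1)
    return counts


def clash_filter(
    conformers: ConformerSet,
    fab: FabModel,
    environment: AtomSet | np.ndarray,
    params: ClashParams = ClashParams(),
) -> ConformerSet:
    """Mark each conformer accepted/rejected under the hard-sphere clash rule.

    Rejection: the count of non-linker Fab atoms within ``distance_cutoff`` of
    any environment atom reaches ``min_clash_atoms`` (or exceeds it in
    strict-greater mode).  An empty environment accepts everything, with a
    warning.
    """
    env = environment.coords if isinstance(environment, AtomSet) else np.asarray(environment, float)
    if env.shape[0] == 0:
        warnings.warn("clash_filter: empty environment, accepting all conformers", stacklevel=2)
        counts = np.zeros(len(conformers), int)
    else:
        counts = clash_counts(
            conformers, fab, env, params.distance_cutoff, params.exclude_linker
        )
    conformers.clash_counts = counts
    conformers.accepted_mask = ~params.rejects(counts)
    return conformers


# ---------------------------------------------------------------------------
# φ statistics
# ---------------------------------------------------------------------------

def phi_reference_axis(
    structure: Structure, domains: DomainMap, plane_domain: str = "Fc_AB"
) -> DirectedAxis:
    """Reference axis for φ: parallel to the Fc_AB plane, through the Fc+JC
    centre of mass.

    Constructed as the Fc_AB centroid axis projected onto the Fc_AB plane
    (which makes it exactly parallel to that plane) and anchored at the
    centre of mass of the Fc_AB, Fc_CD and JC Cα selections.  The in-plane
    direction is a convention; substitute your own DirectedAxis to change it.
    """
    fc = select(structure, domains[plane_domain], "ca")
    ch2 = select(structure, domains[f"{plane_domain}_CH2"], "ca")
    ch3 = select(structure, domains[f"{plane_domain}_CH3"], "ca")
    axis = centroid_axis(fc, ch2, ch3)
    plane = centroid_plane(fc)
    in_plane = axis.direction - (axis.direction @ plane.normal) * plane.normal
    n = np.linalg.norm(in_plane)
    if n < 1e-9:
        raise ValueError("Fc axis is perpendicular to its own plane fit")
    parts = [select(structure, domains[d], "ca").coords
             for d in (plane_domain, "Fc_CD", "JC") if d in domains]
    com = np.concatenate(parts).mean(axis=0)
    return DirectedAxis(origin=com, direction=in_plane / n)


def phi_angles(
    conformers: ConformerSet, fab: FabModel, reference_axis: DirectedAxis
) -> np.ndarray:
    """φ of each *accepted* conformer: angle (degrees, [0,180]) between the
    placed Fab vector and the reference axis direction."""
    if conformers.accepted_mask is None:
        raise ValueError("run clash_filter before phi_angles")
    if conformers.n_accepted == 0:
        warnings.warn("phi_angles: no accepted conformers", stacklevel=2)
        conformers.phi = np.empty(0)
        return conformers.phi
    pivot, cdr = fab.pivot, fab.cdr_com
    out = []
    for t, ok in zip(conformers.transforms, conformers.accepted_mask):
        if not ok:
            continue
        vec = t.apply(cdr) - t.apply(pivot)
        vec /= np.linalg.norm(vec)
        c = float(np.clip(vec @ reference_axis.direction, -1.0, 1.0))
        out.append(np.degrees(np.arccos(c)))
    conformers.phi = np.array(out)
    return conformers.phi


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray
    counts: np.ndarray  # normalised per `mode`
    mode: str


def phi_histogram(
    angles: np.ndarray, bin_width: float = 10.0, mode: str = "max1"
) -> Histogram:
    """Histogram of φ over [0, 180] with contiguous fixed-width bins.

    mode ``max1`` scales counts so the tallest bin equals 1 (the convention
    used for the published frequency plots); ``density`` integrates to 1.
    """
    angles = np.asarray(angles, float)
    if angles.size and (angles.min() < 0 or angles.max() > 180):
        raise ValueError("phi angles must lie in [0, 180] degrees")
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    if angles.size == 0:
        return Histogram(edges=edges, counts=np.zeros(n_bins), mode=mode)
    counts, _ = np.histogram(angles, bins=edges)
    counts = counts.astype(float)
    if mode == "max1":
        m = counts.max()
        counts = counts / m if m > 0 else counts
    elif mode == "density":
        counts = counts / (counts.sum() * bin_width)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return Histogram(edges=edges, counts=counts, mode=mode)
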