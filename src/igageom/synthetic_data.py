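"""Synthetic pseudo-atomic assemblies with known ground truth.

Everything the geometric pipeline measures on real coordinates can be
exercised download-free on these generators:

* ``make_pseudo_domain`` — an elongated Cα point cloud standing in for an Fc;
* ``make_bent_assembly`` — two pseudo-Fc domains placed by explicit rotations
  so their directed axes subtend exactly a chosen *bend* and their fitted
  planes exactly a chosen *tilt* (construction transforms stored as ground
  truth), joined by a central pseudo-JC blob;
* ``make_toy_fab`` — a rigid rod-like cloud with annotated pivot, CDR and
  linker atoms;
* ``plant_clash`` — an environment built so that exactly k Fab atoms clash,
  verified internally by an all-pairs search;
* ``make_wall_environment`` — a dense slab occluding one hemisphere of the
  pivot's view, for end-to-end sampler checks.

The clouds are geometric objects, not stereochemically valid proteins; all
in-scope analyses are purely geometric, so this is sufficient.  Elements are
restricted to C/N/O/S so that SASA radii always resolve.  Every generator is
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fab_sampler import FabModel, _axis_angle  # Rodrigues helper shared with the sampler
from .structure_io import Atom, AtomSet, DomainMap, DomainSpec, Structure

__all__ = [
    "SyntheticAssembly",
    "make_pseudo_domain",
    "make_bent_assembly",
    "make_toy_fab",
    "plant_clash",
    "make_wall_environment",
]

FC_FIRST_RES = 237  # synthetic Fcs span the same numbering the selections use
FC_LAST_RES = 445


@dataclass
class SyntheticAssembly:
    """A generated structure plus the exact construction ground truth."""

    structure: Structure
    domains: DomainMap
    bend: float
    tilt: float
    seed: int
    axes: dict = field(default_factory=dict)     # name -> unit direction
    normals: dict = field(default_factory=dict)  # name -> unit plane normal
    rotation: np.ndarray | None = None           # Fc1 -> Fc2 construction rotation


def _realign_to_principal_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate a cloud so its principal axes are exactly +z (largest variance),
    +y, +x (smallest), with +z along increasing point order."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    _, evecs = np.linalg.eigh(cov)  # ascending eigenvalues: x smallest, z largest
    aligned = centered @ evecs
    # orient +z with point order (residue numbering increases along +z)
    n = len(aligned)
    if np.corrcoef(aligned[:, 2], np.arange(n))[0, 1] < 0:
        aligned[:, 2] *= -1
        aligned[:, 0] *= -1  # keep handedness
    return aligned


def make_pseudo_domain(
    n_atoms: int,
    axial_length: float,
    radial_sd: float,
    seed: int,
    chain_id: str = "A",
    first_res: int = FC_FIRST_RES,
) -> AtomSet:
    """Anisotropic Cα cloud elongated along +z with sequential residue numbers.

    The transverse scatter is deliberately anisotropic (sd and sd/2 on the
    two transverse directions) so a least-squares plane is well defined.
    After generation the cloud is realigned to its own principal frame, so
    its empirical principal axis is *exactly* +z and its plane normal
    *exactly* +x; residue numbering increases along +z.  radial_sd = 0 gives
    a perfectly collinear cloud (degenerate for plane fitting, by design).
    """
    if n_atoms < 10:
        raise ValueError("n_atoms must be >= 10")
    if axial_length <= 0 or radial_sd < 0:
        raise ValueError("axial_length must be positive and radial_sd >= 0")
    rng = np.random.default_rng(seed)
    z = np.linspace(-axial_length / 2, axial_length / 2, n_atoms)
    x = rng.normal(0.0, radial_sd / 2.0, n_atoms)
    y = rng.normal(0.0, radial_sd, n_atoms)
    coords = np.column_stack([x, y, z])
    if radial_sd > 0:
        coords = _realign_to_principal_frame(coords)
    atoms = [
        Atom(
            chain_id=chain_id,
            res_seq=first_res + i,
            icode="",
            res_name="ALA",
            atom_name="CA",
            element="C",
            coord=coords[i],
        )
        for i in range(n_atoms)
    ]
    return Structure(atoms, source=f"<pseudo-domain seed={seed}>").all_atoms()


def _blob(rng, n, center, sd, chain_id, first_res, atom_name="CA", element="C"):
    coords = center + rng.normal(0.0, sd, (n, 3))
    return [
        Atom(chain_id=chain_id, res_seq=first_res + i, icode="", res_name="GLY",
             atom_name=atom_name, element=element, coord=coords[i])
        for i in range(n)
    ]


def make_bent_assembly(
    bend: float,
    tilt: float,
    seed: int,
    n_atoms: int = FC_LAST_RES - FC_FIRST_RES + 1,
    axial_length: float = 60.0,
    radial_sd: float = 6.0,
    noise_sd: float = 0.0,
    separation: float = 70.0,
) -> SyntheticAssembly:
    """Two pseudo-Fc domains subtending exactly (bend, tilt), plus a pseudo-JC.

    Domain 1 (chain A) sits in its principal frame: directed axis +z, plane
    normal +x.  Domain 2 (chain C) is the same cloud under R = R_spin · R_bend
    where R_bend rotates about +x by ``bend`` (moving the axis, leaving the
    normal) and R_spin rotates about the *new* axis by ``tilt`` (moving the
    normal, leaving the axis).  The construction therefore gives exactly the
    requested directed-axis angle and acute plane dihedral; optional isotropic
    coordinate noise is added afterwards.
    """
    if not (0.0 <= bend <= 180.0):
        raise ValueError("bend must lie in [0, 180] degrees")
    if not (0.0 <= tilt <= 90.0):
        raise ValueError("tilt must lie in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    base = make_pseudo_domain(
        n_atoms, axial_length, radial_sd, seed=int(rng.integers(2**31)), chain_id="A"
    )
    coords1 = base.coords

    axis1, normal1 = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    R_bend = _axis_angle(normal1, np.radians(bend))
    axis2 = R_bend @ axis1
    R_spin = _axis_angle(axis2, np.radians(tilt))
    R = R_spin @ R_bend
    normal2 = R @ normal1

    offset = np.array([0.0, separation, 0.0])
    coords2 = coords1 @ R.T + offset

    if noise_sd > 0:
        coords1 = coords1 + rng.normal(0.0, noise_sd, coords1.shape)
        coords2 = coords2 + rng.normal(0.0, noise_sd, coords2.shape)

    atoms: list[Atom] = []
    for i in range(n_atoms):
        atoms.append(Atom("A", FC_FIRST_RES + i, "", "ALA", "CA", "C", coords1[i]))
    for i in range(n_atoms):
        atoms.append(Atom("C", FC_FIRST_RES + i, "", "ALA", "CA", "C", coords2[i]))
    atoms += _blob(rng, 30, offset / 2.0, 4.0, "J", 1)
    structure = Structure(atoms, source=f"<bent-assembly bend={bend} tilt={tilt} seed={seed}>")

    mid = FC_FIRST_RES + (n_atoms - 1) // 2
    dmap = DomainMap()
    for fc, chain in (("Fc_AB", "A"), ("Fc_CD", "C")):
        last = FC_FIRST_RES + n_atoms - 1
        dmap.add(DomainSpec(fc, ((chain, FC_FIRST_RES, last),)))
        dmap.add(DomainSpec(f"{fc}_CH2", ((chain, FC_FIRST_RES, mid),)))
        dmap.add(DomainSpec(f"{fc}_CH3", ((chain, mid + 1, last),)))
    dmap.add(DomainSpec("JC", (("J", 1, 30),)))

    return SyntheticAssembly(
        structure=structure,
        domains=dmap,
        bend=bend,
        tilt=tilt,
        seed=seed,
        axes={"Fc_AB": axis1, "Fc_CD": axis2},
        normals={"Fc_AB": normal1, "Fc_CD": normal2},
        rotation=R,
    )


def make_toy_fab(
    n_atoms: int = 80,
    arm_length: float = 40.0,
    seed: int = 0,
) -> FabModel:
    """A rigid rod-like Fab stand-in with pivot, CDR and linker annotations.

    The pivot (backbone-N-like atom) sits at the origin; body atoms run out
    along a narrow helix to the CDR cluster, whose centre of mass is placed
    at exactly ``arm_length`` from the pivot; a 3-atom linker tag sits
    adjacent to the pivot.  The helix keeps all atoms ≥ ~1.8 Å apart so
    planted-clash environments can target individual atoms unambiguously.
    """
    if n_atoms < 20:
        raise ValueError("n_atoms must be >= 20")
    rng = np.random.default_rng(seed)
    n_cdr = 6
    n_linker = 3
    n_body = n_atoms - n_cdr - n_linker - 1

    # helical body: deterministic minimum separation, small seeded jitter
    body_z = np.linspace(5.0, arm_length - 4.0, n_body)
    turn = 1.8  # rad per atom; radius 1.2 Å keeps all atoms >= ~1.6 Å apart
    phase = turn * np.arange(n_body)
    body = [
        np.array([1.2 * np.cos(p), 1.2 * np.sin(p), z])
        + rng.normal(0.0, 0.1, 3)
        for p, z in zip(phase, body_z)
    ]
    # CDR: hexagonal ring, centre of mass exactly at (0, 0, arm_length)
    ring = np.radians(np.arange(n_cdr) * 60.0)
    cdr = [
        np.array([2.0 * np.cos(t), 2.0 * np.sin(t), arm_length]) for t in ring
    ]
    com = np.mean(cdr, axis=0)
    cdr = [p + (np.array([0.0, 0.0, arm_length]) - com) for p in cdr]
    linker = [np.array([1.8 * (i + 1), 0.0, -2.0]) for i in range(n_linker)]

    atoms: list[Atom] = []
    atoms.append(Atom("F", 10, "", "GLY", "N", "N", np.zeros(3)))  # pivot
    for i, p in enumerate(linker):
        atoms.append(Atom("F", 1 + i, "", "GLY", "CA", "C", p))
    for i, p in enumerate(body):
        atoms.append(Atom("F", 20 + i, "", "ALA", "CA", "C", p))
    for i, p in enumerate(cdr):
        atoms.append(Atom("F", 200 + i, "", "SER", "CA", "C", p))
    structure = Structure(atoms, source=f"<toy-fab seed={seed}>")
    n_total = len(atoms)
    return FabModel(
        atoms=structure.all_atoms(),
        pivot_index=0,
        cdr_indices=np.arange(n_total - n_cdr, n_total),
        linker_indices=np.arange(1, 1 + n_linker),
    )


def plant_clash(
    fab: FabModel,
    k_atoms: int,
    cutoff: float = 1.0,
    target: str = "nonlinker",
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[AtomSet, int]:
    """Environment built so exactly ``k_atoms`` targeted Fab atoms clash.

    One probe atom is dropped at 0.45·cutoff from each chosen Fab atom, on
    the outward side of the cloud.  Before returning, an all-pairs search
    verifies that exactly ``k_atoms`` atoms of the targeted class — and zero
    atoms of the other class — have an environment atom within ``cutoff``;
    construction is retried with fresh picks on failure.
    """
    if target not in ("nonlinker", "linker"):
        raise ValueError("target must be 'nonlinker' or 'linker'")
    coords = fab.coords
    nonlinker = fab.nonlinker_mask()
    pool = np.flatnonzero(nonlinker if target == "nonlinker" else ~nonlinker)
    if k_atoms > pool.size:
        raise ValueError(f"k_atoms={k_atoms} exceeds {target} atom count {pool.size}")
    rng = np.random.default_rng(seed)
    centroid = coords.mean(axis=0)

    for _ in range(max_tries):
        picks = rng.choice(pool, size=k_atoms, replace=False) if k_atoms else np.empty(0, int)
        env_pts = []
        for i in picks:
            d = coords[i] - centroid
            n = np.linalg.norm(d)
            d = d / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
            env_pts.append(coords[i] + 0.45 * cutoff * d)
        env_pts = np.asarray(env_pts).reshape(-1, 3)
        # all-pairs verification of the planted counts
        if env_pts.shape[0]:
            dmat = np.linalg.norm(coords[:, None, :] - env_pts[None, :, :], axis=2)
            hit = (dmat <= cutoff).any(axis=1)
        else:
            hit = np.zeros(len(coords), bool)
        n_non = int(hit[nonlinker].sum())
        n_link = int(hit[~nonlinker].sum())
        ok = (
            (n_non == k_atoms and n_link == 0)
            if target == "nonlinker"
            else (n_link == k_atoms and n_non == 0)
        )
        if ok:
            atoms = [
                Atom("E", 1 + i, "", "UNK", "O", "O", p) for i, p in enumerate(env_pts)
            ]
            env = Structure(atoms, source=f"<planted-clash k={k_atoms}>").all_atoms()
            return env, k_atoms
    raise RuntimeError(
        f"plant_clash: could not construct a clean k={k_atoms} scenario "
        f"in {max_tries} tries"
    )


def make_wall_environment(
    z_top: float = -3.0,
    thickness: float = 4.0,
    extent: float = 60.0,
    spacing: float = 0.8,
) -> AtomSet:
    """A dense rectangular slab below the xy-plane (z from z_top−thickness to
    z_top), occluding roughly the lower hemisphere as seen from the origin."""
    xs = np.arange(-extent, extent + spacing, spacing)
    zs = np.arange(z_top - thickness, z_top + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    atoms = [Atom("W", i + 1, "", "UNK", "O", "O", p) for i, p in enumerate(pts)]
    return Structure(atoms, source="<wall>").all_atoms()
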