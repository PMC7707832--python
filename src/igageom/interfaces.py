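"""Contacts, interaction typing, SASA, buried-interface area, sequon scan.

Solvent-accessible surface area uses the Shrake–Rupley numerical method with
a deterministic golden-spiral point set, probe radius 1.4 Å and the Bondi
(1964) van der Waals radii.  Interface areas follow the PISA convention:
half the SASA buried when the two selections are paired *in isolation*,

    ½ · (SASA(A) + SASA(B) − SASA(A ∪ B)).

Contacts use a residue-level 7 Å heavy-atom criterion; typed interactions
use heavy-atom distance rules only (disulfide Sγ–Sγ ≤ 2.3 Å, salt bridge
basic-N to acidic-O ≤ 4 Å, hydrogen bond N/O–N/O ≤ 3.5 Å without an angle
term — deposited cryo-EM models carry no hydrogens) within a 4 Å validation
shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fab_sampler import fibonacci_lattice
from .structure_io import AtomSet

__all__ = [
    "ContactRecord",
    "InteractionRecord",
    "SASAResult",
    "BONDI_RADII",
    "contact_residues",
    "classify_interactions",
    "sasa",
    "interface_area",
    "occlusion_fraction",
    "find_sequons",
]

# Bondi (1964) van der Waals radii, Å; fallback used for unlisted elements
# only when explicitly allowed.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
    "Zn": 1.39, "Mg": 1.73, "Na": 2.27, "K": 2.75, "Ca": 2.31, "Fe": 1.63,
}
RADII_SET_NAME = "bondi64"

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

DISULFIDE_CUTOFF = 2.3
SALT_BRIDGE_CUTOFF = 4.0
HBOND_CUTOFF = 3.5
INTERACTION_SHELL = 4.0

# Side-chain atoms carrying formal charge at physiological pH
_BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class ResidueKey:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str

    def sort_key(self):
        return (self.chain_id, self.res_seq, self.icode)


@dataclass(frozen=True)
class ContactRecord:
    """A residue pair with at least one heavy-atom pair within the cutoff."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float
    atom_a: str
    atom_b: str


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # hydrogen_bond | salt_bridge | disulfide | nonspecific
    residue_a: ResidueKey
    residue_b: ResidueKey
    atom_a: str
    atom_b: str
    distance: float


@dataclass
class SASAResult:
    """Per-atom accessible areas (Å²) plus the parameters that produced them."""

    atom_areas: np.ndarray
    indices: np.ndarray  # structure indices, parallel to atom_areas
    probe: float
    n_points: int
    radii_set: str = RADII_SET_NAME
    residue_areas: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    def selection_area(self, subset: AtomSet) -> float:
        """Sum of areas over atoms of ``subset`` (must be within the computed set)."""
        pos = {int(i): k for k, i in enumerate(self.indices)}
        return float(sum(self.atom_areas[pos[int(i)]] for i in subset.indices if int(i) in pos))


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _residue_key(sel: AtomSet, local_i: int) -> ResidueKey:
    s = sel.structure
    g = sel.indices[local_i]
    return ResidueKey(s.chain_ids[g], int(s.res_seqs[g]), s.icodes[g], s.res_names[g])


def _heavy(sel: AtomSet) -> AtomSet:
    return sel.subset(~sel.structure.is_hydrogen[sel.indices])


def contact_residues(
    selA: AtomSet, selB: AtomSet, cutoff: float = 7.0
) -> list[ContactRecord]:
    """All residue pairs of A×B with any heavy-atom pair within ``cutoff`` Å.

    KD-tree accelerated but contractually identical to the all-pairs search.
    Each record carries the minimum inter-atom distance and the atom pair
    achieving it; records are ordered lexicographically by (chain, residue).
    """
    if selA.intersects(selB):
        raise ValueError("contact_residues: selections overlap")
    a, b = _heavy(selA), _heavy(selB)
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a.coords), cKDTree(b.coords)
    pairs = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")
    best: dict[tuple, tuple[float, int, int]] = {}
    for ia, ib, d in zip(pairs.row, pairs.col, pairs.data):
        ka, kb = _residue_key(a, ia), _residue_key(b, ib)
        key = (ka, kb)
        if key not in best or d < best[key][0]:
            best[key] = (float(d), int(ia), int(ib))
    sa, sb = a.structure, b.structure
    records = [
        ContactRecord(
            residue_a=ka,
            residue_b=kb,
            min_distance=d,
            atom_a=sa.atom_names[a.indices[ia]],
            atom_b=sb.atom_names[b.indices[ib]],
        )
        for (ka, kb), (d, ia, ib) in best.items()
    ]
    records.sort(key=lambda r: (r.residue_a.sort_key(), r.residue_b.sort_key()))
    return records


def classify_interactions(
    selA: AtomSet, selB: AtomSet, contacts: list[ContactRecord]
) -> list[InteractionRecord]:
    """Type all atom-pair interactions within 4 Å for the contacting residues.

    Priority: disulfide > salt_bridge > hydrogen_bond > nonspecific; one
    record per residue pair and kind (the closest qualifying atom pair).
    """
    a, b = _heavy(selA), _heavy(selB)
    sa, sb = a.structure, b.structure
    contact_pairs = {(c.residue_a, c.residue_b) for c in contacts}
    ta, tb = cKDTree(a.coords), cKDTree(b.coords)
    pairs = ta.sparse_distance_matrix(tb, INTERACTION_SHELL, output_type="coo_matrix")

    best: dict[tuple, InteractionRecord] = {}
    for ia, ib, d in zip(pairs.row, pairs.col, pairs.data):
        ka, kb = _residue_key(a, int(ia)), _residue_key(b, int(ib))
        if contact_pairs and (ka, kb) not in contact_pairs:
            continue
        ga, gb = a.indices[int(ia)], b.indices[int(ib)]
        na, nb = sa.atom_names[ga], sb.atom_names[gb]
        ea, eb = sa.elements[ga], sb.elements[gb]
        d = float(d)
        if (ka.res_name == "CYS" and kb.res_name == "CYS"
                and na == "SG" and nb == "SG" and d <= DISULFIDE_CUTOFF):
            kind = "disulfide"
        elif d <= SALT_BRIDGE_CUTOFF and (
            ((ka.res_name, na) in _BASIC_ATOMS and ((kb.res_name, nb) in _ACIDIC_ATOMS or nb == "OXT"))
            or ((kb.res_name, nb) in _BASIC_ATOMS and ((ka.res_name, na) in _ACIDIC_ATOMS or na == "OXT"))
        ):
            kind = "salt_bridge"
        elif d <= HBOND_CUTOFF and ea in ("N", "O") and eb in ("N", "O"):
            kind = "hydrogen_bond"
        else:
            kind = "nonspecific"
        key = (ka, kb, kind)
        if key not in best or d < best[key].distance:
            best[key] = InteractionRecord(
                kind=kind, residue_a=ka, residue_b=kb, atom_a=na, atom_b=nb, distance=d
            )
    out = list(best.values())
    order = {"disulfide": 0, "salt_bridge": 1, "hydrogen_bond": 2, "nonspecific": 3}
    out.sort(key=lambda r: (order[r.kind], r.residue_a.sort_key(), r.residue_b.sort_key()))
    return out


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _radii_for(elements: np.ndarray, fallback: float | None) -> np.ndarray:
    radii = np.empty(len(elements))
    missing = []
    for i, el in enumerate(elements):
        el_norm = el.capitalize() if len(el) > 1 else el.upper()
        r = BONDI_RADII.get(el_norm)
        if r is None:
            if fallback is None:
                missing.append(el)
                r = np.nan
            else:
                r = fallback
        radii[i] = r
    if missing:
        raise ValueError(
            f"no van der Waals radius for element(s) {sorted(set(missing))}; "
            "pass fallback_radius to use a default"
        )
    return radii


def sasa(
    atoms: AtomSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = False,
    fallback_radius: float | None = None,
) -> SASAResult:
    """Shrake–Rupley SASA of a selection, deterministic for fixed n_points.

    Each atom is expanded to radius r_vdw + probe and sampled at ``n_points``
    golden-spiral sphere points; a point is accessible when outside every
    neighbouring expanded sphere.  Per-atom area = (accessible fraction) ×
    4π(r+probe)².  Only the atoms *in the selection* are reported, and only
    they shadow each other: pass the full environment to measure areas in
    context.
    """
    sel = atoms if include_hydrogens else _heavy(atoms)
    coords = sel.coords
    n = coords.shape[0]
    if n == 0:
        return SASAResult(np.empty(0), np.empty(0, int), probe, n_points)
    radii = _radii_for(sel.elements, fallback_radius) + probe
    sphere = fibonacci_lattice(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=2)
            buried = (d < radii[neigh][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    res = SASAResult(areas, sel.indices.copy(), probe, n_points)
    s = sel.structure
    for k, g in enumerate(sel.indices):
        key = (s.chain_ids[g], int(s.res_seqs[g]), s.icodes[g])
        res.residue_areas[key] = res.residue_areas.get(key, 0.0) + areas[k]
    return res


def interface_area(selA: AtomSet, selB: AtomSet, **sasa_kw) -> float:
    """Buried interface area (Å²) between two disjoint selections.

    PISA convention, computed on the isolated pair:
    ½ (SASA(A) + SASA(B) − SASA(A∪B)).  Symmetric and non-negative up to
    point-sampling noise (clamped at 0).
    """
    if selA.intersects(selB):
        raise ValueError("interface_area: selections overlap")
    area_a = sasa(selA, **sasa_kw).total
    area_b = sasa(selB, **sasa_kw).total
    area_ab = sasa(selA.union(selB), **sasa_kw).total
    return max(0.0, 0.5 * (area_a + area_b - area_ab))


def occlusion_fraction(core: AtomSet, occluder: AtomSet, **sasa_kw) -> float:
    """Fraction of the core's isolated SASA buried by the occluder, in [0,1]."""
    if core.intersects(occluder):
        raise ValueError("occlusion_fraction: selections overlap")
    alone = sasa(core, **sasa_kw).total
    if alone == 0:
        raise ValueError("occlusion_fraction: core has zero accessible area")
    together = sasa(core.union(occluder), **sasa_kw)
    in_context = together.selection_area(core)
    return float(np.clip((alone - in_context) / alone, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Sequon scan
# ---------------------------------------------------------------------------

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


def find_sequons(sequence: str) -> list[int]:
    """0-based positions of N-X-S/T sequons (X ≠ P) — potential N-linked
    glycosylation sites.  Overlapping sequons are all reported."""
    seq = sequence.upper()
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"invalid amino-acid letters: {sorted(bad)}")
    return [
        i for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T")
    ]
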