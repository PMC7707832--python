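"""Atomic-structure I/O and named domain selections.

This module owns the in-memory coordinate container used by the rest of the
package, reading/writing of PDB and mmCIF files (backed by gemmi), and the
domain-configuration format that maps names such as ``Fc_AB`` or ``SC_D1`` to
chain + residue-range selections.  Selections use author residue numbering
throughout, and residue ranges are inclusive on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "AtomSet",
    "Structure",
    "DomainSpec",
    "DomainMap",
    "StructureParseError",
    "SelectionError",
    "ConfigError",
    "read_structure",
    "write_structure",
    "write_models",
    "select",
    "load_domain_config",
    "save_domain_config",
    "default_domain_config",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

ROLE_TAGS = frozenset({"pivot", "cdr", "linker", "core"})


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class SelectionError(KeyError):
    """Raised when a domain selection cannot be resolved on a structure."""


class ConfigError(ValueError):
    """Raised for malformed domain-configuration files."""


@dataclass(frozen=True)
class Atom:
    """A single atom record (author numbering, Å coordinates)."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom coordinate must be a finite 3-vector, got {coord!r}")
        object.__setattr__(self, "coord", coord)
        if not self.element:
            raise ValueError("atom element must be non-empty after inference")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


class Structure:
    """An ordered collection of atoms grouped into chains and residues.

    Internally the fields are stored as parallel numpy arrays so that the
    geometry, SASA and clash machinery can operate vectorised; ``Atom`` views
    are materialised on demand.
    """

    def __init__(self, atoms: Iterable[Atom], source: str = "<memory>", format: str = "memory"):
        atoms = list(atoms)
        self.source = source
        self.format = format
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.res_seqs = np.array([a.res_seq for a in atoms], dtype=int)
        self.icodes = np.array([a.icode for a in atoms], dtype=object)
        self.res_names = np.array([a.res_name for a in atoms], dtype=object)
        self.atom_names = np.array([a.atom_name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.coords = (
            np.array([a.coord for a in atoms], dtype=float) if atoms else np.empty((0, 3))
        )
        self.occupancies = np.array([a.occupancy for a in atoms], dtype=float)
        self.is_hydrogen = np.array([a.is_hydrogen for a in atoms], dtype=bool)

    def __len__(self) -> int:
        return len(self.chain_ids)

    def atom(self, i: int) -> Atom:
        return Atom(
            chain_id=self.chain_ids[i],
            res_seq=int(self.res_seqs[i]),
            icode=self.icodes[i],
            res_name=self.res_names[i],
            atom_name=self.atom_names[i],
            element=self.elements[i],
            coord=self.coords[i].copy(),
            occupancy=float(self.occupancies[i]),
            is_hydrogen=bool(self.is_hydrogen[i]),
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(len(self))]

    @property
    def chains(self) -> dict[str, np.ndarray]:
        """Chain id -> atom indices, preserving file order."""
        out: dict[str, np.ndarray] = {}
        for cid in dict.fromkeys(self.chain_ids.tolist()):
            out[cid] = np.flatnonzero(self.chain_ids == cid)
        return out

    def all_atoms(self) -> "AtomSet":
        return AtomSet(self, np.arange(len(self)))

    def find_atom(
        self, chain_id: str, res_seq: int, atom_name: str, icode: str = ""
    ) -> int:
        """Index of a single atom addressed by chain/residue/name."""
        mask = (
            (self.chain_ids == chain_id)
            & (self.res_seqs == res_seq)
            & (self.atom_names == atom_name)
            & (self.icodes == icode)
        )
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise SelectionError(
                f"address {chain_id}/{res_seq}{icode}/{atom_name} resolves to "
                f"{idx.size} atoms (need exactly 1)"
            )
        return int(idx[0])


@dataclass(frozen=True)
class AtomSet:
    """A view onto a subset of a Structure's atoms (indices into the parent)."""

    structure: Structure
    indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords[self.indices]

    @property
    def elements(self) -> np.ndarray:
        return self.structure.elements[self.indices]

    @property
    def residue_ids(self) -> list[tuple[str, int, str]]:
        s = self.structure
        return [
            (s.chain_ids[i], int(s.res_seqs[i]), s.icodes[i]) for i in self.indices
        ]

    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("centroid of empty selection")
        return self.coords.mean(axis=0)

    def union(self, other: "AtomSet") -> "AtomSet":
        if other.structure is not self.structure:
            raise ValueError("AtomSet union requires the same parent structure")
        return AtomSet(
            self.structure, np.unique(np.concatenate([self.indices, other.indices]))
        )

    def intersects(self, other: "AtomSet") -> bool:
        return bool(np.intersect1d(self.indices, other.indices).size)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(self.structure, self.indices[np.asarray(mask, bool)])


@dataclass(frozen=True)
class DomainSpec:
    """A named selection: inclusive (chain, first_res, last_res) ranges.

    Each range may carry a role tag used by the Fab sampler (``pivot``,
    ``cdr``, ``linker``) or ``core``; untagged ranges default to ``core``.
    """

    name: str
    selections: tuple[tuple[str, int, int], ...]
    roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.selections:
            raise ConfigError(f"domain {self.name!r}: at least one range required")
        roles = self.roles or tuple("core" for _ in self.selections)
        if len(roles) != len(self.selections):
            raise ConfigError(f"domain {self.name!r}: one role per range required")
        for role in roles:
            if role not in ROLE_TAGS:
                raise ConfigError(f"domain {self.name!r}: unknown role {role!r}")
        for chain, first, last in self.selections:
            if last < first:
                raise ConfigError(
                    f"domain {self.name!r}: range {chain}:{first}-{last} has last < first"
                )
        object.__setattr__(self, "selections", tuple(map(tuple, self.selections)))
        object.__setattr__(self, "roles", tuple(roles))

    def ranges_with_role(self, role: str) -> tuple[tuple[str, int, int], ...]:
        return tuple(s for s, r in zip(self.selections, self.roles) if r == role)

    def has_fab_roles(self) -> bool:
        return any(r in ("pivot", "cdr", "linker") for r in self.roles)


@dataclass
class DomainMap:
    """A collection of uniquely named DomainSpecs."""

    domains: dict[str, DomainSpec] = field(default_factory=dict)

    def __getitem__(self, name: str) -> DomainSpec:
        try:
            return self.domains[name]
        except KeyError:
            raise SelectionError(
                f"domain {name!r} not in config (have: {sorted(self.domains)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    def add(self, spec: DomainSpec) -> None:
        if spec.name in self.domains:
            raise ConfigError(f"duplicate domain name {spec.name!r}")
        self.domains[spec.name] = spec


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, res_name: str) -> str:
    """Element from a PDB atom name, for records with a blank element field."""
    name = atom_name.strip()
    if not name:
        return ""
    # Two-letter elements in common residues are rare; digits and remoteness
    # letters are stripped, the leading letter wins (CA -> C, NZ -> N, SG -> S).
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    first = stripped[0].upper()
    if first in "HDT" and res_name not in WATER_NAMES:
        return "H"
    if stripped[:2].upper() in ("FE", "ZN", "MG", "MN", "CL", "BR", "NA", "SE"):
        return stripped[:2].capitalize()
    return first


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_waters: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Only the first model is read.  For alternate locations the highest-
    occupancy conformer is kept (ties broken by altloc identifier order).
    Waters are excluded unless ``include_waters``; hydrogens are kept but
    flagged so downstream geometry can ignore them.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in file")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if not include_waters and res.name in WATER_NAMES:
                continue
            # altloc resolution: highest occupancy wins, ties by altloc order
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = min(group, key=lambda a: (-a.occ, a.altloc))
                element = at.element.name if at.element.name else ""
                if not element or element == "X":
                    element = _infer_element(name, res.name)
                    if element:
                        warnings.warn(
                            f"{path.name}: element inferred from atom name "
                            f"{name!r} in {chain.name}/{res.seqid.num}",
                            stacklevel=2,
                        )
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        res_name=res.name,
                        atom_name=name,
                        element=element,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        is_hydrogen=element in ("H", "D"),
                    )
                )
    return Structure(atoms, source=str(path), format=fmt)


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "igageom"
    for m, s in enumerate(structures, start=1):
        model = gemmi.Model(m)
        for cid, idx in s.chains.items():
            chain = gemmi.Chain(cid)
            # gemmi containers copy on add: build each residue fully first
            groups: list[list[int]] = []
            res_key = None
            for i in idx:
                key = (int(s.res_seqs[i]), s.icodes[i], s.res_names[i])
                if key != res_key:
                    groups.append([])
                    res_key = key
                groups[-1].append(i)
            for grp in groups:
                i0 = grp[0]
                res = gemmi.Residue()
                res.name = s.res_names[i0]
                res.seqid = gemmi.SeqId(int(s.res_seqs[i0]), s.icodes[i0] or " ")
                for i in grp:
                    at = gemmi.Atom()
                    at.name = s.atom_names[i]
                    at.element = gemmi.Element(s.elements[i])
                    x, y, z = s.coords[i]
                    at.pos = gemmi.Position(float(x), float(y), float(z))
                    at.occ = float(s.occupancies[i])
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure to PDB or mmCIF (format from extension when auto)."""
    write_models([structure], path, format=format)


def write_models(
    structures: Sequence[Structure], path: str | Path, format: str = "auto"
) -> None:
    """Write one or more structures; multiple become MODEL/ENDMDL records."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(structures)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(structure: Structure, spec: DomainSpec, atom_filter: str = "all") -> AtomSet:
    """Atoms of ``structure`` falling in any of the spec's ranges.

    atom_filter: ``all`` | ``heavy`` (non-hydrogen) | ``ca`` (Cα only).
    Raises SelectionError when a named chain is absent; an empty result is
    allowed but warned about.
    """
    if atom_filter not in ("all", "heavy", "ca"):
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    present = set(structure.chain_ids.tolist())
    mask = np.zeros(len(structure), dtype=bool)
    for chain, first, last in spec.selections:
        if chain not in present:
            raise SelectionError(
                f"domain {spec.name!r}: chain {chain!r} absent from "
                f"{structure.source} (chains: {sorted(present)})"
            )
        mask |= (
            (structure.chain_ids == chain)
            & (structure.res_seqs >= first)
            & (structure.res_seqs <= last)
        )
    if atom_filter == "heavy":
        mask &= ~structure.is_hydrogen
    elif atom_filter == "ca":
        mask &= (structure.atom_names == "CA") & ~structure.is_hydrogen
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {spec.name!r} is empty on {structure.source}", stacklevel=2)
    return AtomSet(structure, idx)


# ---------------------------------------------------------------------------
# Domain configuration
# ---------------------------------------------------------------------------

def _parse_ranges(name: str, entries) -> DomainSpec:
    if not isinstance(entries, list):
        raise ConfigError(f"domain {name!r}: 'ranges' must be a list")
    selections, roles = [], []
    for e in entries:
        try:
            selections.append((str(e["chain"]), int(e["first"]), int(e["last"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"domain {name!r}: bad range entry {e!r}") from exc
        roles.append(str(e.get("role", "core")))
    spec = DomainSpec(name=name, selections=tuple(selections), roles=tuple(roles))
    if spec.has_fab_roles():
        pivots = spec.ranges_with_role("pivot")
        cdrs = spec.ranges_with_role("cdr")
        if len(pivots) != 1:
            raise ConfigError(
                f"Fab domain {name!r}: exactly one pivot range required, got {len(pivots)}"
            )
        chain, first, last = pivots[0]
        if first != last:
            raise ConfigError(
                f"Fab domain {name!r}: pivot range must be a single residue "
                f"(the amino-terminal residue of C_H2), got {first}-{last}"
            )
        if not cdrs:
            raise ConfigError(f"Fab domain {name!r}: at least one cdr range required")
    return spec


def load_domain_config(path: str | Path) -> DomainMap:
    """Load a YAML domain config (top-level key ``domains``)."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(payload, dict) or "domains" not in payload:
        raise ConfigError(f"{path}: config must have a top-level 'domains' mapping")
    dmap = DomainMap()
    for name, body in payload["domains"].items():
        if not isinstance(body, dict):
            raise ConfigError(f"domain {name!r}: expected a mapping with 'ranges'")
        dmap.add(_parse_ranges(str(name), body.get("ranges")))
    return dmap


def save_domain_config(dmap: DomainMap, path: str | Path) -> None:
    payload = {
        "domains": {
            name: {
                "ranges": [
                    {"chain": c, "first": f, "last": l, "role": r}
                    for (c, f, l), r in zip(spec.selections, spec.roles)
                ]
            }
            for name, spec in dmap.domains.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_domain_config() -> DomainMap:
    """The shipped default domain map for the deposited SIgA/dIgA models.

    Chain naming (heavy chains A-D, JC on chain J, SC on chain S) follows the
    structures' published nomenclature; verify against your local copies of
    the deposited files and override with your own config if they differ.
    """
    with resources.files("igageom.data").joinpath("domains_siga.yaml").open() as fh:
        payload = yaml.safe_load(fh)
    dmap = DomainMap()
    for name, body in payload["domains"].items():
        dmap.add(_parse_ranges(str(name), body.get("ranges")))
    return dmap
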