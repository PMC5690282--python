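"""Structure I/O, coordinate bookkeeping, rigid transforms and superposition.

Geometry is handled at the residue (Cα) level throughout the package;
author chain identifiers and author residue numbers (with insertion codes)
are the single coordinate system.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RigidTransform",
    "Assembly",
    "StructureError",
    "read_structure",
    "write_structure",
    "ca_distance",
    "superpose",
    "radius_of_gyration",
]


class StructureError(ValueError):
    """Raised for unreadable files, missing atoms/residues or degenerate input."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # Å, shape (3,)
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    number: int  # author residue number
    icode: str  # insertion code, "" if absent
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name} {self.number}{self.icode}: no atom {name!r}")

    @property
    def ca(self) -> Atom:
        return self.atom("CA")


class Structure:
    """An ordered set of chains of residues with atomic coordinates in Å."""

    def __init__(self, id: str = "", chains: dict[str, list[Residue]] | None = None):
        self.id = id
        # chain label -> ordered residue list
        self.chains: dict[str, list[Residue]] = chains or {}
        self._check()

    def _check(self) -> None:
        for label, residues in self.chains.items():
            seen: set[tuple[int, str]] = set()
            for res in residues:
                if res.key in seen:
                    raise StructureError(
                        f"chain {label}: duplicate residue {res.number}{res.icode}"
                    )
                seen.add(res.key)

    # -- lookups ------------------------------------------------------------

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        try:
            residues = self.chains[chain]
        except KeyError:
            raise StructureError(f"no chain {chain!r} in structure {self.id!r}") from None
        for res in residues:
            if res.number == number and res.icode == icode:
                return res
        raise StructureError(f"no residue {number}{icode} in chain {chain} of {self.id!r}")

    def ca_coord(self, chain: str, number: int, icode: str = "") -> np.ndarray:
        res = self.residue(chain, number, icode)
        try:
            return res.ca.coord
        except StructureError:
            raise StructureError(
                f"residue {res.name} {chain}:{number}{icode} has no Cα atom"
            ) from None

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        """All Cα coordinates, shape (n, 3), in chain/residue order."""
        coords = []
        for label, residues in self.chains.items():
            if chain is not None and label != chain:
                continue
            for res in residues:
                for a in res.atoms:
                    if a.name == "CA":
                        coords.append(a.coord)
                        break
        if not coords:
            raise StructureError(f"no Cα atoms in structure {self.id!r}")
        return np.array(coords)

    def all_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for residues in self.chains.values() for r in residues for a in r.atoms]
        )

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for residues in self.chains.values() for r in residues)

    @property
    def n_residues(self) -> int:
        return sum(len(residues) for residues in self.chains.values())

    def transformed(self, transform: "RigidTransform") -> "Structure":
        """A copy with every atom coordinate mapped through ``transform``."""
        chains = {
            label: [
                Residue(
                    r.number,
                    r.icode,
                    r.name,
                    [Atom(a.name, a.element, transform.apply(a.coord), a.occupancy, a.b_factor)
                     for a in r.atoms],
                )
                for r in residues
            ]
            for label, residues in self.chains.items()
        }
        return Structure(self.id, chains)

    def info(self) -> dict:
        """Chains and residue ranges, JSON-serializable."""
        out = {"id": self.id, "n_atoms": self.n_atoms, "chains": {}}
        for label, residues in self.chains.items():
            numbers = [r.number for r in residues]
            out["chains"][label] = {
                "n_residues": len(residues),
                "first": min(numbers),
                "last": max(numbers),
            }
        return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise StructureError("RigidTransform: rotation must be 3x3, translation 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise StructureError("RigidTransform: rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class AssemblyComponent:
    label: str
    structure: Structure
    transform: RigidTransform
    role: str = "receptor"  # receptor | mobile


class Assembly:
    """Ordered components, each a Structure with a rigid transform and role tag."""

    def __init__(self, components: list[AssemblyComponent]):
        labels = [c.label for c in components]
        if len(set(labels)) != len(labels):
            raise StructureError("assembly component labels must be unique")
        if sum(1 for c in components if c.role == "mobile") > 1:
            raise StructureError("at most one component may be tagged mobile")
        self.components = list(components)

    def __getitem__(self, label: str) -> AssemblyComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise StructureError(f"no component {label!r} in assembly")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    def component_for_chain(self, chain: str) -> AssemblyComponent:
        hits = [c for c in self.components if chain in c.structure.chains]
        if not hits:
            raise StructureError(f"no component contains chain {chain!r}")
        if len(hits) > 1:
            raise StructureError(f"chain {chain!r} is ambiguous across components")
        return hits[0]

    def ca_coord(self, chain: str, number: int, icode: str = "") -> np.ndarray:
        comp = self.component_for_chain(chain)
        return comp.transform.apply(comp.structure.ca_coord(chain, number, icode))

    def transformed_structures(self) -> list[tuple[str, Structure]]:
        return [(c.label, c.structure.transformed(c.transform)) for c in self.components]

    def with_transform(self, label: str, transform: RigidTransform) -> "Assembly":
        """A copy where component ``label`` carries ``transform`` instead."""
        comps = [
            AssemblyComponent(c.label, c.structure, transform if c.label == label else c.transform,
                              c.role)
            for c in self.components
        ]
        return Assembly(comps)

    def flatten(self, id: str = "assembly") -> Structure:
        """Merge all components into one Structure in current coordinates.

        Receptor components keep their chain labels; colliding labels from
        other components are remapped alphabetically to unused letters.
        """
        used: set[str] = set()
        chains: dict[str, list[Residue]] = {}
        alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
        for comp in self.components:
            moved = comp.structure.transformed(comp.transform)
            for label, residues in moved.chains.items():
                new_label = label
                if new_label in used:
                    for cand in alphabet:
                        if cand not in used:
                            new_label = cand
                            break
                    else:
                        raise StructureError("ran out of chain labels while flattening")
                used.add(new_label)
                chains[new_label] = residues
        return Structure(id, chains)


# ---------------------------------------------------------------------------
# I/O

def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a structure file, preserving author numbering and insertion codes."""
    if format != "pdb":
        raise StructureError(f"unknown format {format!r}; only 'pdb' is supported")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, extra_fields=["occupancy", "b_factor"])
    except Exception as exc:  # biotite raises a mix of error types
        raise StructureError(f"could not parse {path} as PDB: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no atoms found")

    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    current_chain = None
    for i in range(atoms.array_length()):
        chain_id = str(atoms.chain_id[i])
        key = (int(atoms.res_id[i]), str(atoms.ins_code[i]).strip())
        if current is None or chain_id != current_chain or current.key != key:
            current = Residue(key[0], key[1], str(atoms.res_name[i]))
            chains.setdefault(chain_id, []).append(current)
            current_chain = chain_id
        current.atoms.append(
            Atom(
                name=str(atoms.atom_name[i]),
                element=str(atoms.element[i]),
                coord=atoms.coord[i].astype(float),
                occupancy=float(atoms.occupancy[i]),
                b_factor=float(atoms.b_factor[i]),
            )
        )
    return Structure(path.stem, chains)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB; round-trips coordinates to 3 decimals."""
    if structure.n_atoms == 0:
        raise StructureError("cannot write an empty structure")
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.add_annotation("occupancy", float)
    arr.add_annotation("b_factor", float)
    i = 0
    for chain_label, residues in structure.chains.items():
        for res in residues:
            for a in res.atoms:
                arr.chain_id[i] = chain_label
                arr.res_id[i] = res.number
                arr.ins_code[i] = res.icode
                arr.res_name[i] = res.name
                arr.atom_name[i] = a.name
                arr.element[i] = a.element
                arr.hetero[i] = False
                arr.coord[i] = a.coord
                arr.occupancy[i] = a.occupancy
                arr.b_factor[i] = a.b_factor
                i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    path = Path(path)
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Geometry

Site = tuple[str, int]


def ca_distance(obj: Structure | Assembly, site_a: Site, site_b: Site) -> float:
    """Cα–Cα distance in Å between two (chain, residue number) sites."""

    def coord(site: Site) -> np.ndarray:
        chain, number = site
        try:
            return obj.ca_coord(chain, number)
        except StructureError as exc:
            raise StructureError(f"site {chain}:{number}: {exc}") from exc

    return float(np.linalg.norm(coord(site_a) - coord(site_b)))


def superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Kabsch-optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform minimizing RMSD and the minimized RMSD itself.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise StructureError("superpose: point sets must be equal-length (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise StructureError("superpose: need at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of either centered set < 2
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise StructureError("superpose: degenerate (collinear) point set")
    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mob) - ref) ** 2, axis=1))))
    return transform, rmsd


def radius_of_gyration(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration in Å."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise StructureError("radius_of_gyration: empty point set")
    coords = coords.reshape(-1, 3)
    if weights is None:
        weights = np.ones(len(coords))
    weights = np.asarray(weights, dtype=float)
    center = np.average(coords, axis=0, weights=weights)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=weights)))


def structure_info_json(structure: Structure) -> str:
    return json.dumps(structure.info(), indent=2, sort_keys=True)
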