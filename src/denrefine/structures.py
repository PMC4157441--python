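"""Coordinate model types and fixed-column PDB reading/writing.

The dialect is a deliberate subset of PDB v3.3: only ATOM, HETATM, CRYST1,
TER and END records are interpreted; everything else is ignored.  Coordinates
are Cartesian Å throughout the package; fractional coordinates appear only
inside structure-factor computation.  Residue indices are 0-based and
sequential within each chain (gap-free), independent of the author residue
numbers, which are kept only for output.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import element_data, UnknownElementError


class PDBFormatError(ValueError):
    """Malformed or empty PDB content."""


@dataclass
class UnitCell:
    """P1 unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def orth_matrix(self) -> np.ndarray:
        """Orthogonalization matrix M with x_cart = M @ x_frac (PDB convention)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    def frac_matrix(self) -> np.ndarray:
        """Fractionalization matrix, inverse of :meth:`orth_matrix`."""
        return np.linalg.inv(self.orth_matrix())

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth_matrix())))

    def inv_d2(self, hkl: np.ndarray) -> np.ndarray:
        """1/d² for Miller indices (…, 3) via the reciprocal metric tensor."""
        frac = self.frac_matrix()
        gstar = frac @ frac.T  # reciprocal metric
        h = np.asarray(hkl, dtype=float)
        return np.einsum("...i,ij,...j->...", h, gstar, h)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int      # 0-based, sequential within chain
    residue_name: str
    chain_id: str
    position: np.ndarray    # shape (3,), Å
    b_factor: float = 20.0  # Å²
    occupancy: float = 1.0
    auth_resseq: int | None = None  # author residue number, output only

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.b_factor < 0:
            raise ValueError("b_factor must be non-negative")
        element_data(self.element)  # raises UnknownElementError if untabulated


@dataclass
class Structure:
    """An ordered collection of atoms with a P1 unit cell."""

    atoms: list[Atom]
    unit_cell: UnitCell

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, pos in zip(self.atoms, xyz):
            atom.position = pos.copy()

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(xyz)
        return out

    def copy(self) -> "Structure":
        return Structure(
            [replace(a, position=a.position.copy()) for a in self.atoms],
            replace(self.unit_cell),
        )

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.atoms])

    def set_b_factors(self, b: np.ndarray) -> None:
        for atom, bi in zip(self.atoms, np.asarray(b, dtype=float)):
            atom.b_factor = float(bi)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([element_data(a.element).mass for a in self.atoms])

    @property
    def chains(self) -> dict[str, list[list[Atom]]]:
        """chain_id → list of residues, each a list of atoms in file order."""
        out: dict[str, list[list[Atom]]] = {}
        for atom in self.atoms:
            residues = out.setdefault(atom.chain_id, [])
            if not residues or residues[-1][0].residue_index != atom.residue_index:
                residues.append([])
            residues[-1].append(atom)
        return out

    def chain_atom_indices(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            out.setdefault(atom.chain_id, []).append(i)
        return {cid: np.array(idx) for cid, idx in out.items()}


def default_box(coords: np.ndarray, padding: float = 10.0) -> UnitCell:
    """Synthesize a padded orthogonal P1 box around the coordinates."""
    span = coords.max(axis=0) - coords.min(axis=0)
    a, b, c = (float(s) + 2.0 * padding for s in span)
    return UnitCell(a, b, c)


def center_in_cell(structure: Structure) -> None:
    """Translate atoms so their bounding box is centered in the unit cell."""
    xyz = structure.coords
    mid = 0.5 * (xyz.max(axis=0) + xyz.min(axis=0))
    target = 0.5 * np.array(structure.unit_cell.lengths)
    structure.set_coords(xyz + (target - mid))


_ELEMENT_FROM_NAME = {"N": "N", "C": "C", "O": "O", "S": "S", "P": "P", "H": "H"}


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return _ELEMENT_FROM_NAME.get(ch.upper(), ch.upper())
    raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(path) -> Structure:
    """Read a Structure from a fixed-column PDB file.

    Raises :class:`PDBFormatError` (naming the offending line) on unparsable
    coordinate fields and on files with zero ATOM/HETATM records.  When no
    CRYST1 record is present a padded orthogonal box is synthesized.
    """
    atoms: list[Atom] = []
    cell: UnitCell | None = None
    # residue_index bookkeeping: restart at 0 for each chain, increment on
    # change of (auth residue number, residue name)
    last_key: tuple | None = None
    chain_counters: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    cell = UnitCell(
                        float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except ValueError as exc:
                    raise PDBFormatError(f"line {lineno}: bad CRYST1 record: {exc}")
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain_id = line[21]
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ = float(line[54:60]) if line[54:60].strip() else 1.0
                    b = float(line[60:66]) if line[60:66].strip() else 0.0
                except (ValueError, IndexError) as exc:
                    raise PDBFormatError(f"line {lineno}: unparsable record: {exc}")
                elem_field = line[76:78].strip() if len(line) >= 78 else ""
                element = elem_field if elem_field else _guess_element(name)
                key = (chain_id, resseq, resname)
                if key != last_key:
                    if chain_id in chain_counters:
                        chain_counters[chain_id] += 1
                    else:
                        chain_counters[chain_id] = 0
                    last_key = key
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_index=chain_counters[chain_id],
                        residue_name=resname,
                        chain_id=chain_id,
                        position=np.array([x, y, z]),
                        b_factor=b,
                        occupancy=occ,
                        auth_resseq=resseq,
                    )
                )
    if not atoms:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    if cell is None:
        cell = default_box(np.array([a.position for a in atoms]))
    return Structure(atoms, cell)


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-column PDB with a P1 CRYST1 record."""
    if len(structure) == 0:
        raise PDBFormatError("refusing to write an empty structure")
    xyz = structure.coords
    if np.any(xyz >= 10000.0) or np.any(xyz <= -1000.0):
        raise PDBFormatError("coordinate magnitude exceeds PDB field width")
    cell = structure.unit_cell
    lines = [
        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1"
        % (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    ]
    prev_chain = None
    serial = 0
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        serial += 1
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        resseq = atom.auth_resseq if atom.auth_resseq is not None else atom.residue_index + 1
        lines.append(
            "ATOM  %5d %4s %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
            % (
                serial % 100000, name, atom.residue_name[:3], atom.chain_id[:1],
                resseq % 10000, atom.position[0], atom.position[1], atom.position[2],
                atom.occupancy, atom.b_factor, atom.element.rjust(2),
            )
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
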