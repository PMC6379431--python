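"""Macromolecular coordinate I/O and ordered atom selections.

Reads PDB and mmCIF files through :mod:`gemmi`, keeps atoms in a flat,
explicitly ordered container (:class:`StructureModel`) indexed by author
chain id and author residue number, and writes standard PDB. Author
numbering is the canonical coordinate system throughout the toolkit,
because claudin residues (Pro134, Phe146, ...) are always cited in author
numbering. Only the first model of multi-model files is used.

Altloc policy for selections: the highest-occupancy conformer wins; ties
are broken lexicographically by altloc character. Hydrogens and waters are
never part of geometry selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    LookupError_,
    ParseError,
    ValidationError,
)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom as deposited: author numbering, altloc and B-factor kept."""

    chain_id: str
    residue_number: int
    insertion_code: str  # "" when absent
    residue_name: str
    atom_name: str
    altloc: str  # "" when absent
    occupancy: float
    b_factor: float
    position: np.ndarray  # shape (3,), Å
    element: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.atom_name} of {self.chain_id}{self.residue_number}: "
                "position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0.0:
            raise ValidationError(f"negative B-factor {self.b_factor}")

    @property
    def key(self) -> tuple:
        return (
            self.chain_id,
            self.residue_number,
            self.insertion_code,
            self.atom_name,
            self.altloc,
        )

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    def with_b_factor(self, b: float) -> "AtomRecord":
        return AtomRecord(
            self.chain_id,
            self.residue_number,
            self.insertion_code,
            self.residue_name,
            self.atom_name,
            self.altloc,
            self.occupancy,
            b,
            self.position.copy(),
            self.element,
        )


class StructureModel:
    """Ordered atom collection with a per-chain residue index.

    The tuple (chain_id, residue_number, insertion_code, atom_name, altloc)
    is unique across the model; residues within a chain are retrievable in
    ascending residue-number order.
    """

    def __init__(self, identifier: str, atoms: Iterable[AtomRecord]):
        self.identifier = identifier
        self.atoms: list[AtomRecord] = list(atoms)
        seen: set[tuple] = set()
        self._index: dict[str, dict[tuple[int, str], list[int]]] = {}
        for i, atom in enumerate(self.atoms):
            if atom.key in seen:
                raise ValidationError(f"duplicate atom key {atom.key}")
            seen.add(atom.key)
            self._index.setdefault(atom.chain_id, {}).setdefault(
                (atom.residue_number, atom.insertion_code), []
            ).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        return list(self._index)

    def has_chain(self, chain: str) -> bool:
        return chain in self._index

    def residue_numbers(self, chain: str) -> list[int]:
        """Distinct author residue numbers of a chain, ascending."""
        if chain not in self._index:
            raise LookupError_(f"chain {chain!r} not in {sorted(self._index)}")
        return sorted({num for num, _ in self._index[chain]})

    def residue_atoms(
        self, chain: str, residue_number: int, insertion_code: str = ""
    ) -> list[AtomRecord]:
        if chain not in self._index:
            raise LookupError_(f"chain {chain!r} not in {sorted(self._index)}")
        idx = self._index[chain].get((residue_number, insertion_code), [])
        return [self.atoms[i] for i in idx]

    def has_insertion_codes(self, chain: str, residue_range: tuple[int, int]) -> bool:
        lo, hi = residue_range
        return any(
            icode != "" and lo <= num <= hi for num, icode in self._index.get(chain, {})
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with every position mapped to R @ p + t (B-factors untouched)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            AtomRecord(
                a.chain_id,
                a.residue_number,
                a.insertion_code,
                a.residue_name,
                a.atom_name,
                a.altloc,
                a.occupancy,
                a.b_factor,
                R @ a.position + t,
                a.element,
            )
            for a in self.atoms
        ]
        return StructureModel(self.identifier, atoms)


@dataclass
class CalphaTrace:
    """Ordered Cα selection of one chain; gaps are reported, not silent."""

    chain_id: str
    residue_numbers: list[int]
    coords: np.ndarray  # (n, 3)
    missing: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def __iter__(self):
        return iter(zip(self.residue_numbers, self.coords))


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read all atoms of the first model block of a PDB or mmCIF file.

    ``format`` is one of ``pdb``, ``mmcif`` or ``auto`` (infer from the
    extension). Altloc records, author chain ids and author residue numbers
    are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format not in ("auto", *_FORMATS):
        raise ValidationError(f"unknown format {format!r}")
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model block")
    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            icode = residue.seqid.icode.strip()
            for atom in residue:
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=icode,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        altloc=atom.altloc if atom.altloc not in ("", " ", "\0") else "",
                        occupancy=min(max(float(atom.occ), 0.0), 1.0),
                        b_factor=max(float(atom.b_iso), 0.0),
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        element=atom.element.name,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms")
    identifier = st.name if st.name else path.stem
    return StructureModel(identifier, atoms)


def select_calpha(
    model: StructureModel, chain: str, residue_range: tuple[int, int]
) -> CalphaTrace:
    """Ordered Cα positions of a chain over an inclusive residue interval.

    One entry per residue possessing a Cα, ascending residue number. For
    multiple altlocs the highest-occupancy conformer is taken (tie: lowest
    altloc character). Residues in the range lacking a Cα are listed in
    ``missing``. Insertion codes inside the range are rejected: geometry
    ranges must be insertion-free.
    """
    if not model.has_chain(chain):
        raise LookupError_(f"chain {chain!r} not in {sorted(model.chains)}")
    lo, hi = residue_range
    if lo > hi:
        raise ValidationError(f"empty range {residue_range}")
    if model.has_insertion_codes(chain, residue_range):
        raise ValidationError(
            f"chain {chain} range {lo}-{hi} contains insertion codes; "
            "geometry ranges must be insertion-free"
        )
    numbers: list[int] = []
    coords: list[np.ndarray] = []
    missing: list[int] = []
    present = set(model.residue_numbers(chain))
    for num in range(lo, hi + 1):
        if num not in present:
            missing.append(num)
            continue
        cas = [
            a
            for a in model.residue_atoms(chain, num)
            if a.atom_name == "CA" and not a.is_water and not a.is_hydrogen
        ]
        if not cas:
            missing.append(num)
            continue
        best = max(cas, key=lambda a: (a.occupancy, _altloc_rank(a.altloc)))
        numbers.append(num)
        coords.append(best.position)
    if not numbers:
        raise EmptySelectionError(f"no Cα in chain {chain} range {lo}-{hi}")
    return CalphaTrace(chain, numbers, np.asarray(coords, dtype=float), missing)


def _altloc_rank(altloc: str) -> float:
    # Higher rank wins; blank altloc outranks 'A', which outranks 'B', ...
    return -ord(altloc) if altloc else 1.0


def sidechain_heavy_atoms(
    model: StructureModel, chain: str, residue_number: int
) -> list[AtomRecord]:
    """Side-chain heavy atoms of one residue (Cα fallback for glycine)."""
    atoms = [
        a
        for a in model.residue_atoms(chain, residue_number)
        if not a.is_hydrogen and not a.is_water and a.atom_name not in BACKBONE_ATOMS
    ]
    if not atoms:
        atoms = [
            a
            for a in model.residue_atoms(chain, residue_number)
            if a.atom_name == "CA" and not a.is_hydrogen
        ]
    return atoms


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write standard ATOM records (coordinates to 3 decimals, B to 2)."""
    if len(model) == 0:
        raise ValidationError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        if atom.chain_id not in chains:
            chains[atom.chain_id] = gemmi.Chain(atom.chain_id)
        chain = chains[atom.chain_id]
        if (
            len(chain) == 0
            or chain[-1].seqid.num != atom.residue_number
            or chain[-1].seqid.icode.strip() != atom.insertion_code
            or chain[-1].name != atom.residue_name
        ):
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_number, atom.insertion_code or " ")
            chain.add_residue(res)
        gatom = gemmi.Atom()
        gatom.name = atom.atom_name
        gatom.altloc = atom.altloc if atom.altloc else "\0"
        gatom.occ = atom.occupancy
        gatom.b_iso = atom.b_factor
        gatom.pos = gemmi.Position(*atom.position)
        gatom.element = gemmi.Element(atom.element or atom.atom_name[:1])
        chain[-1].add_atom(gatom)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise ClaudinkitIOError(f"cannot write {path}: {exc}") from exc


class ClaudinkitIOError(ParseError):
    """Unwritable or unreadable path."""
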