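"""Structure input: read PDB/mmCIF, filter to heavy atoms, select chains.

The in-memory :class:`StructureModel` is the geometric substrate for every
contact computation downstream.  Conventions applied on load:

* model 1 only (single crystal structure semantics);
* waters and hydrogens/deuteriums removed;
* alternate locations collapsed to the highest-occupancy conformer
  (ties broken by file order);
* HETATM polymer residues (e.g. selenomethionine) kept, free ligands
  dropped unless ``keep_ligands=True``;
* author chain/residue numbering (with insertion codes) is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

from .errors import (
    ChainNotFoundError,
    EmptyStructureError,
    ResidueNotFoundError,
    StructureFormatError,
)

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "StructureModel",
    "load_structure",
    "extract_chain_set",
    "residue_heavy_atoms",
]

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O", "D2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue: chain, number, insertion code, name."""

    chain_id: str
    seq_num: int
    icode: str = ""
    res_name: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_num}{self.icode}:{self.res_name}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        """Inverse of ``str()``: ``chain:number[icode]:name``."""
        chain, middle, name = text.split(":")
        num = middle
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        return cls(chain, int(num), icode, name)


@dataclass
class StructureModel:
    """Chains → residues → heavy atoms.

    ``chains`` maps chain id to an ordered mapping ResidueKey → atom list;
    insertion order follows the source file.
    """

    id: str
    chains: dict[str, dict[ResidueKey, list[AtomRecord]]] = field(default_factory=dict)
    resolution: float | None = None

    def residues(self) -> Iterable[ResidueKey]:
        for residues in self.chains.values():
            yield from residues

    def atoms_of(self, key: ResidueKey) -> list[AtomRecord]:
        try:
            return self.chains[key.chain_id][key]
        except KeyError:
            raise ResidueNotFoundError(
                f"residue {key} not present in structure {self.id!r}"
            ) from None

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(a) for r in self.chains.values() for a in r.values())


def _is_water(name: str) -> bool:
    if name in _WATER_NAMES:
        return True
    info = gemmi.find_tabulated_residue(name)
    return bool(info and info.is_water())


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return bool(info and info.is_amino_acid())


def _dedup_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, first on tie."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > best[atom.name].occupancy:
            best[atom.name] = atom
    return [best[n] for n in order]


def load_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    keep_ligands: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a filtered :class:`StructureModel`.

    Parameters
    ----------
    path : file path
    format : "pdb", "mmcif" or "auto" (detect from contents/extension)
    keep_ligands : retain non-water, non-polymer HETATM residues

    Raises
    ------
    StructureFormatError : the file cannot be parsed as the declared format.
    EmptyStructureError : nothing remains after filtering.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models found")

    model = StructureModel(
        id=st.name or path.stem,
        resolution=float(st.resolution) if st.resolution else None,
    )
    first = st[0]  # model 1 only
    for chain in first:
        residues: dict[ResidueKey, list[AtomRecord]] = {}
        for res in chain:
            name = res.name.strip()
            if _is_water(name):
                continue
            if res.het_flag == "H" and not _is_amino_acid(name) and not keep_ligands:
                continue
            atoms = [
                AtomRecord(
                    name=at.name,
                    element=at.element.name,
                    coord=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=float(at.occ),
                    altloc="" if at.altloc in ("\0", "\x00") else at.altloc,
                )
                for at in res
                if not at.element.is_hydrogen
            ]
            atoms = _dedup_altlocs(atoms)
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            key = ResidueKey(chain.name, res.seqid.num, icode, name)
            if key in residues:
                residues[key].extend(atoms)
            else:
                residues[key] = atoms
        if residues:
            model.chains.setdefault(chain.name, {}).update(residues)
    if model.n_atoms() == 0:
        raise EmptyStructureError(
            f"{path}: structure empty after removing waters/hydrogens/ligands"
        )
    return model


def extract_chain_set(model: StructureModel, chain_ids: set[str]) -> StructureModel:
    """Sub-model containing exactly the requested chains, atoms unchanged."""
    missing = set(chain_ids) - set(model.chains)
    if missing:
        raise ChainNotFoundError(
            f"chain(s) {sorted(missing)} not in structure {model.id!r}; "
            f"available: {sorted(model.chains)}"
        )
    return StructureModel(
        id=model.id,
        chains={c: dict(model.chains[c]) for c in model.chains if c in chain_ids},
        resolution=model.resolution,
    )


def residue_heavy_atoms(model: StructureModel, key: ResidueKey) -> list[AtomRecord]:
    """Heavy atoms of one residue, in stable file order."""
    return [a for a in model.atoms_of(key) if a.element.upper() not in ("H", "D")]
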