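"""Typed coordinate model: atoms, residues, chains, structures, entity typing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

# ---------------------------------------------------------------------------
# residue-name tables

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common nonstandard residues with a canonical parent
    "MSE": "M", "SEC": "U", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in (
    "MSE", "PYL", "HYP", "SEP", "TPO", "PTR", "CSO", "MLY")}

STANDARD_AMINO_ACIDS = frozenset(
    k for k in THREE_TO_ONE if k not in ("MSE", "SEC", "PYL", "HYP", "SEP", "TPO", "PTR", "CSO", "MLY")
)
PROTEIN_RESNAMES = frozenset(THREE_TO_ONE)

DNA_RESNAMES = frozenset({"DA", "DC", "DG", "DT", "DI", "DU"})
RNA_RESNAMES = frozenset({"A", "C", "G", "U", "I"})
METAL_RESNAMES = frozenset({"ZN", "MG", "FE", "FE2", "CA", "MN", "CU", "CU1", "NI", "CO", "CD", "HG", "MO", "W"})
ION_RESNAMES = frozenset({"NA", "K", "CL", "BR", "IOD", "F", "LI", "RB", "CS"})
WATER_RESNAMES = frozenset({"HOH", "DOD", "WAT"})

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C"})


def entity_type_of_resname(resname: str) -> str:
    """Total map from a chemical-component name to an entity type."""
    resname = resname.strip().upper()
    if resname in PROTEIN_RESNAMES:
        return "protein"
    if resname in DNA_RESNAMES:
        return "dna"
    if resname in RNA_RESNAMES:
        return "rna"
    if resname in METAL_RESNAMES:
        return "metal"
    if resname in ION_RESNAMES:
        return "ion"
    if resname in WATER_RESNAMES:
        return "water"
    return "ligand"


def classify_entity(resnames) -> str:
    """Majority-vote entity type of a chain from its residue names.

    Water never wins for a chain that also contains non-water residues.
    """
    resnames = list(resnames)
    if not resnames:
        raise ValueError("cannot classify an empty residue-name collection")
    votes: dict[str, int] = {}
    for rn in resnames:
        t = entity_type_of_resname(rn)
        votes[t] = votes.get(t, 0) + 1
    if len(votes) > 1 and "water" in votes:
        del votes["water"]
    # deterministic: ties broken by fixed precedence
    order = ("protein", "dna", "rna", "metal", "ion", "ligand", "water")
    return max(votes, key=lambda t: (votes[t], -order.index(t)))


# ---------------------------------------------------------------------------
# model dataclasses


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain_id: str
    resnum: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    is_hetatm: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS


@dataclass
class Residue:
    resnum: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.resnum, self.icode)

    @property
    def entity_type(self) -> str:
        return entity_type_of_resname(self.resname)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return any(a.name in BACKBONE_ATOMS for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def mainchain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_mainchain]

    def sidechain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_mainchain]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: (r.resnum, r.icode))

    @property
    def entity_type(self) -> str:
        if not self.residues:
            return "ligand"
        return classify_entity(r.resname for r in self.residues)

    @property
    def is_protein(self) -> bool:
        return self.entity_type == "protein"

    def residue(self, resnum: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.resnum == resnum and r.icode == icode:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    is_model: bool = False

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.entry_id}: {ids}")

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_protein]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def extract_atom_sequence(model: StructureModel, chain_id: str) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence of a protein chain from its coordinate records.

    Returns the sequence together with a positionally parallel list of
    ``(resnum, icode)`` keys.  Residue numbering gaps are preserved, never
    imputed.  Nonstandard residues map through the parent-residue table,
    anything unknown becomes ``X``.
    """
    chain = model.chain(chain_id)
    if chain is None:
        raise KeyError(f"no chain {chain_id!r} in {model.entry_id}")
    if not chain.is_protein:
        raise TypeError(f"chain {chain_id!r} of {model.entry_id} is {chain.entity_type}, not protein")
    seq: list[str] = []
    keys: list[tuple[int, str]] = []
    for res in chain.residues:
        if res.entity_type != "protein" or not res.has_backbone:
            continue
        seq.append(res.one_letter)
        keys.append(res.key)
    return "".join(seq), keys
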