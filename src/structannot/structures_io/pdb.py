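"""Fixed-column PDB reading and writing.

Only the records the pipeline needs are interpreted: ATOM/HETATM, TER,
MODEL/ENDMDL and ``REMARK   2 RESOLUTION``.  The first model is kept,
alternate locations are collapsed to the highest-occupancy copy and
hydrogens are discarded.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

from .model import AtomRecord, Chain, Residue, StructureModel

_RESOLUTION_RE = re.compile(r"REMARK\s+2\s+RESOLUTION\.?\s+([0-9.]+)\s+ANGSTROM", re.IGNORECASE)

_ELEMENT_SYMBOLS = {
    "C", "N", "O", "S", "P", "H", "D", "SE", "FE", "ZN", "MG", "CA", "MN",
    "CU", "NI", "CO", "NA", "K", "CL", "BR", "I", "F", "CD", "HG", "MO", "W", "LI",
}


_TWO_LETTER_ELEMENTS = frozenset(
    {"SE", "FE", "ZN", "MG", "MN", "CU", "NI", "CO", "NA", "CL", "BR", "CD", "HG", "MO", "LI", "CA"}
)


def _infer_element(name: str, resname: str) -> str:
    """Guess the element from the atom-name column when column 77-78 is blank."""
    stripped = name.strip().upper()
    if not stripped:
        return ""
    letters = "".join(ch for ch in stripped if ch.isalpha())
    # metal/halide heteroatoms are usually named after the bare element
    if letters[:2] in _TWO_LETTER_ELEMENTS and len(letters) == 2 and letters == resname.strip().upper()[:2]:
        return letters[:2]
    return letters[:1]


class PDBFormatError(ValueError):
    pass


def _parse_atom_line(line: str, serial_fallback: int) -> AtomRecord:
    def _float(s: str, default: float = 0.0) -> float:
        s = s.strip()
        return float(s) if s else default

    def _int(s: str, default: int) -> int:
        s = s.strip()
        return int(s) if s else default

    line = line.rstrip("\n").ljust(80)
    name = line[12:16].strip()
    resname = line[17:20].strip()
    element = line[76:78].strip().upper()
    if not element:
        element = _infer_element(line[12:16], resname)
    occupancy = _float(line[54:60], 1.0)
    return AtomRecord(
        serial=_int(line[6:11], serial_fallback),
        name=name,
        altloc=line[16].strip(),
        resname=resname,
        chain_id=line[21].strip() or "A",
        resnum=_int(line[22:26], 0),
        icode=line[26].strip(),
        x=_float(line[30:38]),
        y=_float(line[38:46]),
        z=_float(line[46:54]),
        occupancy=min(max(occupancy, 0.0), 1.0),
        bfactor=_float(line[60:66]),
        element=element,
        is_hetatm=line.startswith("HETATM"),
    )


def parse_structure(path: str | Path, entry_id: str | None = None) -> StructureModel:
    """Parse a PDB-format file into a :class:`StructureModel`.

    First model only; for duplicated altlocs the highest-occupancy copy is
    kept (ties prefer altloc ``A``, then lexicographic); hydrogens are
    dropped; resolution is read from ``REMARK   2`` when present.
    """
    path = Path(path)
    if entry_id is None:
        entry_id = path.stem
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read structure file {path}: {exc}") from exc

    resolution: float | None = None
    is_model = False
    atoms: list[AtomRecord] = []
    in_first_model = True
    serial_fallback = 0
    for line in text.splitlines():
        rec = line[:6]
        if rec == "REMARK" and resolution is None:
            m = _RESOLUTION_RE.match(line)
            if m:
                resolution = float(m.group(1))
        elif rec.startswith("EXPDTA") and "MODEL" in line.upper():
            is_model = True
        elif rec == "ENDMDL":
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM") and in_first_model:
            serial_fallback += 1
            atom = _parse_atom_line(line, serial_fallback)
            if atom.element in ("H", "D"):
                continue
            if not math.isfinite(atom.x) or not math.isfinite(atom.y) or not math.isfinite(atom.z):
                continue
            atoms.append(atom)

    if not atoms:
        raise PDBFormatError(f"no ATOM/HETATM records parsed from {path}")

    # collapse altlocs: per (chain, resnum, icode, atom-name) keep the best copy
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.resnum, atom.icode, atom.name)
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            order.append(key)
        else:
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (prev.occupancy, _altloc_rank(prev.altloc)):
                best[key] = atom

    chains: dict[str, dict[tuple, Residue]] = {}
    chain_order: list[str] = []
    for key in order:
        atom = best[key]
        atom.altloc = ""
        if atom.chain_id not in chains:
            chains[atom.chain_id] = {}
            chain_order.append(atom.chain_id)
        residues = chains[atom.chain_id]
        rkey = (atom.resnum, atom.icode)
        if rkey not in residues:
            residues[rkey] = Residue(atom.resnum, atom.icode, atom.resname)
        residues[rkey].atoms.append(atom)

    model = StructureModel(
        entry_id=entry_id,
        chains=[Chain(cid, list(chains[cid].values())) for cid in chain_order],
        resolution=resolution,
        is_model=is_model,
    )
    return model


def _altloc_rank(altloc: str) -> tuple:
    # '' best, then 'A', then reverse-lexicographic so that max() prefers
    # earlier letters at equal occupancy
    if altloc in ("", "A"):
        return (1,)
    return (0, -ord(altloc))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model back out in fixed-column PDB format."""
    lines: list[str] = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    serial = 0
    for chain in model.chains:
        het_chain = not chain.is_protein
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if (atom.is_hetatm or (het_chain and res.entity_type not in ("protein", "dna", "rna"))) else "ATOM  "
                name = atom.name
                # standard justification: 1/2-letter elements start in col 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                lines.append(
                    f"{record}{serial:>5d} {padded}{atom.altloc or ' '}{res.resname:>3s} "
                    f"{chain.chain_id}{res.resnum:>4d}{atom.icode or ' '}   "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
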