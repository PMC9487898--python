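"""Heavy-atom contact detection with typed partners.

Contacts are directed: each qualifying atom pair yields two records, one per
participating residue's perspective, so downstream per-residue scoring never
has to re-orient pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..structures_io.model import StructureModel

ResKey = tuple[str, int, str]  # (chain_id, resnum, icode)


@dataclass
class Contact:
    res_key: ResKey          # focal residue
    atom_name: str
    part: str                # mainchain | sidechain (of the focal atom)
    partner_key: ResKey
    partner_resname: str
    partner_entity: str      # protein | ligand | metal | ion | dna | rna
    category: str            # interaction type from the focal perspective
    distance: float
    separation: int | None   # sequence separation for same-chain protein pairs


def _category(same_chain: bool, partner_entity: str, separation: int | None,
              short_max: int) -> str:
    if partner_entity == "protein":
        if same_chain and separation is not None:
            return "intra_short" if separation <= short_max else "intra_long"
        return "protein"
    return partner_entity


def find_contacts(
    model: StructureModel,
    dist_cutoff: float = 5.0,
    short_range_max_separation: int = 6,
) -> list[Contact]:
    """All heavy-atom pairs within the cutoff, excluding intra-residue pairs
    and the covalent backbone link of chain-adjacent residues.  Waters are
    ignored entirely."""
    atoms = []       # (coord, name, part, res_key, resname, entity, chain_idx)
    for chain in model.chains:
        protein_index = 0
        for res in chain.residues:
            etype = res.entity_type
            if etype == "water":
                continue
            idx = protein_index if etype == "protein" else -1
            for a in res.atoms:
                part = "mainchain" if a.is_mainchain and etype == "protein" else "sidechain"
                atoms.append(((a.x, a.y, a.z), a.name, part,
                              (chain.chain_id, res.resnum, res.icode),
                              res.resname, etype, idx))
            if etype == "protein":
                protein_index += 1

    if not atoms:
        return []
    coords = np.array([a[0] for a in atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(dist_cutoff, output_type="ndarray")

    contacts: list[Contact] = []
    for i, j in pairs:
        (_, name_i, part_i, key_i, rn_i, et_i, ci) = atoms[i]
        (_, name_j, part_j, key_j, rn_j, et_j, cj) = atoms[j]
        if key_i == key_j:
            continue
        same_chain = key_i[0] == key_j[0]
        sep = None
        if same_chain and et_i == "protein" and et_j == "protein" and ci >= 0 and cj >= 0:
            sep = abs(ci - cj)
            # covalent peptide bond between sequence neighbours
            if sep == 1 and {name_i, name_j} == {"C", "N"}:
                continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        contacts.append(Contact(key_i, name_i, part_i, key_j, rn_j, et_j,
                                _category(same_chain, et_j, sep, short_range_max_separation),
                                d, sep))
        contacts.append(Contact(key_j, name_j, part_j, key_i, rn_i, et_i,
                                _category(same_chain, et_i, sep, short_range_max_separation),
                                d, sep))
    return contacts
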