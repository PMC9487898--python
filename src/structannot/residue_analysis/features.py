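"""Full per-residue feature assembly for one structure.

``analyze_structure`` fills the complete 100-entry registry for every
protein residue of every chain, plus a small metadata block (contacted
ligand names, partner chains) consumed by the evidence features downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ..config import AnalysisConfig, DEFAULT_CONFIG
from ..registry import FEATURE_NAMES
from ..structures_io.model import StructureModel
from .contacts import ResKey, find_contacts
from .geometry import assign_secondary_structure, backbone_dihedrals, ca_bend_angles
from .rin import build_rin, interaction_scores, rin_centralities
from .sasa import compute_sasa, residue_rsa


@dataclass
class ResidueFeatures:
    """One residue's 100-entry feature vector plus context and metadata."""

    entry_id: str
    chain_id: str
    resnum: int
    icode: str
    values: dict[str, float | None]
    ligand_partners: tuple[str, ...] = ()
    protein_partner_chains: tuple[str, ...] = ()
    secondary_structure: str = "C"

    @property
    def res_key(self) -> ResKey:
        return (self.chain_id, self.resnum, self.icode)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"incomplete feature vector, missing {sorted(missing)[:3]}...")


@dataclass
class StructureAnalysis:
    """All residue feature vectors of one analyzed structure."""

    entry_id: str
    residues: dict[ResKey, ResidueFeatures] = field(default_factory=dict)

    def get(self, key: ResKey) -> ResidueFeatures | None:
        return self.residues.get(key)


def _median_min_max(values: list[float]) -> tuple[float | None, float | None, float | None]:
    if not values:
        return (None, None, None)
    return (float(np.median(values)), float(min(values)), float(max(values)))


def neighborhood_profile(
    model: StructureModel,
    rsa_by_key: dict[ResKey, float | None],
    residue_key: ResKey,
    radius: float = 10.0,
) -> dict[str, float | None]:
    """Counts and RSA statistics of protein residues within a sphere.

    Distances are Calpha-Calpha; residues without a Calpha fall back to
    their nearest atom.  Same-chain and other-chain residues are profiled
    separately; empty neighbour sets give undefined statistics.
    """
    chain_id, resnum, icode = residue_key
    focal = model.chain(chain_id).residue(resnum, icode)
    focal_ca = focal.atom("CA")
    focal_point = focal_ca.coord if focal_ca is not None else focal.coords().mean(axis=0)

    same: list[float] = []
    other: list[float] = []
    n_same = 0
    n_other = 0
    for chain in model.protein_chains:
        for res in chain.residues:
            if res.entity_type != "protein":
                continue
            key = (chain.chain_id, res.resnum, res.icode)
            if key == residue_key:
                continue
            ca = res.atom("CA")
            if ca is not None:
                d = float(np.linalg.norm(ca.coord - focal_point))
            else:
                d = float(np.min(np.linalg.norm(res.coords() - focal_point, axis=1)))
            if d > radius:
                continue
            rsa = rsa_by_key.get(key)
            if chain.chain_id == chain_id:
                n_same += 1
                if rsa is not None:
                    same.append(rsa)
            else:
                n_other += 1
                if rsa is not None:
                    other.append(rsa)

    med_s, min_s, max_s = _median_min_max(same)
    med_o, min_o, max_o = _median_min_max(other)
    return {
        "nbr_same_chain_count": float(n_same),
        "nbr_same_chain_rsa_median": med_s,
        "nbr_same_chain_rsa_min": min_s,
        "nbr_same_chain_rsa_max": max_s,
        "nbr_other_chain_count": float(n_other),
        "nbr_other_chain_rsa_median": med_o,
        "nbr_other_chain_rsa_min": min_o,
        "nbr_other_chain_rsa_max": max_o,
    }


def analyze_structure(
    model: StructureModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
    only_residues: set[ResKey] | None = None,
) -> StructureAnalysis:
    """Compute the full registry for every protein residue of the complex.

    ``only_residues`` restricts the per-residue assembly (lite mode); the
    complex-wide quantities (SASA, contacts, RIN) are computed either way
    because they are inputs to every residue's features.
    """
    atom_sasa = compute_sasa(model, n_points=config.sasa_points, probe=config.probe_radius)
    contacts = find_contacts(model, config.contact_cutoff, config.short_range_max_separation)
    rin = build_rin(model, contacts, config.contact_cutoff)
    centralities = rin_centralities(rin)

    # per-residue contact aggregates
    contact_counts: dict[ResKey, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    ligand_partners: dict[ResKey, set] = defaultdict(set)
    partner_chains: dict[ResKey, set] = defaultdict(set)
    for c in contacts:
        contact_counts[c.res_key][c.category] += 1
        if c.partner_entity in ("ligand", "metal", "ion"):
            ligand_partners[c.res_key].add(c.partner_resname)
        if c.category == "protein":
            partner_chains[c.res_key].add(c.partner_key[0])

    # accessibility for all protein residues (needed for neighbourhood stats)
    rsa_records: dict[ResKey, dict] = {}
    for chain in model.protein_chains:
        for res in chain.residues:
            if res.entity_type != "protein":
                continue
            key = (chain.chain_id, res.resnum, res.icode)
            rsa_records[key] = residue_rsa(res, atom_sasa, chain.chain_id)
    rsa_all_by_key = {k: v["rsa_all"] for k, v in rsa_records.items()}

    # all protein CA coordinates for packing density
    ca_keys = []
    ca_coords = []
    for chain in model.protein_chains:
        for res in chain.residues:
            ca = res.atom("CA")
            if res.entity_type == "protein" and ca is not None:
                ca_keys.append((chain.chain_id, res.resnum, res.icode))
                ca_coords.append(ca.coord)
    ca_coords = np.array(ca_coords) if ca_coords else np.zeros((0, 3))

    analysis = StructureAnalysis(model.entry_id)
    for chain in model.protein_chains:
        protein_residues = [r for r in chain.residues if r.entity_type == "protein"]
        ss_states = assign_secondary_structure(chain)
        dihedrals = backbone_dihedrals(chain)
        bends = ca_bend_angles(chain)

        res_bmeans = [float(np.mean([a.bfactor for a in r.atoms])) for r in protein_residues]
        chain_b_mean = float(np.mean(res_bmeans)) if res_bmeans else 0.0
        chain_b_std = float(np.std(res_bmeans)) if res_bmeans else 0.0

        for i, res in enumerate(protein_residues):
            key: ResKey = (chain.chain_id, res.resnum, res.icode)
            if only_residues is not None and key not in only_residues:
                continue
            values: dict[str, float | None] = {}
            values.update(rsa_records[key])
            values.update(neighborhood_profile(model, rsa_all_by_key, key,
                                               config.neighborhood_radius))

            counts = contact_counts.get(key, {})
            values["contact_count_intra_short"] = float(counts.get("intra_short", 0))
            values["contact_count_intra_long"] = float(counts.get("intra_long", 0))
            values["contact_count_interchain_protein"] = float(counts.get("protein", 0))
            values["contact_count_ligand"] = float(counts.get("ligand", 0))
            values["contact_count_nucleic"] = float(counts.get("dna", 0) + counts.get("rna", 0))
            values["contact_count_metal_ion"] = float(counts.get("metal", 0) + counts.get("ion", 0))

            n_atoms_by_part = {
                "mainchain": len(res.mainchain_atoms()),
                "sidechain": len(res.sidechain_atoms()),
            }
            scores = interaction_scores(rin, key, n_atoms_by_part,
                                        config.short_range_max_separation)
            for (part, itype), (score, degree) in scores.items():
                values[f"{part}_{itype}_score"] = score
                values[f"{part}_{itype}_degree"] = degree

            state = ss_states[i]
            values["ss_helix"] = 1.0 if state == "H" else 0.0
            values["ss_sheet"] = 1.0 if state == "E" else 0.0
            values["ss_coil"] = 1.0 if state == "C" else 0.0

            values["phi"] = dihedrals[i]["phi"]
            values["psi"] = dihedrals[i]["psi"]
            values["omega"] = dihedrals[i]["omega"]
            values["ca_bend_angle"] = bends[i]
            ca = res.atom("CA")
            if ca is not None and len(ca_coords):
                d = np.linalg.norm(ca_coords - ca.coord, axis=1)
                values["packing_density"] = float((d <= config.neighborhood_radius).sum() - 1)
            else:
                values["packing_density"] = None

            bfac_all = [a.bfactor for a in res.atoms]
            bfac_mc = [a.bfactor for a in res.mainchain_atoms()]
            bfac_sc = [a.bfactor for a in res.sidechain_atoms()]
            values["b_mean_all"] = float(np.mean(bfac_all)) if bfac_all else None
            values["b_mean_mainchain"] = float(np.mean(bfac_mc)) if bfac_mc else None
            values["b_mean_sidechain"] = float(np.mean(bfac_sc)) if bfac_sc else None
            values["b_chain_zscore"] = (
                float((res_bmeans[i] - chain_b_mean) / chain_b_std) if chain_b_std > 0 else None
            )

            cent = centralities.get(key, {})
            for name in FEATURE_NAMES:
                if name.startswith("rin_"):
                    values[name] = cent.get(name)

            analysis.residues[key] = ResidueFeatures(
                entry_id=model.entry_id,
                chain_id=chain.chain_id,
                resnum=res.resnum,
                icode=res.icode,
                values={n: values.get(n) for n in FEATURE_NAMES},
                ligand_partners=tuple(sorted(ligand_partners.get(key, ()))),
                protein_partner_chains=tuple(sorted(partner_chains.get(key, ()))),
                secondary_structure=state,
            )
    return analysis
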