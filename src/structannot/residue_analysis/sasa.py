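"""Solvent accessible surface area (Shrake-Rupley with a Fibonacci lattice)
and relative solvent accessibility.

RSA maxima are the theoretical per-residue values of Tien et al. 2013.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..structures_io.model import MAINCHAIN_ATOMS, StructureModel

ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70

# Tien et al. 2013, theoretical maximum ASA per residue type (A^2)
MAX_ASA_TOTAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
MAX_ASA_UNKNOWN = float(np.mean(list(MAX_ASA_TOTAL.values())))
# the glycine maximum is essentially pure backbone; used as mainchain maximum
MAX_ASA_MAINCHAIN = MAX_ASA_TOTAL["GLY"]

RSA_CAP = 1.3  # aggregated/raw RSA values are clipped here


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly even unit-sphere sampling (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radius(element: str) -> float:
    return ATOM_RADII.get(element.upper(), DEFAULT_RADIUS)


def compute_atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    n_points: int = 960,
    probe: float = 1.4,
) -> np.ndarray:
    """Per-atom SASA in A^2 for a set of spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = float(radii.max())
    out = np.empty(n)
    for i in range(n):
        r_i = radii[i] + probe
        neighbors = tree.query_ball_point(coords[i], r_i + max_r + probe)
        neighbors = [j for j in neighbors if j != i]
        points = coords[i] + sphere * r_i
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((points[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            cut2 = (radii[nb] + probe) ** 2
            accessible = ~(d2 < cut2 - 1e-12).any(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * r_i * r_i * frac
    return out


def compute_sasa(model: StructureModel, n_points: int = 960, probe: float = 1.4) -> dict:
    """SASA per atom of the model, keyed by (chain_id, resnum, icode, atom name).

    Water molecules neither receive an area nor occlude other atoms.
    """
    atoms = []
    for chain in model.chains:
        for res in chain.residues:
            if res.entity_type == "water":
                continue
            for a in res.atoms:
                atoms.append((chain.chain_id, res.resnum, res.icode, a))
    coords = np.array([[a.x, a.y, a.z] for _, _, _, a in atoms])
    radii = np.array([atom_radius(a.element) for _, _, _, a in atoms])
    areas = compute_atom_sasa(coords, radii, n_points=n_points, probe=probe)
    return {
        (cid, resnum, icode, a.name): float(area)
        for (cid, resnum, icode, a), area in zip(atoms, areas)
    }


def residue_rsa(residue, atom_sasa: dict, chain_id: str) -> dict:
    """Six accessibility values for one protein residue.

    Returns sasa_all/mainchain/sidechain and rsa_all/mainchain/sidechain;
    the glycine sidechain entries are the undefined marker ``None``.
    """
    sasa_mc = 0.0
    sasa_sc = 0.0
    has_sc = False
    for a in residue.atoms:
        area = atom_sasa.get((chain_id, residue.resnum, residue.icode, a.name))
        if area is None:
            continue
        if a.name in MAINCHAIN_ATOMS:
            sasa_mc += area
        else:
            sasa_sc += area
            has_sc = True
    sasa_all = sasa_mc + sasa_sc
    max_total = MAX_ASA_TOTAL.get(residue.resname, MAX_ASA_UNKNOWN)
    max_sc = max(max_total - MAX_ASA_MAINCHAIN, 1.0)
    out = {
        "sasa_all": sasa_all,
        "sasa_mainchain": sasa_mc,
        "sasa_sidechain": sasa_sc if has_sc else None,
        "rsa_all": min(sasa_all / max_total, RSA_CAP),
        "rsa_mainchain": min(sasa_mc / MAX_ASA_MAINCHAIN, RSA_CAP),
        "rsa_sidechain": min(sasa_sc / max_sc, RSA_CAP) if has_sc else None,
    }
    return out
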