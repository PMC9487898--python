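"""Synthetic template structures with known ground truth.

Fixtures are built from ideal peptide geometry (NeRF chain extension from
backbone dihedrals) so that burial, interface and ligand-contact status of
every residue is derivable from the construction itself.  All generators are
deterministic for a given seed and emit models that round-trip through the
PDB writer/parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AtomRecord, Chain, ONE_TO_THREE, Residue, StructureModel

# ideal backbone geometry (lengths in Angstrom, angles in degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.5

# Disjoint per-chain alphabets: exact-match identity between sequences drawn
# from different sets is zero, so fixtures sharing a template library never
# cross-annotate each other's chains.  Small/medium residues keep single-CB
# sidechains reasonably close to their theoretical maximum accessibility.
CHAIN_ALPHABETS = {
    "helix": "ASTV",
    "dimer_a": "DNQE",
    "dimer_b": "KRHW",
    "ligand": "CMPI",
    "nucleic": "FYLG",
}

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 130.0


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three reference atoms, a bond length, bond angle
    b-c-d and dihedral a-b-c-d (natural extension reference frame)."""
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-length * np.cos(theta),
                   length * np.sin(theta) * np.cos(tau),
                   length * np.sin(theta) * np.sin(tau)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """IUPAC dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_peptide(sequence: str, phi: float, psi: float, chain_id: str = "A",
                  start_resnum: int = 1, bfactors: np.ndarray | None = None) -> Chain:
    """Build an all-residue peptide chain with uniform backbone dihedrals.

    Atoms per residue: N, CA, C, O and CB (except glycine).
    """
    n = len(sequence)
    if n < 1:
        raise ValueError("sequence must be non-empty")
    coords_n = np.zeros((n, 3))
    coords_ca = np.zeros((n, 3))
    coords_c = np.zeros((n, 3))

    coords_n[0] = np.array([0.0, 0.0, 0.0])
    coords_ca[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    coords_c[0] = coords_ca[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n):
        coords_n[i] = nerf_place(coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
                                 _B_C_N, _A_CA_C_N, psi)
        coords_ca[i] = nerf_place(coords_ca[i - 1], coords_c[i - 1], coords_n[i],
                                  _B_N_CA, _A_C_N_CA, 180.0)
        coords_c[i] = nerf_place(coords_c[i - 1], coords_n[i], coords_ca[i],
                                 _B_CA_C, _A_N_CA_C, phi)

    residues: list[Residue] = []
    serial = 0
    for i, one in enumerate(sequence):
        resname = ONE_TO_THREE.get(one)
        if resname is None:
            raise ValueError(f"unsupported residue letter {one!r}")
        resnum = start_resnum + i
        b = float(bfactors[i]) if bfactors is not None else 20.0
        res = Residue(resnum, "", resname)
        o = nerf_place(coords_n[i], coords_ca[i], coords_c[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = [("N", coords_n[i], "N"), ("CA", coords_ca[i], "C"),
                 ("C", coords_c[i], "C"), ("O", o, "O")]
        if one != "G":
            cb = nerf_place(coords_c[i], coords_n[i], coords_ca[i], _B_CA_CB, _A_N_CA_CB, 122.5)
            atoms.append(("CB", cb, "C"))
        for name, xyz, elem in atoms:
            serial += 1
            res.atoms.append(AtomRecord(serial, name, "", resname, chain_id, resnum, "",
                                        float(xyz[0]), float(xyz[1]), float(xyz[2]),
                                        1.0, b, elem, False))
        residues.append(res)
    return Chain(chain_id, residues)


def _chain_coords(chain: Chain) -> np.ndarray:
    return np.vstack([r.coords() for r in chain.residues])


def _translate_chain(chain: Chain, shift: np.ndarray) -> None:
    for res in chain.residues:
        for a in res.atoms:
            a.x += float(shift[0])
            a.y += float(shift[1])
            a.z += float(shift[2])


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _min_interchain_distance(a: Chain, b: Chain) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(_chain_coords(a), _chain_coords(b)).min())


def _random_sequence(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _bfactors(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.round(20.0 + 10.0 * rng.random(n), 2)


@dataclass
class FixtureResult:
    """A generated structure plus the labels implied by its construction."""

    model: StructureModel
    # (chain_id, resnum) -> {"surface", "interface", "ligand_contact", "nucleic_contact"}
    ground_truth: dict[tuple[str, int], str] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)


def _contact_labels(result: FixtureResult, cutoff: float = 5.0) -> None:
    """Label residues from interatomic distances of the finished model."""
    from scipy.spatial.distance import cdist

    model = result.model
    partner_label = {"ligand": "ligand_contact", "metal": "ligand_contact",
                     "ion": "ligand_contact", "dna": "nucleic_contact",
                     "rna": "nucleic_contact", "protein": "interface"}
    # label priority when several partner kinds are near: metal-ish < nucleic < ligand
    priority = {"surface": 0, "interface": 1, "nucleic_contact": 2, "ligand_contact": 3}
    for chain in model.protein_chains:
        for res in chain.residues:
            label = "surface"
            rc = res.coords()
            for other in model.chains:
                if other.chain_id == chain.chain_id or other.entity_type == "water":
                    continue
                kind = partner_label.get(other.entity_type)
                if kind is None:
                    continue
                if cdist(rc, _chain_coords(other)).min() <= cutoff and priority[kind] > priority[label]:
                    label = kind
            result.ground_truth[(chain.chain_id, res.resnum)] = label
            result.sequences.setdefault(chain.chain_id, "")
        seq = "".join(r.one_letter for r in chain.residues)
        result.sequences[chain.chain_id] = seq


def make_helix(n: int = 20, seed: int = 0, entry_id: str = "FIX1") -> FixtureResult:
    if n < 4:
        raise ValueError("helix fixture needs n >= 4")
    rng = np.random.default_rng(seed)
    chain = build_peptide(_random_sequence(rng, n, CHAIN_ALPHABETS["helix"]),
                          HELIX_PHI, HELIX_PSI, "A", bfactors=_bfactors(rng, n))
    model = StructureModel(entry_id, [chain], resolution=1.5)
    result = FixtureResult(model)
    _contact_labels(result)
    return result


def make_dimer(n: int = 15, seed: int = 0, interface_gap: float = 4.5,
               entry_id: str = "FIX2") -> FixtureResult:
    if n < 4:
        raise ValueError("dimer fixture needs n >= 4")
    if interface_gap <= 0:
        raise ValueError("interface_gap must be positive")
    rng = np.random.default_rng(seed)
    chain_a = build_peptide(_random_sequence(rng, n, CHAIN_ALPHABETS["dimer_a"]),
                            HELIX_PHI, HELIX_PSI, "A", bfactors=_bfactors(rng, n))
    chain_b = build_peptide(_random_sequence(rng, n, CHAIN_ALPHABETS["dimer_b"]),
                            HELIX_PHI, HELIX_PSI, "B", bfactors=_bfactors(rng, n))
    # shift the second helix perpendicular to the axis until the closest
    # heavy-atom approach equals the requested gap
    coords_a = _chain_coords(chain_a)
    axis = _principal_axis(coords_a)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    lo, hi = 0.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _translate_chain(chain_b, perp * mid - _chain_coords(chain_b).mean(axis=0)
                         + coords_a.mean(axis=0))
        d = _min_interchain_distance(chain_a, chain_b)
        if d < interface_gap:
            lo = mid
        else:
            hi = mid
    _translate_chain(chain_b, perp * hi - _chain_coords(chain_b).mean(axis=0)
                     + coords_a.mean(axis=0))
    model = StructureModel(entry_id, [chain_a, chain_b], resolution=2.0)
    result = FixtureResult(model)
    _contact_labels(result)
    return result


def make_ligand_complex(n: int = 20, seed: int = 0, ligand_distance: float = 3.5,
                        target_resnum: int = 8, entry_id: str = "FIX3") -> FixtureResult:
    if not 1 <= target_resnum <= n:
        raise ValueError("target_resnum outside the chain")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, n, CHAIN_ALPHABETS["ligand"])
    if seq[target_resnum - 1] == "G":  # ensure a CB anchor for the ligand
        seq = seq[: target_resnum - 1] + "M" + seq[target_resnum:]
    chain = build_peptide(seq, HELIX_PHI, HELIX_PSI, "A", bfactors=_bfactors(rng, n))
    target = chain.residue(target_resnum)
    anchor = target.atom("CB") or target.atom("CA")
    centroid = _chain_coords(chain).mean(axis=0)
    direction = anchor.coord - centroid
    direction /= np.linalg.norm(direction)
    pos = anchor.coord + direction * ligand_distance
    lig = Residue(1, "", "LIG")
    lig.atoms.append(AtomRecord(0, "C1", "", "LIG", "L", 1, "",
                                float(pos[0]), float(pos[1]), float(pos[2]),
                                1.0, 30.0, "C", True))
    model = StructureModel(entry_id, [chain, Chain("L", [lig])], resolution=1.8)
    result = FixtureResult(model)
    _contact_labels(result)
    return result


def make_nucleic_complex(n: int = 20, seed: int = 0, gap: float = 4.0,
                         entry_id: str = "FIX4") -> FixtureResult:
    rng = np.random.default_rng(seed)
    chain = build_peptide(_random_sequence(rng, n, CHAIN_ALPHABETS["nucleic"]),
                          HELIX_PHI, HELIX_PSI, "A", bfactors=_bfactors(rng, n))
    coords = _chain_coords(chain)
    axis = _principal_axis(coords)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    mid = coords.mean(axis=0)
    edge = float(np.max((coords - mid) @ perp))  # helix extent along perp
    # crude single-strand stand-in: phosphate + sugar carbon per nucleotide
    residues = []
    serial = 0
    names = ["DA", "DT", "DG", "DC"]
    n_nt = 4
    for i in range(n_nt):
        resname = names[i % 4]
        base = mid + perp * (edge + gap + 6.0) + axis * (3.4 * (i - (n_nt - 1) / 2.0))
        res = Residue(i + 1, "", resname)
        for name, offset, elem in (("P", -perp * 0.0, "P"), ("C1", -perp * 6.0, "C")):
            serial += 1
            xyz = base + offset
            res.atoms.append(AtomRecord(serial, name, "", resname, "N", i + 1, "",
                                        float(xyz[0]), float(xyz[1]), float(xyz[2]),
                                        1.0, 30.0, elem, True))
        residues.append(res)
    model = StructureModel(entry_id, [chain, Chain("N", residues)], resolution=2.5)
    result = FixtureResult(model)
    _contact_labels(result)
    return result


_GENERATORS = {
    "helix": make_helix,
    "dimer": make_dimer,
    "ligand_complex": make_ligand_complex,
    "nucleic_complex": make_nucleic_complex,
}


def generate_fixture(kind: str, **params) -> FixtureResult:
    """Dispatch to one of the fixture generators by kind name."""
    try:
        gen = _GENERATORS[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_GENERATORS)}")
    return gen(**params)
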