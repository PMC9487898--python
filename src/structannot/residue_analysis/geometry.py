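"""Backbone geometry: dihedrals, secondary-structure states, bend angles."""

from __future__ import annotations

import numpy as np

from ..structures_io.fixtures import dihedral
from ..structures_io.model import Chain

# phi/psi windows for the three-state assignment
HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-80.0, -5.0)
SHEET_PHI_RANGE = (-170.0, -70.0)
SHEET_PSI_RANGE = (90.0, 180.0)


def backbone_dihedrals(chain: Chain) -> list[dict[str, float | None]]:
    """phi/psi/omega per protein residue of the chain (None where undefined)."""
    residues = [r for r in chain.residues if r.entity_type == "protein"]
    out: list[dict[str, float | None]] = []
    for i, res in enumerate(residues):
        phi = psi = omega = None
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if all(a is not None for a in (n, ca, c)):
            if prev is not None and prev.atom("C") is not None:
                phi = dihedral(prev.atom("C").coord, n.coord, ca.coord, c.coord)
            if nxt is not None and nxt.atom("N") is not None:
                psi = dihedral(n.coord, ca.coord, c.coord, nxt.atom("N").coord)
        if prev is not None and all(
            a is not None for a in (prev.atom("CA"), prev.atom("C"), n, ca)
        ):
            omega = dihedral(prev.atom("CA").coord, prev.atom("C").coord, n.coord, ca.coord)
        out.append({"phi": phi, "psi": psi, "omega": omega})
    return out


def _in_range(value: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= value <= lo_hi[1]


def assign_secondary_structure(chain: Chain) -> list[str]:
    """Three-state secondary structure (H/E/C) from raw phi/psi windows.

    Chain termini with an undefined dihedral are coil; no smoothing.
    """
    states: list[str] = []
    for d in backbone_dihedrals(chain):
        phi, psi = d["phi"], d["psi"]
        if phi is None or psi is None:
            states.append("C")
        elif _in_range(phi, HELIX_PHI_RANGE) and _in_range(psi, HELIX_PSI_RANGE):
            states.append("H")
        elif _in_range(phi, SHEET_PHI_RANGE) and _in_range(psi, SHEET_PSI_RANGE):
            states.append("E")
        else:
            states.append("C")
    return states


def ca_bend_angles(chain: Chain) -> list[float | None]:
    """Angle (degrees) at CA(i) between the directions to CA(i-2) and CA(i+2)."""
    residues = [r for r in chain.residues if r.entity_type == "protein"]
    cas = [r.atom("CA") for r in residues]
    out: list[float | None] = []
    for i in range(len(residues)):
        if i < 2 or i + 2 >= len(residues) or cas[i] is None \
                or cas[i - 2] is None or cas[i + 2] is None:
            out.append(None)
            continue
        v1 = cas[i - 2].coord - cas[i].coord
        v2 = cas[i + 2].coord - cas[i].coord
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        out.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    return out
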