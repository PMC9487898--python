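"""Decision-tree structural classification of aggregated positions.

An interaction interface call precedes the core/surface split: if any
aggregated interaction degree reaches the threshold, the class is the
highest-priority partner type; otherwise aggregated RSA against the 0.16
burial threshold decides (strictly greater means surface).
"""

from __future__ import annotations

from ..registry import INTERFACE_TYPES, PARTS

# partner rarity ordering for the class label when several types are present
TYPE_PRIORITY = ("metal", "ion", "dna", "rna", "ligand", "protein")

TYPE_DISPLAY = {
    "protein": "protein",
    "ligand": "ligand",
    "metal": "metal",
    "ion": "ion",
    "dna": "DNA",
    "rna": "RNA",
}

CLASS_DISPLAY = {
    "protein": "Protein interaction",
    "ligand": "Ligand interaction",
    "metal": "Metal interaction",
    "ion": "Ion interaction",
    "dna": "DNA interaction",
    "rna": "RNA interaction",
}

NO_STRUCTURE = "No structure"


def _location(rsa: float | None, threshold: float) -> str | None:
    if rsa is None:
        return None
    return "Surface" if rsa > threshold else "Core"


def classify_position(
    features: dict[str, float | None] | None,
    rsa_threshold: float = 0.16,
    degree_eps: float = 0.1,
) -> dict[str, str | None]:
    """Class labels for one aggregated position.

    ``features`` is the aggregated 100-entry registry; ``None`` means the
    position could not be mapped to any structure.
    """
    if features is None:
        return {
            "location": None,
            "mainchain_location": None,
            "sidechain_location": None,
            "structural_class": NO_STRUCTURE,
            "simple_class": NO_STRUCTURE,
            "rin_class": NO_STRUCTURE,
            "rin_simple_class": NO_STRUCTURE,
            "interaction_profile": None,
        }

    # (part, type) pairs whose aggregated degree reaches the threshold,
    # ordered by partner-type priority, sidechain first within a type
    present: list[tuple[str, str, float]] = []
    for itype in TYPE_PRIORITY:
        for part in ("sidechain", "mainchain"):
            degree = features.get(f"{part}_{itype}_degree")
            if degree is not None and degree >= degree_eps:
                present.append((part, itype, degree))

    location = _location(features.get("rsa_all"), rsa_threshold)
    mainchain_location = _location(features.get("rsa_mainchain"), rsa_threshold)
    sidechain_location = _location(features.get("rsa_sidechain"), rsa_threshold)

    profile = ",".join(
        f"{part}_{itype}:{degree:.2f}" for part, itype, degree in present
    ) or None

    if not present:
        label = location if location is not None else "Core"
        return {
            "location": location,
            "mainchain_location": mainchain_location,
            "sidechain_location": sidechain_location,
            "structural_class": label,
            "simple_class": label,
            "rin_class": label,
            "rin_simple_class": label,
            "interaction_profile": profile,
        }

    top_type = present[0][1]
    structural_class = CLASS_DISPLAY[top_type]
    phrases = [f"{part} contact with a {TYPE_DISPLAY[itype]}" for part, itype, _ in present]
    if len(present) == 1:
        rin_class = phrases[0][0].upper() + phrases[0][1:]
        rin_simple = rin_class
    else:
        rin_class = "Multiple interactions: " + " and ".join(phrases)
        rin_simple = "Multiple interactions"
    return {
        "location": location,
        "mainchain_location": mainchain_location,
        "sidechain_location": sidechain_location,
        "structural_class": structural_class,
        "simple_class": "Interaction",
        "rin_class": rin_class,
        "rin_simple_class": rin_simple,
        "interaction_profile": profile,
    }


def simple_class_of(labels: dict[str, str | None]) -> str:
    return labels["simple_class"] or NO_STRUCTURE
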