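"""Evidence meta-features and recommended-structure selection."""

from __future__ import annotations

import numpy as np

from ..registry import EVIDENCE_NAMES
from ..residue_analysis.features import ResidueFeatures
from ..search_align.mapping import SeqToStructAnnotation

_LOCATION_CODE = {"Core": 0.0, "Surface": 1.0}


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def evidence_features(
    annotations: list[SeqToStructAnnotation],
    residue_features: list[ResidueFeatures | None],
    labels: dict[str, str | None] | None = None,
) -> dict[str, float | None]:
    """The 23-entry evidence block for one query position.

    ``annotations`` are the accepted annotations of the protein;
    ``residue_features`` is parallel, holding the mapped residue's features
    where the position maps into that structure and ``None`` elsewhere.
    """
    mapped = [(a, rf) for a, rf in zip(annotations, residue_features) if rf is not None]
    out: dict[str, float | None] = dict.fromkeys(EVIDENCE_NAMES)

    out["n_mapped_structures"] = float(len(mapped))
    out["n_distinct_entries"] = float(len({a.entry_id for a, _ in mapped}))
    identities = [a.identity for a, _ in mapped]
    coverages = [a.coverage for a, _ in mapped]
    qualities = [a.quality for a, _ in mapped]
    resolutions = [a.resolution for a, _ in mapped if a.resolution is not None]
    if mapped:
        out["max_identity"] = float(max(identities))
        qsum = sum(qualities)
        out["qweighted_mean_identity"] = (
            float(sum(q * i for q, i in zip(qualities, identities)) / qsum) if qsum else None
        )
        out["max_coverage"] = float(max(coverages))
        out["mean_coverage"] = _mean(coverages)
        out["best_resolution"] = float(min(resolutions)) if resolutions else None
        out["mean_resolution"] = _mean(resolutions)
        out["mean_quality"] = _mean(qualities)
        out["max_quality"] = float(max(qualities))
        defined_rsa = [rf for _, rf in mapped if rf.values.get("rsa_all") is not None]
        out["n_resolved"] = float(len(defined_rsa))
        out["defined_sidechain_fraction"] = float(
            sum(1 for _, rf in mapped if rf.values.get("rsa_sidechain") is not None) / len(mapped)
        )
        out["n_protein_interaction_annotations"] = float(
            sum(1 for _, rf in mapped if (rf.values.get("contact_count_interchain_protein") or 0) > 0)
        )
        out["n_ligand_interaction_annotations"] = float(
            sum(1 for _, rf in mapped if (rf.values.get("contact_count_ligand") or 0) > 0)
        )
        out["n_nucleic_interaction_annotations"] = float(
            sum(1 for _, rf in mapped if (rf.values.get("contact_count_nucleic") or 0) > 0)
        )
        out["n_metal_ion_interaction_annotations"] = float(
            sum(1 for _, rf in mapped if (rf.values.get("contact_count_metal_ion") or 0) > 0)
        )
        ligands = set()
        partner_chains = set()
        for a, rf in mapped:
            ligands.update(rf.ligand_partners)
            partner_chains.update((a.entry_id, c) for c in rf.protein_partner_chains)
        out["n_distinct_ligands"] = float(len(ligands))
        out["n_distinct_partner_chains"] = float(len(partner_chains))
        n_helix = sum(1 for _, rf in mapped if rf.secondary_structure == "H")
        n_sheet = sum(1 for _, rf in mapped if rf.secondary_structure == "E")
        out["helix_majority"] = 1.0 if n_helix * 2 > len(mapped) else 0.0
        out["sheet_majority"] = 1.0 if n_sheet * 2 > len(mapped) else 0.0
    else:
        out["n_mapped_structures"] = 0.0
        out["n_distinct_entries"] = 0.0

    if labels is not None:
        out["location_code"] = _LOCATION_CODE.get(labels.get("location"))
        out["mainchain_location_code"] = _LOCATION_CODE.get(labels.get("mainchain_location"))
        out["sidechain_location_code"] = _LOCATION_CODE.get(labels.get("sidechain_location"))
    return out


def _interaction_type_count(rf: ResidueFeatures) -> int:
    v = rf.values
    kinds = 0
    kinds += (v.get("contact_count_interchain_protein") or 0) > 0
    kinds += (v.get("contact_count_ligand") or 0) > 0
    kinds += (v.get("contact_count_nucleic") or 0) > 0
    kinds += (v.get("contact_count_metal_ion") or 0) > 0
    return int(kinds)


def render_structure_ref(annotation: SeqToStructAnnotation) -> str:
    return f"{annotation.entry_id}:{annotation.chain_id}"


def render_residue_ref(rf: ResidueFeatures | None) -> str | None:
    if rf is None:
        return None
    return f"{rf.resnum}{rf.icode}:{rf.chain_id}"


def select_recommended(
    annotations: list[SeqToStructAnnotation],
    residue_features: list[ResidueFeatures | None],
) -> tuple[SeqToStructAnnotation | None, SeqToStructAnnotation | None]:
    """(max-identity annotation, recommended annotation) for one position.

    Max identity breaks ties by coverage, then better (smaller) resolution,
    then lexicographic structure key.  The recommendation maximizes
    q * (1 + number of distinct interaction types seen at the position in
    that structure); both picks are permutation-invariant.
    """
    mapped = [(a, rf) for a, rf in zip(annotations, residue_features) if rf is not None]
    if not mapped:
        return (None, None)

    def _res_rank(a: SeqToStructAnnotation) -> float:
        return -(a.resolution if a.resolution is not None else 99.0)

    max_identity = max(
        mapped,
        key=lambda pair: (
            pair[0].identity,
            pair[0].coverage,
            _res_rank(pair[0]),
            tuple(-ord(c) for c in pair[0].entry_id + ":" + pair[0].chain_id),
        ),
    )[0]
    recommended = max(
        mapped,
        key=lambda pair: (
            pair[0].quality * (1 + _interaction_type_count(pair[1])),
            pair[0].identity,
            pair[0].coverage,
            _res_rank(pair[0]),
            tuple(-ord(c) for c in pair[0].entry_id + ":" + pair[0].chain_id),
        ),
    )[0]
    return (max_identity, recommended)
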