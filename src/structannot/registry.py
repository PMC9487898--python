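"""The fixed feature registry.

Every per-residue analysis produces one value (or the undefined marker
``None``) for each of the 100 names in :data:`FEATURE_NAMES`, in this order.
Aggregated positions additionally carry the 23 :data:`EVIDENCE_NAMES`
meta-features.  SAV vectors are the concatenation of both (123 entries);
indel vectors are six region blocks of the 100 aggregatable features
(600 entries).
"""

from __future__ import annotations

INTERACTION_TYPES = (
    "protein",
    "ligand",
    "metal",
    "ion",
    "dna",
    "rna",
    "intra_short",
    "intra_long",
)

# partner types that count as "interface" in classification (intra-chain
# short/long range contacts describe fold topology, not interfaces)
INTERFACE_TYPES = ("protein", "ligand", "metal", "ion", "dna", "rna")

PARTS = ("mainchain", "sidechain")

CENTRALITY_METRICS = (
    "weighted_degree",
    "degree",
    "closeness",
    "betweenness",
    "clustering",
    "mean_edge_weight",
)
CENTRALITY_SCOPES = ("complex", "chain")
CENTRALITY_EDGESETS = ("all", "sidechain", "mainchain")


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    # accessibility (6) -- sasa_all is feature #1 by contract
    names += [
        "sasa_all",
        "sasa_mainchain",
        "sasa_sidechain",
        "rsa_all",
        "rsa_mainchain",
        "rsa_sidechain",
    ]
    # 10 A neighborhood profile (8)
    names += [
        "nbr_same_chain_count",
        "nbr_same_chain_rsa_median",
        "nbr_same_chain_rsa_min",
        "nbr_same_chain_rsa_max",
        "nbr_other_chain_count",
        "nbr_other_chain_rsa_median",
        "nbr_other_chain_rsa_min",
        "nbr_other_chain_rsa_max",
    ]
    # atom-pair contact counts (6)
    names += [
        "contact_count_intra_short",
        "contact_count_intra_long",
        "contact_count_interchain_protein",
        "contact_count_ligand",
        "contact_count_nucleic",
        "contact_count_metal_ion",
    ]
    # interaction score/degree grid (2 parts x 8 types x 2 = 32)
    for part in PARTS:
        for itype in INTERACTION_TYPES:
            names.append(f"{part}_{itype}_score")
            names.append(f"{part}_{itype}_degree")
    # secondary structure one-hot (3)
    names += ["ss_helix", "ss_sheet", "ss_coil"]
    # backbone geometry (5)
    names += ["phi", "psi", "omega", "ca_bend_angle", "packing_density"]
    # B-factor statistics (4)
    names += ["b_mean_all", "b_mean_mainchain", "b_mean_sidechain", "b_chain_zscore"]
    # RIN centralities (6 metrics x 2 scopes x 3 edge sets = 36)
    for scope in CENTRALITY_SCOPES:
        for edgeset in CENTRALITY_EDGESETS:
            for metric in CENTRALITY_METRICS:
                names.append(f"rin_{scope}_{edgeset}_{metric}")
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_feature_names()

EVIDENCE_NAMES: tuple[str, ...] = (
    "n_mapped_structures",
    "n_distinct_entries",
    "max_identity",
    "qweighted_mean_identity",
    "max_coverage",
    "mean_coverage",
    "best_resolution",
    "mean_resolution",
    "mean_quality",
    "max_quality",
    "n_resolved",
    "defined_sidechain_fraction",
    "n_protein_interaction_annotations",
    "n_ligand_interaction_annotations",
    "n_nucleic_interaction_annotations",
    "n_metal_ion_interaction_annotations",
    "n_distinct_ligands",
    "n_distinct_partner_chains",
    "helix_majority",
    "sheet_majority",
    "location_code",
    "mainchain_location_code",
    "sidechain_location_code",
)

SAV_VECTOR_NAMES: tuple[str, ...] = FEATURE_NAMES + EVIDENCE_NAMES

INDEL_REGIONS = (
    "wt_left_flank",
    "wt_indel_region",
    "wt_right_flank",
    "mut_left_flank",
    "mut_indel_region",
    "mut_right_flank",
)

INDEL_VECTOR_NAMES: tuple[str, ...] = tuple(
    f"{region}__{name}" for region in INDEL_REGIONS for name in FEATURE_NAMES
)

# the six accessibility features get the squared-coverage aggregation bias
RSA_BIASED_FEATURES = frozenset(
    {
        "sasa_all",
        "sasa_mainchain",
        "sasa_sidechain",
        "rsa_all",
        "rsa_mainchain",
        "rsa_sidechain",
    }
)

assert len(FEATURE_NAMES) == 100, len(FEATURE_NAMES)
assert len(EVIDENCE_NAMES) == 23
assert len(SAV_VECTOR_NAMES) == 123
assert len(INDEL_VECTOR_NAMES) == 600
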