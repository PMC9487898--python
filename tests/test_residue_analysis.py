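from __future__ import annotations

import numpy as np
import pytest

from structannot.registry import FEATURE_NAMES
from structannot.residue_analysis import (
    analyze_structure,
    assign_secondary_structure,
    build_rin,
    compute_atom_sasa,
    find_contacts,
    interaction_scores,
    neighborhood_profile,
    residue_rsa,
    rin_centralities,
)
from structannot.residue_analysis.sasa import compute_sasa
from structannot.structures_io import build_peptide
from structannot.structures_io.model import AtomRecord, Chain, Residue, StructureModel

from .oracles import (
    brute_force_betweenness,
    brute_force_clustering,
    brute_force_closeness,
)


def _residue(resname, resnum, chain_id, atoms):
    """atoms: list of (name, element, xyz)."""
    res = Residue(resnum, "", resname)
    for i, (name, element, (x, y, z)) in enumerate(atoms):
        res.atoms.append(AtomRecord(i + 1, name, "", resname, chain_id, resnum, "",
                                    float(x), float(y), float(z), 1.0, 20.0,
                                    element, False))
    return res


def _shell_model():
    """A single ALA enclosed by a carbon shell, plus one free ALA far away."""
    enclosed = _residue("ALA", 1, "A", [
        ("N", "N", (1.4, 0, 0)), ("CA", "C", (0, 0, 0)), ("C", "C", (-1.4, 0.4, 0)),
        ("O", "O", (-2.0, 1.2, 0.8)), ("CB", "C", (0.3, 1.2, 1.0)),
    ])
    shell_atoms = []
    idx = 0
    for r in (4.5, 6.5):
        for i in range(-2, 3):
            for j in range(-2, 3):
                for k in range(-2, 3):
                    v = np.array([i, j, k], dtype=float)
                    if not np.any(v):
                        continue
                    v = v / np.linalg.norm(v) * r
                    idx += 1
                    shell_atoms.append((f"C{idx}", "C", tuple(v)))
    shell = _residue("SHL", 1, "S", shell_atoms)
    free = _residue("ALA", 1, "B", [
        ("N", "N", (101.4, 0, 0)), ("CA", "C", (100, 0, 0)), ("C", "C", (98.6, 0.4, 0)),
        ("O", "O", (98.0, 1.2, 0.8)), ("CB", "C", (100.3, 1.2, 1.0)),
    ])
    return StructureModel("SHELL", [Chain("A", [enclosed]), Chain("S", [shell]),
                                    Chain("B", [free])])


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        area = compute_atom_sasa(np.zeros((1, 3)), np.array([1.7]))[0]
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_two_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        radii = np.array([1.7, 1.55])
        areas = compute_atom_sasa(coords, radii)
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)
        assert areas[1] == pytest.approx(4 * np.pi * (1.55 + 1.4) ** 2, rel=0.01)

    def test_cubic_shell_occludes_center(self):
        # 26 atoms on a cube surface at 2.5 A bury the central atom
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0, 0]] + [o / np.linalg.norm(o) * 2.5 for o in offsets])
        radii = np.full(len(coords), 1.7)
        area_default = compute_atom_sasa(coords, radii)[0]
        area_highres = compute_atom_sasa(coords, radii, n_points=5000)[0]
        assert area_default < 1.0
        assert area_highres < 1.0
        assert area_default == pytest.approx(area_highres, abs=0.5)

    def test_adding_atoms_never_increases_sasa(self):
        rng = np.random.default_rng(0)
        base = rng.normal(scale=3.0, size=(10, 3))
        extra = rng.normal(scale=3.0, size=(5, 3))
        radii10 = np.full(10, 1.7)
        before = compute_atom_sasa(base, radii10)
        after = compute_atom_sasa(np.vstack([base, extra]), np.full(15, 1.7))[:10]
        assert np.all(after <= before + 1e-9)

    def test_waters_do_not_occlude(self):
        ala = _residue("ALA", 1, "A", [("CA", "C", (0, 0, 0))])
        water = _residue("HOH", 1, "W", [("O", "O", (2.5, 0, 0))])
        model = StructureModel("W", [Chain("A", [ala]), Chain("W", [water])])
        sasa = compute_sasa(model)
        assert ("W", 1, "", "O") not in sasa
        assert sasa[("A", 1, "", "CA")] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)


class TestResidueRsa:
    def test_extended_central_alanine_near_maximum(self):
        # Gly-Ala-Gly matches the context the theoretical maxima are defined in
        chain = build_peptide("GAG", 180.0, 180.0)
        model = StructureModel("T", [chain])
        sasa = compute_sasa(model)
        values = residue_rsa(chain.residues[1], sasa, "A")
        assert 0.8 <= values["rsa_all"] <= 1.3

    def test_enclosed_residue_buried(self):
        model = _shell_model()
        sasa = compute_sasa(model)
        buried = residue_rsa(model.chain("A").residue(1), sasa, "A")
        free = residue_rsa(model.chain("B").residue(1), sasa, "B")
        assert buried["rsa_all"] < 0.16
        assert free["rsa_all"] > 0.8

    def test_glycine_sidechain_undefined(self):
        chain = build_peptide("GGG", -120.0, 130.0)
        model = StructureModel("G", [chain])
        sasa = compute_sasa(model)
        values = residue_rsa(chain.residues[1], sasa, "A")
        assert values["rsa_sidechain"] is None
        assert values["sasa_sidechain"] is None
        assert values["rsa_all"] is not None

    def test_unknown_residue_uses_mean_maximum(self):
        res = _residue("XXX", 1, "A", [("CA", "C", (0, 0, 0))])
        model = StructureModel("X", [Chain("A", [res])])
        sasa = compute_sasa(model)
        values = residue_rsa(res, sasa, "A")
        assert values["rsa_all"] is not None


def _spread_chain_with_close_pair(sep: int, distance: float = 4.0) -> Chain:
    """Protein chain where residue 1 and residue 1+sep are `distance` apart
    and every other residue pair is far beyond the contact cutoff."""
    residues = []
    for i in range(sep + 1):
        base = np.array([0.0, 30.0 * (i + 1), 0.0])
        residues.append(_residue("ALA", i + 1, "A", [
            ("N", "N", tuple(base)), ("CA", "C", tuple(base + [1.4, 0, 0])),
            ("C", "C", tuple(base + [2.8, 0, 0])),
        ]))
    # move the last residue next to the first
    last = residues[-1]
    for a, (dx, dy, dz) in zip(last.atoms, ([0, 0, 0], [1.4, 0, 0], [2.8, 0, 0])):
        a.x, a.y, a.z = dx, 30.0 + distance, dz
    return Chain("A", residues)


class TestContacts:
    def test_dimer_interface_contacts(self, dimer_fixture):
        contacts = find_contacts(dimer_fixture.model)
        inter = {c.res_key for c in contacts if c.category == "protein"}
        expected = {("A" if cid == "A" else "B", rn, "")
                    for (cid, rn), label in dimer_fixture.ground_truth.items()
                    if label == "interface"}
        assert expected <= inter

    def test_adjacent_backbone_c_n_excluded(self):
        chain = build_peptide("AA", -57.0, -47.0)
        contacts = find_contacts(StructureModel("T", [chain]))
        for c in contacts:
            if c.res_key == ("A", 1, "") and c.partner_key == ("A", 2, ""):
                assert not (c.atom_name == "C" and c.partner_resname == "ALA"
                            and c.distance < 1.5)
        # the peptide-bond pair itself is gone: no C->N record at bond length
        bond_pairs = [c for c in contacts
                      if c.atom_name in ("C", "N") and c.distance < 1.6]
        assert bond_pairs == []

    @pytest.mark.parametrize("sep,expected", [
        (4, "intra_short"), (5, "intra_short"), (6, "intra_short"),
        (7, "intra_long"), (8, "intra_long"), (9, "intra_long"),
    ])
    def test_sequence_separation_split(self, sep, expected):
        chain = _spread_chain_with_close_pair(sep)
        contacts = find_contacts(StructureModel("T", [chain]))
        cats = {c.category for c in contacts
                if c.res_key == ("A", 1, "") and c.partner_key == ("A", sep + 1, "")}
        assert cats == {expected}

    def test_symmetric(self, ligand_fixture):
        contacts = find_contacts(ligand_fixture.model)
        directed = {(c.res_key, c.partner_key, c.atom_name, round(c.distance, 6))
                    for c in contacts}
        for c in contacts:
            mirrored = [d for d in contacts
                        if d.res_key == c.partner_key and d.partner_key == c.res_key
                        and round(d.distance, 6) == round(c.distance, 6)]
            assert mirrored
        assert directed  # non-empty

    def test_empty_model_no_contacts(self):
        res = _residue("ALA", 1, "A", [("CA", "C", (0, 0, 0))])
        assert find_contacts(StructureModel("E", [Chain("A", [res])])) == []


class TestRin:
    def test_three_residue_strand_two_covalent_edges(self):
        residues = [
            _residue("ALA", i, "A", [("CA", "C", (0, 20.0 * i, 0))])
            for i in (1, 2, 3)
        ]
        model = StructureModel("S", [Chain("A", residues)])
        rin = build_rin(model, find_contacts(model))
        assert rin.number_of_edges() == 2
        assert all(d["kind"] == "covalent" for _, _, d in rin.edges(data=True))

    def test_boundary_distance_weight_zero(self):
        r1 = _residue("ALA", 1, "A", [("CA", "C", (0, 0, 0))])
        r2 = _residue("ALA", 5, "A", [("CA", "C", (5.0, 0, 0))])
        model = StructureModel("B", [Chain("A", [r1, r2])])
        contacts = find_contacts(model)
        rin = build_rin(model, contacts)
        if rin.has_edge(("A", 1, ""), ("A", 5, "")):
            edge = rin.edges[("A", 1, ""), ("A", 5, "")]
            if edge["kind"] == "noncovalent":
                assert edge["weight"] == pytest.approx(0.0, abs=1e-9)

    def test_weights_match_pairwise_recomputation(self):
        chain = build_peptide("AAAAA", -57.0, -47.0)
        model = StructureModel("T", [chain])
        rin = build_rin(model, find_contacts(model))
        for u, v, data in rin.edges(data=True):
            if data["kind"] != "noncovalent":
                continue
            ru = model.chain(u[0]).residue(u[1], u[2])
            rv = model.chain(v[0]).residue(v[1], v[2])
            adjacent = abs(rin.nodes[u]["chain_index"] - rin.nodes[v]["chain_index"]) == 1
            expected = 0.0
            for a in ru.atoms:
                for b in rv.atoms:
                    if adjacent and {a.name, b.name} == {"C", "N"}:
                        continue
                    d = float(np.linalg.norm(a.coord - b.coord))
                    if d <= 5.0:
                        expected += 1 - d / 5.0
            assert data["weight"] == pytest.approx(expected)

    def test_no_self_edges(self, dimer_fixture):
        model = dimer_fixture.model
        rin = build_rin(model, find_contacts(model))
        assert all(u != v for u, v in rin.edges)


class TestInteractionScores:
    def _ligand_toy(self, n_ligand_atoms=1):
        ala = _residue("ALA", 1, "A", [
            ("N", "N", (10.0, 0, 0)), ("CA", "C", (11.4, 0, 0)),
            ("C", "C", (12.8, 0, 0)), ("O", "O", (14.0, 0, 0)),
            ("CB", "C", (0.0, 0, 0)),
        ])
        lig_atoms = [(f"C{i+1}", "C", (0.0, 0, 3.5 + 0.5 * i))
                     for i in range(n_ligand_atoms)]
        lig = _residue("LIG", 1, "L", lig_atoms)
        model = StructureModel("TOY", [Chain("A", [ala]), Chain("L", [lig])])
        rin = build_rin(model, find_contacts(model))
        return rin

    def test_isolated_residue_all_zero(self):
        ala = _residue("ALA", 1, "A", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        model = StructureModel("I", [Chain("A", [ala])])
        rin = build_rin(model, find_contacts(model))
        scores = interaction_scores(rin, ("A", 1, ""), {"mainchain": 1, "sidechain": 1})
        assert all(v == (0.0, 0.0) for v in scores.values())

    def test_single_sidechain_ligand_contact(self):
        rin = self._ligand_toy()
        scores = interaction_scores(rin, ("A", 1, ""), {"mainchain": 4, "sidechain": 1})
        score, degree = scores[("sidechain", "ligand")]
        assert degree == 1.0
        assert score == pytest.approx((1 - 3.5 / 5.0) / (10 * 1))
        assert scores[("mainchain", "ligand")] == (0.0, 0.0)

    def test_degree_counts_partner_once(self):
        rin = self._ligand_toy(n_ligand_atoms=3)  # atoms at 3.5, 4.0, 4.5
        scores = interaction_scores(rin, ("A", 1, ""), {"mainchain": 4, "sidechain": 1})
        score, degree = scores[("sidechain", "ligand")]
        assert degree == 1.0
        expected = ((1 - 3.5 / 5) + (1 - 4.0 / 5) + (1 - 4.5 / 5)) / 10
        assert score == pytest.approx(expected)

    def test_glycine_sidechain_undefined(self):
        rin = self._ligand_toy()
        scores = interaction_scores(rin, ("A", 1, ""), {"mainchain": 4, "sidechain": 0})
        assert scores[("sidechain", "ligand")] == (None, None)


class TestSecondaryStructure:
    def test_helix_interior(self):
        chain = build_peptide("AAAAAAAAAA", -57.0, -47.0)
        states = assign_secondary_structure(chain)
        assert states[0] == "C" and states[-1] == "C"
        assert set(states[1:-1]) == {"H"}

    def test_strand(self):
        chain = build_peptide("AAAAAAAAAA", -120.0, 130.0)
        states = assign_secondary_structure(chain)
        assert set(states[1:-1]) == {"E"}

    def test_neither_is_coil(self):
        chain = build_peptide("AAAAAAAAAA", 60.0, 60.0)
        states = assign_secondary_structure(chain)
        assert set(states) == {"C"}


class TestNeighborhood:
    def test_isolated_helix_other_chain_undefined(self, helix_fixture):
        model = helix_fixture.model
        rsa = {("A", r.resnum, ""): 0.5 for r in model.chains[0].residues}
        profile = neighborhood_profile(model, rsa, ("A", 10, ""))
        assert profile["nbr_other_chain_count"] == 0.0
        assert profile["nbr_other_chain_rsa_median"] is None
        assert profile["nbr_same_chain_count"] >= 4

    def test_dimer_interface_sees_other_chain(self, dimer_fixture):
        model = dimer_fixture.model
        rsa = {(c.chain_id, r.resnum, ""): 0.5
               for c in model.chains for r in c.residues}
        interface = next(k for k, v in dimer_fixture.ground_truth.items()
                         if v == "interface")
        profile = neighborhood_profile(model, rsa, (interface[0], interface[1], ""))
        assert profile["nbr_other_chain_count"] >= 1.0

    def test_median_matches_direct_recomputation(self):
        focal = _residue("ALA", 1, "A", [("CA", "C", (0, 0, 0))])
        others = [
            _residue("ALA", i + 2, "A", [("CA", "C", (3.0 + i, 0, 0))])
            for i in range(4)
        ]
        model = StructureModel("N", [Chain("A", [focal] + others)])
        rsa = {("A", 1, ""): 0.9, ("A", 2, ""): 0.1, ("A", 3, ""): 0.2,
               ("A", 4, ""): 0.3, ("A", 5, ""): 0.4}
        profile = neighborhood_profile(model, rsa, ("A", 1, ""))
        assert profile["nbr_same_chain_count"] == 4.0
        assert profile["nbr_same_chain_rsa_median"] == pytest.approx(
            float(np.median([0.1, 0.2, 0.3, 0.4])))
        assert profile["nbr_same_chain_rsa_min"] == pytest.approx(0.1)
        assert profile["nbr_same_chain_rsa_max"] == pytest.approx(0.4)


class TestAnalyzeStructure:
    def test_every_residue_has_all_100_slots(self, ligand_fixture):
        analysis = analyze_structure(ligand_fixture.model)
        assert len(analysis.residues) == 20
        for rf in analysis.residues.values():
            assert tuple(rf.values.keys()) == FEATURE_NAMES

    def test_buried_below_surface_rsa(self):
        model = _shell_model()
        analysis = analyze_structure(model)
        assert (analysis.residues[("A", 1, "")].values["rsa_all"]
                < analysis.residues[("B", 1, "")].values["rsa_all"])

    def test_deterministic(self, dimer_fixture):
        a = analyze_structure(dimer_fixture.model)
        b = analyze_structure(dimer_fixture.model)
        assert {k: rf.values for k, rf in a.residues.items()} == \
               {k: rf.values for k, rf in b.residues.items()}

    def test_lite_subset(self, dimer_fixture):
        full = analyze_structure(dimer_fixture.model)
        subset = analyze_structure(dimer_fixture.model,
                                   only_residues={("A", 5, ""), ("B", 7, "")})
        assert set(subset.residues) == {("A", 5, ""), ("B", 7, "")}
        for key, rf in subset.residues.items():
            assert rf.values == full.residues[key].values

    def test_centralities_match_brute_force(self):
        chain = build_peptide("AAAAAAAA", -57.0, -47.0)
        model = StructureModel("C", [chain])
        rin = build_rin(model, find_contacts(model))
        assert rin.number_of_nodes() <= 30
        cents = rin_centralities(rin)
        nodes = list(rin.nodes)
        edges = list(rin.edges)
        for node in nodes:
            assert cents[node]["rin_complex_all_closeness"] == pytest.approx(
                brute_force_closeness(nodes, edges, node))
            assert cents[node]["rin_complex_all_betweenness"] == pytest.approx(
                brute_force_betweenness(nodes, edges, node))
            assert cents[node]["rin_complex_all_clustering"] == pytest.approx(
                brute_force_clustering(nodes, edges, node))

    def test_ligand_fixture_degrees(self, ligand_fixture):
        analysis = analyze_structure(ligand_fixture.model)
        target = analysis.residues[("A", 8, "")]
        assert (target.values["sidechain_ligand_degree"] or 0) >= 1.0
        assert target.ligand_partners == ("LIG",)
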