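"""Residue interaction network construction and per-residue graph features.

Edges carry a distance-derived weight: each contacting atom pair at distance
``d`` contributes ``1 - d / cutoff``; covalent backbone links weigh 1.  The
per-edge bookkeeping keeps the contribution split by the atom part
(mainchain/sidechain) on each side so interaction scores can be read off the
graph directly.
"""

from __future__ import annotations

from collections import defaultdict

import networkx as nx

from ..structures_io.model import StructureModel
from .contacts import Contact, ResKey


def build_rin(model: StructureModel, contacts: list[Contact], cutoff: float = 5.0) -> nx.Graph:
    """Graph over all non-water residues of the complex.

    Node attributes: ``chain``, ``entity``, ``resname``, ``chain_index``.
    Edge attributes: ``kind`` (covalent|noncovalent), ``weight``, ``part``
    (mainchain|sidechain|mixed over all contributing atoms), ``part_weights``
    and ``part_counts`` (per endpoint, per part), ``separation``.
    """
    g = nx.Graph()
    for chain in model.chains:
        index = 0
        for res in chain.residues:
            if res.entity_type == "water":
                continue
            key = (chain.chain_id, res.resnum, res.icode)
            g.add_node(key, chain=chain.chain_id, entity=res.entity_type,
                       resname=res.resname, chain_index=index)
            index += 1
        # covalent edges between chain-adjacent polymer residues
        polymer = [r for r in chain.residues if r.entity_type in ("protein", "dna", "rna")]
        for a, b in zip(polymer, polymer[1:]):
            ka = (chain.chain_id, a.resnum, a.icode)
            kb = (chain.chain_id, b.resnum, b.icode)
            g.add_edge(ka, kb, kind="covalent", weight=1.0, part="mainchain",
                       part_weights={}, part_counts={}, separation=1)

    agg: dict[tuple[ResKey, ResKey], dict] = {}
    for c in contacts:
        a, b = c.res_key, c.partner_key
        if a > b:
            continue  # directed duplicates: process each unordered pair once
        key = (a, b)
        if key not in agg:
            agg[key] = {
                "weight": 0.0,
                "part_weights": {a: defaultdict(float), b: defaultdict(float)},
                "part_counts": {a: defaultdict(int), b: defaultdict(int)},
                "parts": set(),
                "separation": c.separation,
            }
        rec = agg[key]
        w = max(0.0, 1.0 - c.distance / cutoff)
        rec["weight"] += w
        rec["part_weights"][a][c.part] += w
        rec["part_counts"][a][c.part] += 1
        rec["parts"].add(c.part)

    # fill in the partner-side split from the mirrored records
    for c in contacts:
        a, b = c.res_key, c.partner_key
        if a <= b:
            continue
        rec = agg[(b, a)]
        w = max(0.0, 1.0 - c.distance / cutoff)
        rec["part_weights"][a][c.part] += w
        rec["part_counts"][a][c.part] += 1
        rec["parts"].add(c.part)

    for (a, b), rec in agg.items():
        if g.has_edge(a, b) and g.edges[a, b]["kind"] == "covalent":
            continue  # covalent wins for chain neighbours
        part = rec["parts"].pop() if len(rec["parts"]) == 1 else "mixed"
        g.add_edge(a, b, kind="noncovalent", weight=rec["weight"], part=part,
                   part_weights={k: dict(v) for k, v in rec["part_weights"].items()},
                   part_counts={k: dict(v) for k, v in rec["part_counts"].items()},
                   separation=rec["separation"])
    return g


def _edge_category(g: nx.Graph, focal: ResKey, partner: ResKey,
                   short_max: int) -> str:
    """Interaction type of a neighbour from the focal residue's perspective."""
    pdata = g.nodes[partner]
    if pdata["entity"] != "protein":
        return pdata["entity"]
    if g.nodes[focal]["chain"] == pdata["chain"]:
        sep = abs(g.nodes[focal]["chain_index"] - pdata["chain_index"])
        return "intra_short" if sep <= short_max else "intra_long"
    return "protein"


def interaction_scores(
    g: nx.Graph,
    residue_key: ResKey,
    n_atoms_by_part: dict[str, int],
    short_range_max_separation: int = 6,
) -> dict[tuple[str, str], tuple[float | None, float | None]]:
    """(part, type) -> (score, degree) from the residue's noncovalent edges.

    score(part, type) = sum of that part's edge-weight contributions to
    partners of that type / (10 * heavy atoms of the part).  Parts with no
    atoms (glycine sidechain) yield undefined entries.
    """
    from ..registry import INTERACTION_TYPES, PARTS

    sums: dict[tuple[str, str], float] = defaultdict(float)
    partners: dict[tuple[str, str], set] = defaultdict(set)
    if residue_key in g:
        for partner in g.neighbors(residue_key):
            edge = g.edges[residue_key, partner]
            if edge["kind"] != "noncovalent":
                continue
            category = _edge_category(g, residue_key, partner, short_range_max_separation)
            pw = edge["part_weights"].get(residue_key, {})
            pc = edge["part_counts"].get(residue_key, {})
            for part in PARTS:
                if pc.get(part, 0) > 0:
                    sums[(part, category)] += pw.get(part, 0.0)
                    partners[(part, category)].add(partner)

    out: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for part in PARTS:
        n_atoms = n_atoms_by_part.get(part, 0)
        for itype in INTERACTION_TYPES:
            if n_atoms == 0:
                out[(part, itype)] = (None, None)
            else:
                out[(part, itype)] = (
                    sums[(part, itype)] / (10.0 * n_atoms),
                    float(len(partners[(part, itype)])),
                )
    return out


def _subgraph(g: nx.Graph, chain: str | None, edgeset: str) -> nx.Graph:
    nodes = [n for n, d in g.nodes(data=True) if chain is None or d["chain"] == chain]
    sub = g.subgraph(nodes)
    if edgeset == "all":
        return sub
    keep = [(u, v) for u, v, d in sub.edges(data=True) if d["part"] == edgeset]
    out = nx.Graph()
    out.add_nodes_from(sub.nodes(data=True))
    out.add_edges_from((u, v, sub.edges[u, v]) for u, v in keep)
    return out


def rin_centralities(g: nx.Graph) -> dict[ResKey, dict[str, float | None]]:
    """The 36 graph features per node: 6 metrics x {complex, chain} x
    {all, sidechain, mainchain} edge sets.

    Closeness, betweenness and clustering are computed on the unweighted
    topology; weighted degree and mean edge weight use the contact weights.
    """
    from ..registry import CENTRALITY_EDGESETS, CENTRALITY_SCOPES

    out: dict[ResKey, dict[str, float | None]] = {n: {} for n in g.nodes}
    chains = sorted({d["chain"] for _, d in g.nodes(data=True)})
    for scope in CENTRALITY_SCOPES:
        scope_graphs = []
        if scope == "complex":
            scope_graphs.append((None, g))
        else:
            scope_graphs.extend((c, None) for c in chains)
        for chain, base in scope_graphs:
            for edgeset in CENTRALITY_EDGESETS:
                sub = _subgraph(g, chain, edgeset)
                closeness = nx.closeness_centrality(sub)
                betweenness = nx.betweenness_centrality(sub, normalized=True)
                clustering = nx.clustering(sub)
                prefix = f"rin_{scope}_{edgeset}_"
                for node in sub.nodes:
                    edges = sub.edges(node, data=True)
                    weights = [d["weight"] for _, _, d in edges]
                    feats = out[node]
                    feats[prefix + "weighted_degree"] = float(sum(weights))
                    feats[prefix + "degree"] = float(len(weights))
                    feats[prefix + "closeness"] = float(closeness[node])
                    feats[prefix + "betweenness"] = float(betweenness[node])
                    feats[prefix + "clustering"] = float(clustering[node])
                    feats[prefix + "mean_edge_weight"] = (
                        float(sum(weights) / len(weights)) if weights else None
                    )
    return out
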