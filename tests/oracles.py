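"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / graph /
quadrature code paths: alignments are enumerated exhaustively, SASA is
re-quadratured at high resolution, and graph metrics are recomputed from
first principles.
"""

from __future__ import annotations

from structannot.search_align import substitution_score


def score_gapped_alignment(aq: str, at: str, gap_open: float = 10.0,
                           gap_extend: float = 0.5) -> float:
    """Score a gapped string pair: terminal gap runs are free, an internal
    run of length L costs gap_open + (L-1)*gap_extend."""
    assert len(aq) == len(at)
    total = 0.0
    for s in (aq, at):
        i = 0
        while i < len(s):
            if s[i] == "-":
                j = i
                while j < len(s) and s[j] == "-":
                    j += 1
                if i != 0 and j != len(s):
                    total -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    for a, b in zip(aq, at):
        if a != "-" and b != "-":
            total += substitution_score(a, b)
    return total


def enumerate_alignments(q: str, t: str):
    """Yield every monotone global alignment of q and t as gapped strings."""

    def rec(i: int, j: int):
        if i == len(q) and j == len(t):
            yield ("", "")
            return
        if i < len(q) and j < len(t):
            for a, b in rec(i + 1, j + 1):
                yield (q[i] + a, t[j] + b)
        if i < len(q):
            for a, b in rec(i + 1, j):
                yield (q[i] + a, "-" + b)
        if j < len(t):
            for a, b in rec(i, j + 1):
                yield ("-" + a, t[j] + b)

    return rec(0, 0)


def brute_force_alignment_score(q: str, t: str, gap_open: float = 10.0,
                                gap_extend: float = 0.5) -> float:
    return max(score_gapped_alignment(a, b, gap_open, gap_extend)
               for a, b in enumerate_alignments(q, t))


def brute_force_closeness(nodes, edges, node):
    """Unweighted closeness centrality, networkx convention (Wasserman-Faust
    scaling for disconnected graphs), via breadth-first search."""
    adjacency = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    dist = {node: 0}
    frontier = [node]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adjacency[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    reachable = len(dist) - 1
    if reachable == 0:
        return 0.0
    total = sum(dist.values())
    return (reachable / total) * (reachable / (len(nodes) - 1))


def brute_force_betweenness(nodes, edges, node):
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    import itertools

    adjacency = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    def all_shortest_paths(s, t):
        if s == t:
            return []
        paths = [[s]]
        found = []
        seen_len = None
        while paths and found == []:
            nxt = []
            for p in paths:
                for w in adjacency[p[-1]]:
                    if w in p:
                        continue
                    if w == t:
                        found.append(p + [w])
                    else:
                        nxt.append(p + [w])
            paths = nxt
        return found

    score = 0.0
    others = [n for n in nodes if n != node]
    for s, t in itertools.combinations(others, 2):
        sps = all_shortest_paths(s, t)
        if not sps:
            continue
        through = sum(1 for p in sps if node in p[1:-1])
        score += through / len(sps)
    n = len(nodes)
    if n > 2:
        score /= (n - 1) * (n - 2) / 2
    return score


def brute_force_clustering(nodes, edges, node):
    adjacency = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    nbrs = list(adjacency[node])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    for i in range(k):
        for j in range(i + 1, k):
            if nbrs[j] in adjacency[nbrs[i]]:
                links += 1
    return 2.0 * links / (k * (k - 1))
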