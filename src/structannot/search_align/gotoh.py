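"""Affine-gap global alignment with free end gaps (three-state Gotoh).

Gap run of length L costs ``gap_open + (L - 1) * gap_extend``; terminal gap
runs in either sequence cost nothing.  Substitution scores come from
BLOSUM62.  Traceback tie-breaking is deterministic: diagonal over
gap-in-template over gap-in-query.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NEG_INF = float("-inf")

VALID_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYXU")


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def substitution_score(a: str, b: str) -> float:
    table = _blosum62()
    a = "C" if a == "U" else a
    b = "C" if b == "U" else b
    return table[(a, b)]


def _validate(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - VALID_CHARS
    if bad:
        raise ValueError(f"{label} sequence contains invalid characters: {sorted(bad)}")


@dataclass
class AlignmentResult:
    aligned_query: str
    aligned_template: str
    score: float
    core_start: int
    core_end: int
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_template):
            raise ValueError("gapped strings differ in length")


def _core_bounds(aq: str, at: str) -> tuple[int, int]:
    def first_non_gap(s: str) -> int:
        for i, ch in enumerate(s):
            if ch != "-":
                return i
        return len(s)

    def last_non_gap(s: str) -> int:
        for i in range(len(s) - 1, -1, -1):
            if s[i] != "-":
                return i
        return -1

    start = max(first_non_gap(aq), first_non_gap(at))
    end = min(last_non_gap(aq), last_non_gap(at)) + 1
    return (start, max(start, end))


def sequence_identity_core(aln: AlignmentResult) -> float:
    """Identical pairs / core columns; end-gap columns are excluded, internal
    gap columns count in the denominator."""
    start, end = aln.core_start, aln.core_end
    if end <= start:
        return 0.0
    matches = sum(
        1
        for i in range(start, end)
        if aln.aligned_query[i] == aln.aligned_template[i] and aln.aligned_query[i] != "-"
    )
    return matches / (end - start)


def align_global_free_end(
    query: str,
    template_seq: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal free-end-gap global alignment of two protein sequences."""
    _validate(query, "query")
    _validate(template_seq, "template")
    q, t = query, template_seq
    n, m = len(q), len(t)
    sub = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = substitution_score(q[i], t[j])

    # state matrices: M diagonal, X gap in template (query consumed),
    # Y gap in query (template consumed)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # free leading gap in template
    Y[0, 1:] = 0.0  # free leading gap in query

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)

    # free trailing gaps: best score on the last row or column, any state
    best = (NEG_INF, None)
    for i in range(n + 1):
        for state, mat in (("M", M), ("X", X), ("Y", Y)):
            s = mat[i, m]
            if s > best[0]:
                best = (s, (i, m, state))
    for j in range(m + 1):
        for state, mat in (("M", M), ("X", X), ("Y", Y)):
            s = mat[n, j]
            if s > best[0]:
                best = (s, (n, j, state))
    score, (bi, bj, bstate) = best

    # traceback with deterministic state priority (M > X > Y)
    aq: list[str] = []
    at: list[str] = []
    # trailing gaps
    for i in range(n, bi, -1):
        aq.append(q[i - 1])
        at.append("-")
    for j in range(m, bj, -1):
        aq.append("-")
        at.append(t[j - 1])

    i, j, state = bi, bj, bstate
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                # M only valid at origin
                break
            aq.append(q[i - 1])
            at.append(t[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i, j] - target) < eps:
                    state = cand
                    break
        elif state == "X":
            if j == 0:
                # leading free gap in template
                for k in range(i, 0, -1):
                    aq.append(q[k - 1])
                    at.append("-")
                i = 0
                break
            aq.append(q[i - 1])
            at.append("-")
            val = X[i, j]
            i -= 1
            if abs(M[i, j] - gap_open - val) < eps:
                state = "M"
            elif abs(X[i, j] - gap_extend - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            if i == 0:
                for k in range(j, 0, -1):
                    aq.append("-")
                    at.append(t[k - 1])
                j = 0
                break
            aq.append("-")
            at.append(t[j - 1])
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] - gap_open - val) < eps:
                state = "M"
            elif abs(Y[i, j] - gap_extend - val) < eps:
                state = "Y"
            else:
                state = "X"

    aligned_query = "".join(reversed(aq))
    aligned_template = "".join(reversed(at))
    start, end = _core_bounds(aligned_query, aligned_template)
    result = AlignmentResult(aligned_query, aligned_template, float(score), start, end, 0.0)
    result.identity = sequence_identity_core(result)
    return result
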