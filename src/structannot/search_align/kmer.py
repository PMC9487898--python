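"""Built-in candidate search: exact shared k-mers at maximal sensitivity.

This replaces an external similarity-search tool at desk scale.  Any callable
with the same ``(query, chain_sequences, k) -> candidate keys`` signature can
be plugged into the pipeline instead.
"""

from __future__ import annotations

from collections import defaultdict


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_candidates(
    query: str,
    chain_sequences: dict[tuple[str, str], str],
    k: int = 5,
) -> list[tuple[str, str]]:
    """Every library chain sharing at least one exact k-mer with the query.

    A query shorter than ``k`` falls back to returning all chains.  The
    result order is deterministic (sorted by key).
    """
    keys = sorted(chain_sequences)
    if len(query) < k:
        return keys
    query_kmers = _kmers(query, k)
    if not query_kmers:
        return keys
    index: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for key in keys:
        for kmer in _kmers(chain_sequences[key], k):
            index[kmer].add(key)
    hits: set[tuple[str, str]] = set()
    for kmer in query_kmers:
        hits |= index.get(kmer, set())
    return sorted(hits)
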