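"""Quality-weighted aggregation of per-structure features (the W(D) mean).

Undefined values never enter the sums; accessibility features additionally
weight each annotation by its squared alignment coverage, biasing partially
resolved structures toward the buried call.
"""

from __future__ import annotations

from collections.abc import Sequence

from ..registry import FEATURE_NAMES, RSA_BIASED_FEATURES


def quality_score(identity: float, coverage: float, resolution: float | None) -> float:
    """Per-annotation weight from identity, coverage and structure resolution.

    The resolution factor is clamp((6.5 - res) / 5, 0.1, 1.0); structures
    without a stated resolution (models) count as 3.5 A.
    """
    res = 3.5 if resolution is None else resolution
    r = min(max((6.5 - res) / 5.0, 0.1), 1.0)
    q = identity * coverage * r
    return max(q, 1e-9)


def weighted_aggregate(
    values: Sequence[float | None],
    qualities: Sequence[float],
) -> float | None:
    """W = sum(q_i * d_i) / sum(q_i) over defined d_i; all-undefined -> None."""
    if len(values) != len(qualities):
        raise ValueError("values and qualities must be parallel")
    num = 0.0
    den = 0.0
    for d, q in zip(values, qualities):
        if q < 0:
            raise ValueError(f"negative quality {q}")
        if d is None:
            continue
        num += q * d
        den += q
    if den == 0.0:
        return None
    return num / den


def aggregate_rsa(
    values: Sequence[float | None],
    qualities: Sequence[float],
    coverages: Sequence[float],
) -> float | None:
    """Accessibility aggregation: weights are q_i * coverage_i**2."""
    if not (len(values) == len(qualities) == len(coverages)):
        raise ValueError("values, qualities and coverages must be parallel")
    weights = [q * c * c for q, c in zip(qualities, coverages)]
    return weighted_aggregate(values, weights)


def aggregate_feature_vectors(
    vectors: Sequence[dict[str, float | None]],
    qualities: Sequence[float],
    coverages: Sequence[float],
) -> dict[str, float | None]:
    """Aggregate the full 100-entry registry across annotations."""
    out: dict[str, float | None] = {}
    for name in FEATURE_NAMES:
        values = [v.get(name) for v in vectors]
        if name in RSA_BIASED_FEATURES:
            out[name] = aggregate_rsa(values, qualities, coverages)
        else:
            out[name] = weighted_aggregate(values, qualities)
    return out
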