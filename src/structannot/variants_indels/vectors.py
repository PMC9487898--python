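"""SAV (123-entry) and indel (600-entry) feature vector assembly."""

from __future__ import annotations

from ..aggregation_classify.aggregate import weighted_aggregate
from ..aggregation_classify.positions import AggregatedPosition
from ..registry import (
    EVIDENCE_NAMES,
    FEATURE_NAMES,
    INDEL_REGIONS,
    INDEL_VECTOR_NAMES,
    SAV_VECTOR_NAMES,
)
from .indels import IndelDecomposition, span_positions


def sav_feature_vector(agg: AggregatedPosition | None) -> dict[str, float | None]:
    """The 123 named entries for one position: 100 aggregated registry
    features followed by the 23 evidence features."""
    out: dict[str, float | None] = dict.fromkeys(SAV_VECTOR_NAMES)
    if agg is None:
        return out
    if agg.features is not None:
        for name in FEATURE_NAMES:
            out[name] = agg.features.get(name)
    for name in EVIDENCE_NAMES:
        out[name] = agg.evidence.get(name)
    return out


def _aggregate_region(
    positions: list[int],
    aggs: dict[int, AggregatedPosition],
) -> dict[str, float | None]:
    """Eq.-1 style aggregation of a region block across its positions.

    Position weights are the mean annotation quality of each position;
    unmapped positions contribute nothing.
    """
    block: dict[str, float | None] = dict.fromkeys(FEATURE_NAMES)
    rows = []
    weights = []
    for pos in positions:
        agg = aggs.get(pos)
        if agg is None or agg.features is None:
            continue
        w = agg.mean_quality
        if w is None or w <= 0:
            continue
        rows.append(agg.features)
        weights.append(w)
    if not rows:
        return block
    for name in FEATURE_NAMES:
        block[name] = weighted_aggregate([r.get(name) for r in rows], weights)
    return block


def aggregate_indel_features(
    wt_aggs: dict[int, AggregatedPosition],
    mut_aggs: dict[int, AggregatedPosition],
    dec: IndelDecomposition,
) -> dict[str, float | None]:
    """The 600 named entries for one indel: six region blocks, each the 100
    aggregatable registry features, concatenated in fixed order.  Empty
    regions contribute a fully undefined block."""
    spans = dict(zip(INDEL_REGIONS, dec.wt_spans() + dec.mut_spans()))
    out: dict[str, float | None] = {}
    for region in INDEL_REGIONS:
        aggs = wt_aggs if region.startswith("wt_") else mut_aggs
        block = _aggregate_region(span_positions(spans[region]), aggs)
        for name in FEATURE_NAMES:
            out[f"{region}__{name}"] = block[name]
    assert tuple(out) == INDEL_VECTOR_NAMES
    return out
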