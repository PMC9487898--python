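"""Assembly of one fully aggregated, classified query position."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..config import AnalysisConfig, DEFAULT_CONFIG
from ..residue_analysis.features import ResidueFeatures
from ..search_align.mapping import SeqToStructAnnotation
from .aggregate import aggregate_feature_vectors
from .classify import classify_position
from .evidence import evidence_features, select_recommended


@dataclass
class AggregatedPosition:
    query_id: str
    position: int
    features: dict[str, float | None] | None  # None when unmapped
    labels: dict[str, str | None] = field(default_factory=dict)
    evidence: dict[str, float | None] = field(default_factory=dict)
    max_identity_annotation: SeqToStructAnnotation | None = None
    recommended_annotation: SeqToStructAnnotation | None = None
    max_identity_residue: ResidueFeatures | None = None
    recommended_residue: ResidueFeatures | None = None
    confidence: float | None = None

    @property
    def is_mapped(self) -> bool:
        return self.features is not None

    @property
    def mean_quality(self) -> float | None:
        return self.evidence.get("mean_quality")


def aggregate_position(
    query_id: str,
    position: int,
    annotations: list[SeqToStructAnnotation],
    residue_features: list[ResidueFeatures | None],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> AggregatedPosition:
    """Aggregate, classify and attach evidence for one query position.

    ``residue_features`` is parallel to ``annotations``: the analyzed
    residue the position maps to in that structure, or None.
    """
    mapped = [(a, rf) for a, rf in zip(annotations, residue_features) if rf is not None]
    if not mapped:
        labels = classify_position(None, config.rsa_threshold, config.degree_eps)
        evidence = evidence_features([], [], labels)
        return AggregatedPosition(query_id, position, None, labels, evidence)

    vectors = [rf.values for _, rf in mapped]
    qualities = [a.quality for a, _ in mapped]
    coverages = [a.coverage for a, _ in mapped]
    features = aggregate_feature_vectors(vectors, qualities, coverages)
    labels = classify_position(features, config.rsa_threshold, config.degree_eps)
    evidence = evidence_features(
        [a for a, _ in mapped], [rf for _, rf in mapped], labels
    )
    max_id_ann, rec_ann = select_recommended(
        [a for a, _ in mapped], [rf for _, rf in mapped]
    )
    by_ann = {id(a): rf for a, rf in mapped}
    return AggregatedPosition(
        query_id=query_id,
        position=position,
        features=features,
        labels=labels,
        evidence=evidence,
        max_identity_annotation=max_id_ann,
        recommended_annotation=rec_ann,
        max_identity_residue=by_ann.get(id(max_id_ann)),
        recommended_residue=by_ann.get(id(rec_ann)),
        confidence=evidence.get("mean_quality"),
    )
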