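"""Annotation acceptance, coverage and query-position -> residue mapping."""

from __future__ import annotations

from dataclasses import dataclass, field

from .gotoh import AlignmentResult

ResidueKey = tuple[int, str]  # (resnum, icode)


def accept_annotation(identity: float, threshold: float = 0.35, inclusive: bool = True) -> bool:
    """Retain a sequence-to-structure annotation by core identity."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0, 1], got {identity}")
    return identity >= threshold if inclusive else identity > threshold


def map_positions(
    aln: AlignmentResult,
    template_keys: list[ResidueKey],
    resolved: set[ResidueKey] | None = None,
) -> dict[int, ResidueKey]:
    """1-based query position -> template residue key for aligned columns.

    ``template_keys`` is positionally parallel to the ungapped template
    sequence.  Positions opposite gaps, or mapped to residues outside
    ``resolved`` (when given), stay unmapped.
    """
    mapping: dict[int, ResidueKey] = {}
    qpos = 0
    tpos = 0
    for qc, tc in zip(aln.aligned_query, aln.aligned_template):
        if qc != "-":
            qpos += 1
        if tc != "-":
            tpos += 1
        if qc != "-" and tc != "-":
            key = template_keys[tpos - 1]
            if resolved is None or key in resolved:
                mapping[qpos] = key
    return mapping


def alignment_coverage(aln: AlignmentResult, position_map: dict[int, ResidueKey]) -> float:
    """Fraction of query positions mapped to a resolved template residue."""
    query_length = sum(1 for c in aln.aligned_query if c != "-")
    if query_length == 0:
        return 0.0
    return len(position_map) / query_length


@dataclass
class SeqToStructAnnotation:
    """One accepted query-to-structure alignment with its derived metadata."""

    query_id: str
    entry_id: str
    chain_id: str
    alignment: AlignmentResult
    resolution: float | None
    position_map: dict[int, ResidueKey] = field(default_factory=dict)
    coverage: float = 0.0
    quality: float = 0.0
    is_own_structure: bool = False  # identity >= 0.99: experimentally resolved self

    @property
    def identity(self) -> float:
        return self.alignment.identity

    @property
    def structure_key(self) -> tuple[str, str]:
        return (self.entry_id, self.chain_id)
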