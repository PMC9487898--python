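"""Indel region decomposition: flanks and indel region for WT and MUT.

The flank length is half the indel length, rounded up (at least one
residue).  Insertions have an empty WT indel region, deletions an empty MUT
indel region; spans are clipped to the sequence bounds and may become empty
at the termini.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variants import Variant

Span = tuple[int, int] | None  # 1-based inclusive, None when empty


def _clip(start: int, end: int, length: int) -> Span:
    start = max(start, 1)
    end = min(end, length)
    if start > end:
        return None
    return (start, end)


@dataclass
class IndelDecomposition:
    wt_left_flank: Span
    wt_indel_region: Span
    wt_right_flank: Span
    mut_left_flank: Span
    mut_indel_region: Span
    mut_right_flank: Span
    flank_length: int

    def region(self, name: str) -> Span:
        return getattr(self, name)

    def wt_spans(self) -> tuple[Span, Span, Span]:
        return (self.wt_left_flank, self.wt_indel_region, self.wt_right_flank)

    def mut_spans(self) -> tuple[Span, Span, Span]:
        return (self.mut_left_flank, self.mut_indel_region, self.mut_right_flank)


def decompose_indel(seq_wt: str, seq_mut: str, variant: Variant) -> IndelDecomposition:
    if not variant.is_indel:
        raise ValueError(f"{variant.kind} is not an indel")
    flank = variant.flank_length
    n_wt, n_mut = len(seq_wt), len(seq_mut)
    left, right = variant.left, variant.right

    if variant.kind == "insertion":
        # insert after `left`; WT indel region is empty by definition
        wt_indel: Span = None
        wt_left = _clip(left - flank + 1, left, n_wt)
        wt_right = _clip(left + 1, left + flank, n_wt)
        n_ins = len(variant.alt_residues)
        mut_indel = _clip(left + 1, left + n_ins, n_mut)
        mut_left = _clip(left - flank + 1, left, n_mut)
        mut_right = _clip(left + n_ins + 1, left + n_ins + flank, n_mut)
    elif variant.kind == "deletion":
        wt_indel = _clip(left, right, n_wt)
        wt_left = _clip(left - flank, left - 1, n_wt)
        wt_right = _clip(right + 1, right + flank, n_wt)
        # MUT indel region is empty; flanks meet at the deletion point
        mut_indel = None
        mut_left = _clip(left - flank, left - 1, n_mut)
        mut_right = _clip(left, left + flank - 1, n_mut)
    else:  # delins
        wt_indel = _clip(left, right, n_wt)
        wt_left = _clip(left - flank, left - 1, n_wt)
        wt_right = _clip(right + 1, right + flank, n_wt)
        n_alt = len(variant.alt_residues)
        mut_indel = _clip(left, left + n_alt - 1, n_mut)
        mut_left = _clip(left - flank, left - 1, n_mut)
        mut_right = _clip(left + n_alt, left + n_alt + flank - 1, n_mut)

    return IndelDecomposition(
        wt_left_flank=wt_left,
        wt_indel_region=wt_indel,
        wt_right_flank=wt_right,
        mut_left_flank=mut_left,
        mut_indel_region=mut_indel,
        mut_right_flank=mut_right,
        flank_length=flank,
    )


def span_positions(span: Span) -> list[int]:
    if span is None:
        return []
    return list(range(span[0], span[1] + 1))
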