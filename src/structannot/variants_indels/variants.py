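"""Variant notation parsing and mutant-sequence construction.

Grammar (1-based positions):

* SAV:        ``D833A``
* deletion:   ``del10`` or ``del10-13``
* insertion:  ``ins7GS``          (insert after position 7)
* delins:     ``delins10-12GSW``  (replace the segment by the new residues)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import ceil

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWYXU"

_SAV_RE = re.compile(rf"^([{AA_LETTERS}])(\d+)([{AA_LETTERS}])$")
_DEL_RE = re.compile(r"^del(\d+)(?:-(\d+))?$")
_INS_RE = re.compile(rf"^ins(\d+)([{AA_LETTERS}]+)$")
_DELINS_RE = re.compile(rf"^delins(\d+)(?:-(\d+))?([{AA_LETTERS}]+)$")


class VariantParseError(ValueError):
    pass


class VariantValidationError(ValueError):
    pass


@dataclass
class Variant:
    kind: str                 # sav | deletion | insertion | delins
    left: int                 # 1-based inclusive anchor
    right: int
    wt_residues: str = ""
    alt_residues: str = ""
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("sav", "deletion", "insertion", "delins"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "sav" and (len(self.wt_residues) != 1 or len(self.alt_residues) != 1):
            raise ValueError("sav requires single wt and alt residues")
        if self.kind == "deletion" and self.alt_residues:
            raise ValueError("deletion carries no alt residues")
        if self.kind == "insertion":
            if self.wt_residues:
                raise ValueError("insertion carries no wt residues")
            if self.right != self.left + 1:
                raise ValueError("insertion anchors must be adjacent")
        if self.kind != "insertion" and self.right < self.left:
            raise ValueError("right anchor before left anchor")

    @property
    def is_indel(self) -> bool:
        return self.kind in ("deletion", "insertion", "delins")

    @property
    def indel_length(self) -> int:
        return max(len(self.wt_residues), len(self.alt_residues))

    @property
    def flank_length(self) -> int:
        return max(1, ceil(self.indel_length / 2))

    def text(self) -> str:
        if self.kind == "sav":
            return f"{self.wt_residues}{self.left}{self.alt_residues}"
        if self.kind == "deletion":
            return f"del{self.left}" if self.left == self.right else f"del{self.left}-{self.right}"
        if self.kind == "insertion":
            return f"ins{self.left}{self.alt_residues}"
        span = f"{self.left}" if self.left == self.right else f"{self.left}-{self.right}"
        return f"delins{span}{self.alt_residues}"


def parse_variant(text: str, tags: list[str] | None = None) -> Variant:
    """Parse one variant string; raises :class:`VariantParseError` otherwise."""
    text = text.strip()
    if not text:
        raise VariantParseError("empty variant string")
    tags = list(tags or [])
    m = _SAV_RE.match(text)
    if m:
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return Variant("sav", pos, pos, wt, alt, tags)
    m = _DEL_RE.match(text)
    if m:
        left = int(m.group(1))
        right = int(m.group(2)) if m.group(2) else left
        return Variant("deletion", left, right, "?" * (right - left + 1), "", tags)
    m = _INS_RE.match(text)
    if m:
        pos, seq = int(m.group(1)), m.group(2)
        return Variant("insertion", pos, pos + 1, "", seq, tags)
    m = _DELINS_RE.match(text)
    if m:
        left = int(m.group(1))
        right = int(m.group(2)) if m.group(2) else left
        return Variant("delins", left, right, "?" * (right - left + 1), m.group(3), tags)
    raise VariantParseError(f"cannot parse variant string {text!r}")


def validate_variant(variant: Variant, sequence: str) -> Variant:
    """Check anchors against the sequence and fill in wild-type residues."""
    n = len(sequence)
    left, right = variant.left, variant.right
    if variant.kind == "insertion":
        if not 1 <= left <= n:
            raise VariantValidationError(
                f"insertion anchor {left} outside protein of length {n}")
        return variant
    if not (1 <= left <= n and 1 <= right <= n):
        raise VariantValidationError(
            f"variant span {left}-{right} outside protein of length {n}")
    actual = sequence[left - 1 : right]
    if variant.kind == "sav":
        if variant.wt_residues != actual:
            raise VariantValidationError(
                f"wild-type mismatch at position {left}: variant says "
                f"{variant.wt_residues!r}, sequence has {actual!r}")
    else:
        if "?" in variant.wt_residues:
            variant.wt_residues = actual
        elif variant.wt_residues != actual:
            raise VariantValidationError(
                f"wild-type mismatch at span {left}-{right}")
    return variant


def apply_variant(sequence: str, variant: Variant) -> str:
    """Build the mutant sequence; flanking sequence is untouched."""
    variant = validate_variant(variant, sequence)
    left, right = variant.left, variant.right
    if variant.kind == "sav":
        return sequence[: left - 1] + variant.alt_residues + sequence[left:]
    if variant.kind == "deletion":
        return sequence[: left - 1] + sequence[right:]
    if variant.kind == "insertion":
        return sequence[:left] + variant.alt_residues + sequence[left:]
    # delins
    return sequence[: left - 1] + variant.alt_residues + sequence[right:]
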