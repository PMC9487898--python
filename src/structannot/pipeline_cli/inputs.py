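"""Job assembly from mutation-list and FASTA inputs, plus chunking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ..variants_indels import Variant, parse_variant


class InputFormatError(ValueError):
    pass


@dataclass
class ProteinInput:
    protein_id: str
    sequence: str | None = None  # None: to be resolved from the template library
    variants: list[Variant] = field(default_factory=list)
    annotate_all: bool = False   # no variant given: annotate every position

    def merge(self, other: "ProteinInput") -> None:
        if other.sequence is not None:
            if self.sequence is not None and self.sequence != other.sequence:
                raise InputFormatError(
                    f"conflicting sequences for protein {self.protein_id!r}")
            self.sequence = other.sequence
        self.variants.extend(other.variants)
        self.annotate_all = self.annotate_all or other.annotate_all


@dataclass
class Job:
    proteins: dict[str, ProteinInput] = field(default_factory=dict)

    def add(self, entry: ProteinInput) -> None:
        existing = self.proteins.get(entry.protein_id)
        if existing is None:
            self.proteins[entry.protein_id] = entry
        else:
            existing.merge(entry)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins)


def parse_mutation_list(path: str | Path, job: Job | None = None) -> Job:
    """Tab-separated lines: protein id, optional variant, optional comma-tags.

    A blank variant column requests whole-protein annotation.
    """
    job = job or Job()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) > 3:
            raise InputFormatError(f"{path}:{lineno}: more than 3 tab-separated fields")
        protein_id = parts[0].strip()
        if not protein_id:
            raise InputFormatError(f"{path}:{lineno}: empty protein id")
        variant_text = parts[1].strip() if len(parts) > 1 else ""
        tags = [t.strip() for t in parts[2].split(",") if t.strip()] if len(parts) > 2 else []
        entry = ProteinInput(protein_id)
        if variant_text:
            try:
                entry.variants.append(parse_variant(variant_text, tags))
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
        else:
            entry.annotate_all = True
        job.add(entry)
    return job


def parse_fasta_input(path: str | Path, job: Job | None = None) -> Job:
    """FASTA input; the first header token is the protein id, any further
    tokens are variant strings in the mutation-list grammar."""
    job = job or Job()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        tokens = header.split()
        protein_id = tokens[0]
        sequence = "".join(chunks).upper()
        if not sequence:
            raise InputFormatError(f"{path}: empty sequence for {protein_id!r}")
        prior = job.proteins.get(protein_id)
        if prior is not None and prior.sequence not in (None, sequence):
            raise InputFormatError(
                f"{path}: duplicate id {protein_id!r} with a different sequence")
        entry = ProteinInput(protein_id, sequence)
        variants = []
        for token in tokens[1:]:
            try:
                variants.append(parse_variant(token))
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}: bad variant token {token!r} in header of {protein_id!r}: {exc}"
                ) from exc
        entry.variants = variants
        if not variants:
            entry.annotate_all = True
        job.add(entry)

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            chunks = []
        elif line:
            if header is None:
                raise InputFormatError(f"{path}: sequence data before first header")
            chunks.append(line)
    _flush()
    return job


def chunk_input(job: Job, chunk_size: int = 100) -> list[list[str]]:
    """Ordered protein-id chunks of at most ``chunk_size`` proteins."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    ids = job.protein_ids
    return [ids[i : i + chunk_size] for i in range(0, len(ids), chunk_size)]
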