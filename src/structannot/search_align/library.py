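"""Template library: a directory of PDB files plus a sequence index sidecar."""

from __future__ import annotations

from pathlib import Path

from ..structures_io import StructureModel, extract_atom_sequence, parse_structure

INDEX_NAME = "library_index.tsv"


class TemplateLibrary:
    """Lazy access to template structures and their ATOM-derived sequences.

    The index sidecar (``library_index.tsv``: entry_id, chain_id, sequence)
    is read when present and rebuilt from the PDB files otherwise.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise IOError(f"template library directory not found: {self.directory}")
        self._paths: dict[str, Path] = {}
        for path in sorted(self.directory.glob("*.pdb")):
            self._paths[path.stem] = path
        self._sequences: dict[tuple[str, str], str] | None = None
        self._models: dict[str, StructureModel] = {}

    # -- sequences ---------------------------------------------------------

    @property
    def chain_sequences(self) -> dict[tuple[str, str], str]:
        if self._sequences is None:
            index_path = self.directory / INDEX_NAME
            if index_path.exists():
                self._sequences = self._read_index(index_path)
            else:
                self._sequences = self._build_index()
                self.write_index(index_path)
        return self._sequences

    def _read_index(self, path: Path) -> dict[tuple[str, str], str]:
        sequences: dict[tuple[str, str], str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            entry_id, chain_id, seq = parts
            sequences[(entry_id, chain_id)] = seq
        return sequences

    def _build_index(self) -> dict[tuple[str, str], str]:
        sequences: dict[tuple[str, str], str] = {}
        for entry_id in sorted(self._paths):
            model = self.model(entry_id)
            for chain in model.protein_chains:
                seq, _ = extract_atom_sequence(model, chain.chain_id)
                if seq:
                    sequences[(entry_id, chain.chain_id)] = seq
        return sequences

    def write_index(self, path: Path | None = None) -> Path:
        path = path or self.directory / INDEX_NAME
        lines = [f"{e}\t{c}\t{s}" for (e, c), s in sorted(self.chain_sequences.items())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path

    # -- structures --------------------------------------------------------

    @property
    def entry_ids(self) -> list[str]:
        return sorted(self._paths)

    def model(self, entry_id: str) -> StructureModel:
        if entry_id not in self._models:
            if entry_id not in self._paths:
                raise KeyError(f"no entry {entry_id!r} in template library")
            self._models[entry_id] = parse_structure(self._paths[entry_id], entry_id)
        return self._models[entry_id]

    def path(self, entry_id: str) -> Path:
        return self._paths[entry_id]

    def __len__(self) -> int:
        return len(self._paths)
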