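"""On-disk cache of per-structure analyses (never-compute-anything-twice).

One tab-separated file per entry, keyed by entry id and a hash of the
analysis parameters.  Layout: residue key columns, metadata columns, then
the 100 named feature columns ('-' marks undefined).
"""

from __future__ import annotations

from pathlib import Path

from ..config import AnalysisConfig
from ..registry import FEATURE_NAMES
from ..residue_analysis.features import ResidueFeatures, StructureAnalysis

_KEY_COLUMNS = ("chain_id", "resnum", "icode", "secondary_structure",
                "ligand_partners", "protein_partner_chains")


def _fmt(value: float | None) -> str:
    if value is None:
        return "-"
    return format(value, ".10g")


class AnalysisCache:
    """File-backed store for :class:`StructureAnalysis` results."""

    def __init__(self, directory: str | Path, config: AnalysisConfig):
        self.directory = Path(directory)
        self.param_hash = config.param_hash()
        self.hits = 0
        self.misses = 0
        try:
            self.directory.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(
                f"cache directory {self.directory} is not writable: {exc}; "
                "consider running in lite mode"
            ) from exc

    def _path(self, entry_id: str) -> Path:
        return self.directory / f"{entry_id}.{self.param_hash}.tsv"

    def load(self, entry_id: str) -> StructureAnalysis | None:
        path = self._path(entry_id)
        if not path.exists():
            self.misses += 1
            return None
        analysis = StructureAnalysis(entry_id)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        expected = list(_KEY_COLUMNS) + list(FEATURE_NAMES)
        if header != expected:
            self.misses += 1
            return None
        for line in lines[1:]:
            fields = line.split("\t")
            chain_id, resnum, icode, ss, ligands, chains = fields[:6]
            values = {
                name: (None if raw == "-" else float(raw))
                for name, raw in zip(FEATURE_NAMES, fields[6:])
            }
            rf = ResidueFeatures(
                entry_id=entry_id,
                chain_id=chain_id,
                resnum=int(resnum),
                icode="" if icode == "-" else icode,
                values=values,
                ligand_partners=tuple(ligands.split(";")) if ligands != "-" else (),
                protein_partner_chains=tuple(chains.split(";")) if chains != "-" else (),
                secondary_structure=ss,
            )
            analysis.residues[rf.res_key] = rf
        self.hits += 1
        return analysis

    def store(self, analysis: StructureAnalysis) -> Path:
        path = self._path(analysis.entry_id)
        lines = ["\t".join(list(_KEY_COLUMNS) + list(FEATURE_NAMES))]
        for key in sorted(analysis.residues):
            rf = analysis.residues[key]
            fields = [
                rf.chain_id,
                str(rf.resnum),
                rf.icode or "-",
                rf.secondary_structure,
                ";".join(rf.ligand_partners) or "-",
                ";".join(rf.protein_partner_chains) or "-",
            ]
            fields += [_fmt(rf.values[name]) for name in FEATURE_NAMES]
            lines.append("\t".join(fields))
        path.write_text("\n".join(lines) + "\n")
        return path
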