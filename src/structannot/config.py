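"""Run-wide configuration with the analysis defaults used throughout the package."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Tunable parameters of the structural analysis and classification.

    The defaults are the values used by the reference workflow; everything is
    overridable through the YAML config file accepted by the CLI.
    """

    # alignment / annotation acceptance
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_threshold: float = 0.35
    identity_inclusive: bool = True
    kmer_size: int = 5

    # solvent accessibility
    probe_radius: float = 1.4
    sasa_points: int = 960

    # contacts / interaction network
    contact_cutoff: float = 5.0
    short_range_max_separation: int = 6
    neighborhood_radius: float = 10.0

    # classification
    rsa_threshold: float = 0.16
    degree_eps: float = 0.1

    # pipeline
    chunk_size: int = 100
    workers: int = 1
    lite: bool = False
    seed: int = 0

    def param_hash(self) -> str:
        """Hash of the parameters that influence per-structure analysis results.

        Used as part of the cache key so cached analyses are never reused
        across incompatible parameter sets.
        """
        relevant = {
            k: v
            for k, v in asdict(self).items()
            if k
            in (
                "probe_radius",
                "sasa_points",
                "contact_cutoff",
                "short_range_max_separation",
                "neighborhood_radius",
            )
        }
        blob = json.dumps(relevant, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = AnalysisConfig()
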