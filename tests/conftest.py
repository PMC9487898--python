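from __future__ import annotations

from pathlib import Path

import pytest

from structannot.config import AnalysisConfig
from structannot.structures_io import (
    make_dimer,
    make_helix,
    make_ligand_complex,
    make_nucleic_complex,
    write_pdb,
)


@pytest.fixture(scope="session")
def helix_fixture():
    return make_helix(20, seed=1, entry_id="FIXH")


@pytest.fixture(scope="session")
def dimer_fixture():
    return make_dimer(15, seed=2, entry_id="FIXD")


@pytest.fixture(scope="session")
def ligand_fixture():
    return make_ligand_complex(20, seed=3, entry_id="FIXL")


@pytest.fixture(scope="session")
def nucleic_fixture():
    return make_nucleic_complex(20, seed=4, entry_id="FIXN")


@pytest.fixture(scope="session")
def template_dir(tmp_path_factory, helix_fixture, dimer_fixture, ligand_fixture,
                 nucleic_fixture) -> Path:
    """A template library holding all four fixture structures."""
    directory = tmp_path_factory.mktemp("templates")
    for fixture in (helix_fixture, dimer_fixture, ligand_fixture, nucleic_fixture):
        write_pdb(fixture.model, directory / f"{fixture.model.entry_id}.pdb")
    return directory


@pytest.fixture()
def config() -> AnalysisConfig:
    return AnalysisConfig()
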