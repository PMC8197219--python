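"""Shared fixtures: small synthetic complexes and prepared structures."""

from __future__ import annotations

import numpy as np
import pytest

from voxbind import SynthSpec, generate_complex
from voxbind.config import PipelineConfig
from voxbind.pipeline import featurize_complex, prepare_structure
from voxbind.synth import write_pdb


@pytest.fixture(scope="session")
def contact_spec() -> SynthSpec:
    return SynthSpec(seed=1, n_residues=8, dna_length=4, contact_distance=4.0)


@pytest.fixture(scope="session")
def contact_complex(contact_spec):
    """A toy complex whose protein touches DNA at ~4 Å."""
    return generate_complex(contact_spec)


@pytest.fixture(scope="session")
def contact_pdb(tmp_path_factory, contact_complex):
    path = tmp_path_factory.mktemp("pdb") / f"{contact_complex.id}.pdb"
    return write_pdb(contact_complex, path)


@pytest.fixture(scope="session")
def prepared(contact_pdb):
    """Parsed, screened, SASA-flagged and typed version of the toy complex."""
    return prepare_structure(contact_pdb)


@pytest.fixture(scope="session")
def featurized(prepared):
    return featurize_complex(prepared)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig(seed=0)


def random_structure(seed: int, n_protein: int = 30, n_dna: int = 20, box: float = 12.0):
    """Random point cloud labelled as protein/DNA for mask-rule tests."""
    from voxbind.structure import Atom, MoleculeClass, Structure

    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_protein):
        atoms.append(
            Atom(serial=i + 1, name="CA", residue_name="ALA", chain_id="A",
                 residue_seq=i + 1, coords=rng.uniform(0, box, 3), element="C",
                 molecule_class=MoleculeClass.PROTEIN)
        )
    for j in range(n_dna):
        atoms.append(
            Atom(serial=n_protein + j + 1, name="P", residue_name="DA", chain_id="B",
                 residue_seq=j + 1, coords=rng.uniform(0, box, 3), element="P",
                 molecule_class=MoleculeClass.DNA)
        )
    return Structure(id=f"rnd{seed}", atoms=atoms)
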