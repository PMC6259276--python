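import numpy as np
import pytest
from rdkit import Chem

from trpa1_qsar import compounds as cmpd
from trpa1_qsar import prep
from trpa1_qsar.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def library():
    return cmpd.load_compound_table()


@pytest.fixture(scope="session")
def activity_table():
    return cmpd.load_activity_table()


@pytest.fixture(scope="session")
def reference():
    return cmpd.load_reference_stats()


@pytest.fixture(scope="session")
def compound10(library):
    rec = next(r for r in library if r.compound_id == 10)
    mol = cmpd.build_structure(rec)
    return prep.conformer_from_mol(prep.embed_and_minimize(mol, seed=7), 10)


@pytest.fixture(scope="session")
def benzene_conformer():
    mol = Chem.MolFromSmiles("c1ccccc1")
    mol.SetIntProp("compound_id", 0)
    return prep.conformer_from_mol(prep.embed_and_minimize(mol, seed=3), 0)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(out_dir=out, seed=11)), out


def toy_conformer(coords, charges=None, radii=None, epsilons=None, weights=None,
                  elements=None, compound_id=0):
    """Minimal Conformer built from raw arrays (no RDKit molecule)."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    if elements is None:
        elements = tuple(["C"] * n)
    if charges is None:
        charges = np.zeros(n)
    if radii is None:
        radii = np.full(n, 1.70)
    if epsilons is None:
        epsilons = np.full(n, 0.107)
    base = {k: np.ones(n) for k in prep.CHANNEL_WEIGHT_KEYS}
    if weights:
        base.update({k: np.asarray(v, float) for k, v in weights.items()})
    return prep.Conformer(
        compound_id=compound_id,
        elements=tuple(elements),
        coords=coords,
        charges=np.asarray(charges, float),
        radii=np.asarray(radii, float),
        epsilons=np.asarray(epsilons, float),
        weights=base,
        mol=None,
    )
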