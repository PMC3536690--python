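import numpy as np
import pytest

from comfa3d import compound_library as cl
from comfa3d import conformer_alignment as ca
from comfa3d.conformer_alignment import Molecule3D
from comfa3d.params import vdw_for
from comfa3d.pipeline import PipelineConfig, run_pipeline
from comfa3d.synthetic_data import SyntheticSeriesSpec, simulate_congeneric_series


@pytest.fixture(scope="session")
def records():
    return cl.load_activity_table()


@pytest.fixture(scope="session")
def record_by_id(records):
    return {r.id: r for r in records}


@pytest.fixture(scope="session")
def d5(record_by_id):
    mol = ca.embed_3d(record_by_id["D5"].smiles, seed=7, compound_id="D5")
    return ca.assign_gasteiger_charges(mol)


@pytest.fixture(scope="session")
def embedded_series(records):
    return [
        ca.assign_gasteiger_charges(ca.embed_3d(r.smiles, seed=7, compound_id=r.id))
        for r in records
    ]


@pytest.fixture(scope="session")
def pipeline_result():
    return run_pipeline(PipelineConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_series_result():
    spec = SyntheticSeriesSpec(seed=3, noise_sd=0.0)
    mols, acts = simulate_congeneric_series(spec)
    result = run_pipeline(
        PipelineConfig(seed=3, n_components=2, min_sigma=1.0),
        molecules=mols,
        activities=acts,
    )
    return result


def make_point_molecule(positions, charges=None, elements=None, compound_id="toy"):
    """Bare Molecule3D from explicit coordinates (no RDKit mol attached)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    elements = elements or ["C"] * n
    params = np.array([vdw_for(e) for e in elements])
    return Molecule3D(
        compound_id=compound_id,
        elements=list(elements),
        coords=positions,
        bonds=[],
        embed_seed=0,
        charges=None if charges is None else np.asarray(charges, dtype=float),
        vdw_radius=params[:, 0],
        well_depth=params[:, 1],
        rdkit_mol=None,
    )


@pytest.fixture
def point_molecule_factory():
    return make_point_molecule
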