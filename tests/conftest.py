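import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbneq import PBPrototypeTable, ped_like_spec, simulate_ensemble

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    return PBPrototypeTable.default()


@pytest.fixture(scope="session")
def sim_ensemble():
    """One full-size simulated ensemble shared across tests.

    Study-condition sizes: 60 residues, 200 models, 5 deg angular noise.
    """
    spec = ped_like_spec(length=60, n_models=200, seed=11, sigma=5.0)
    return simulate_ensemble(spec)


@pytest.fixture(scope="session")
def recomputed(sim_ensemble, table):
    """The simulated ensemble pushed back through the analysis pipeline."""
    from pbneq import EnsemblePBMatrix, compute_dihedrals, neq_profile, read_ensemble

    models = read_ensemble(sim_ensemble.pdb_text)
    dih = compute_dihedrals(models)
    matrix = EnsemblePBMatrix.from_dihedrals(dih, table)
    return {
        "models": models,
        "dihedrals": dih,
        "matrix": matrix,
        "profile": neq_profile(matrix, table=table),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
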