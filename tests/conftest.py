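import numpy as np
import pytest

import gpconf as g


def random_conformation(n_atoms: int, seed: int, conf_id: str = "c") -> g.Conformation:
    """Random well-separated geometry with random light-element charges."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-4, 4, size=(n_atoms, 3))
    # push apart any close pair so the min-separation invariant holds
    for _ in range(50):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > 0.3:
            break
        coords[i] += rng.normal(0, 1, 3)
    zs = rng.integers(1, 9, size=n_atoms)
    return g.Conformation(conf_id, zs, coords)


@pytest.fixture(scope="session")
def toy_spec():
    return g.ToyMoleculeSpec()


@pytest.fixture(scope="session")
def energy_params(toy_spec):
    return g.default_energy_params(toy_spec)


@pytest.fixture(scope="session")
def small_study(toy_spec, energy_params):
    """Two biased runs of 40 conformers each — cheap stand-in for unit tests."""
    study = g.StudyConfig(n_runs=2, frames_per_run=40, seed=3)
    return g.generate_study(toy_spec, energy_params, study)


@pytest.fixture(scope="session")
def full_study(toy_spec, energy_params):
    """The default study conditions: four biased runs of 240 conformers."""
    return g.generate_study(toy_spec, energy_params, g.StudyConfig(seed=0))


@pytest.fixture(scope="session")
def full_study_arrays(full_study):
    X = np.vstack([g.featurize_ensemble(r) for r in full_study])
    y = np.concatenate([r.energies() for r in full_study])
    run_id = np.concatenate([np.full(len(r), i) for i, r in enumerate(full_study)])
    return X, y, run_id


@pytest.fixture(scope="session")
def real_cv_result(full_study_arrays):
    """Nested 10x10 stratified CV of the pooled study (shared across tests)."""
    X, y, _ = full_study_arrays
    return g.nested_cv(X, y, k=10, reps=10, seed=0)
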