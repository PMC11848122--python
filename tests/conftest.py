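import numpy as np
import pandas as pd
import pytest

import traitstab as ts


@pytest.fixture(scope="session")
def tiny_pool():
    return ts.generate_species_pool(8, 0.5, seed=7)


@pytest.fixture(scope="session")
def tiny_cfg(tiny_pool):
    return ts.SynthConfig(
        n_ponds=3, n_years=4, n_months=3, n_stations=2,
        species_pool=tuple(tiny_pool), redundancy=0.5,
        spatial_filter_strength=0.5, temporal_cv=0.5, compensation=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_survey(tiny_cfg):
    return ts.simulate_survey(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_measurements(tiny_cfg):
    return ts.simulate_trait_measurements(tiny_cfg, n_per_species=12, noise_sd=0.02)


@pytest.fixture(scope="session")
def tiny_models(tiny_measurements):
    return ts.fit_all_trait_models(tiny_measurements, basis_dim=6)


@pytest.fixture(scope="session")
def tiny_predictions(tiny_models, tiny_survey, tiny_measurements):
    return ts.impute_survey_traits(
        tiny_models, tiny_survey, ts.species_to_family_map(tiny_measurements)
    )


@pytest.fixture(scope="session")
def tiny_matrices(tiny_survey, tiny_predictions):
    A = ts.build_abundance_matrix(tiny_survey)
    T = ts.build_trait_matrix(tiny_predictions)
    return A, T


def euclidean_dm(points, labels=None):
    """Distance matrix of a Euclidean point cloud (test helper)."""
    X = np.asarray(points, dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    if labels is None:
        labels = list(range(len(X)))
    return ts.DistanceMatrix(labels, d)


@pytest.fixture
def euclid_dm_factory():
    return euclidean_dm


def pond_year_matrix(values, ponds, years, columns=None):
    """Composition matrix with a (pond, year) MultiIndex (test helper)."""
    values = np.asarray(values, dtype=float)
    if columns is None:
        columns = [f"c{i}" for i in range(values.shape[1])]
    idx = pd.MultiIndex.from_tuples(list(zip(ponds, years)), names=["pond", "year"])
    return pd.DataFrame(values, index=idx, columns=columns)


@pytest.fixture
def pond_year_matrix_factory():
    return pond_year_matrix
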