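"""Shared synthetic fixtures: a small landscape with known generative truth."""

import numpy as np
import pytest

from treedensity import synthetic as syn
from treedensity.grids import GridSpec
from treedensity.ingest import extract_covariates


@pytest.fixture(scope="session")
def grid():
    return GridSpec(60, 60, 897.27)


@pytest.fixture(scope="session")
def stack(grid):
    return syn.make_covariate_stack(grid, n_blocks=3, vars_per_block=3,
                                    rho_within=0.8, rho_between=0.05, seed=11)


@pytest.fixture(scope="session")
def regions(grid):
    return syn.make_region_map(grid, n_biomes=3, ecoregions_per_biome=2, seed=12)


@pytest.fixture(scope="session")
def forest(stack):
    return syn.make_forest_cover(stack, 0.63, 0.35, seed=13)


@pytest.fixture(scope="session")
def true_models(regions, stack):
    return syn.default_true_models(regions.biome_ids, stack.names, seed=14)


@pytest.fixture(scope="session")
def plots(stack, regions, true_models, forest):
    table = syn.simulate_plots(stack, regions, true_models, n_per_region=300,
                               forest_cover=forest, seed=15)
    bound, flagged = extract_covariates(table, stack)
    assert len(flagged) == 0
    return bound


@pytest.fixture(scope="session")
def fitted_models(plots, stack):
    from treedensity.models import fit_region_models

    return fit_region_models(plots, stack.names, level="biome", min_n=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
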