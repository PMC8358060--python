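"""Shared synthetic worlds for the test suite.

Everything is generated in-process under fixed seeds; session scope keeps
the heavier worlds to a single construction.
"""

import warnings

import numpy as np
import pytest

import flnrmap as fm


@pytest.fixture(scope="session")
def small_grid():
    """20x40 half-degree window with independent covariate fields."""
    return fm.make_covariate_grid((20, 40), seed=101, smoothness=3.0)


@pytest.fixture(scope="session")
def small_traits(small_grid):
    return fm.make_traits(small_grid, seed=102)


@pytest.fixture(scope="session")
def noiseless_truth(small_grid, small_traits):
    """Noiseless truth from the global empirical equation slopes; the
    intercept is raised so no cell hits the positivity floor (slopes are
    unaffected by the shift)."""
    return fm.make_truth(
        small_grid, small_traits, intercept=55.0, noise_sd=0.0, seed=103
    )


@pytest.fixture(scope="session")
def wide_world():
    """40x80 world with clustered + isolated sites, used by the upscaling
    and attribution tests that need spatial extent."""
    grid = fm.make_covariate_grid((40, 80), seed=201, smoothness=3.0)
    traits = fm.make_traits(grid, seed=202)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = fm.make_truth(grid, traits, intercept=30.0, noise_sd=2.0, seed=203)
    obs = fm.sample_observations(
        truth, grid, n=300, n_clusters=15, cluster_radius=1.5,
        obs_noise_sd=3.0, isolated_fraction=0.3, seed=204,
    )
    obs["vcmax25"] = fm.standardize_to_25(
        obs["vcmax_obs"].to_numpy(), obs["tleaf"].to_numpy()
    )
    return {"grid": grid, "traits": traits, "truth": truth, "obs": obs}


@pytest.fixture(scope="session")
def noiseless_attribution(small_grid, noiseless_truth):
    """Full-rank PCA + GAM fit of the noiseless linear world."""
    table = small_grid.table()
    pca = fm.group_pca(table)
    gam = fm.FLNRAttribution(
        noiseless_truth.flnr_true[small_grid.mask],
        pca,
        table["pft"].to_numpy(),
        n_pcs=8,
    ).fit()
    return {"table": table, "pca": pca, "results": gam}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
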