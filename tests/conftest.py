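"""Shared fixtures: one default synthetic study, generated once per session."""

import numpy as np
import pytest

import prismspot as ps


@pytest.fixture(scope="session")
def sim_config():
    return ps.SimConfig()


@pytest.fixture(scope="session")
def reference(sim_config):
    return ps.make_reference(sim_config)


@pytest.fixture(scope="session")
def spatial(sim_config):
    """(SpatialDataset, GroundTruth) under the default study conditions."""
    return ps.make_spatial_dataset(sim_config)


@pytest.fixture(scope="session")
def markers(reference):
    return ps.select_markers(reference)


@pytest.fixture(scope="session")
def profile(reference, markers):
    return ps.build_reference(reference, markers.union, pseudo_min=0.0)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down tissue for tests that refit the sampler repeatedly."""
    return ps.SimConfig(grid_shape=(8, 8), depth_mean=800, seed=3)


@pytest.fixture(scope="session")
def small_spatial(small_config):
    return ps.make_spatial_dataset(small_config)


@pytest.fixture(scope="session")
def prism_fit(spatial, reference):
    """Full deconvolution-aware pipeline fit on the default dataset."""
    ds, _ = spatial
    return ps.PrismSpotModel(ds, reference).fit(seed=101)


@pytest.fixture(scope="session")
def raw_fit(spatial, reference):
    """Same spatial analysis on raw (un-deconvolved) counts."""
    ds, _ = spatial
    return ps.PrismSpotModel(ds, reference, use_deconvolution=False).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
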