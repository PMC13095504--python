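"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from isodrift.isoscape import Isoscape, IsoscapeConfig, fit_isoscape, predict_isoscape
from isodrift.raster import Raster
from isodrift.synth import LandscapeConfig, make_landscape, sample_foliar


@pytest.fixture(scope="session")
def noiseless_landscape():
    """60×60 @ 8 km landscape with zero micro-noise: the truth is an exact
    function of the covariates."""
    cfg = LandscapeConfig(grid_shape=(60, 60), cell_size=8.0,
                          noise_sd_foliar=0.0, seed=11)
    return make_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    cfg = LandscapeConfig(seed=7)
    return make_landscape(cfg)


@pytest.fixture(scope="session")
def truth_isoscape(noiseless_landscape):
    """Isoscape whose mean *is* the true foliar field (σ = 1‰)."""
    _, true = noiseless_landscape
    ones = true.like(np.where(true.mask, 1.0, np.nan))
    mask = true.like(true.mask.astype(float))
    return Isoscape(mean=true, sigma=ones, valid_mask=mask)


@pytest.fixture(scope="session")
def fitted_model(noiseless_landscape):
    """Quantile forest fit on 120 noiseless sites of the 60×60 landscape."""
    covs, true = noiseless_landscape
    samples = sample_foliar(true, covs, 120, seed=21, noise_sd=0.0)
    cfg = IsoscapeConfig(n_trees=200, tune=False, cv_reps=0, seed=21)
    return fit_isoscape(samples, covs, cfg), samples


@pytest.fixture(scope="session")
def fitted_isoscape(fitted_model, noiseless_landscape):
    covs, _ = noiseless_landscape
    model, _ = fitted_model
    return predict_isoscape(model, covs)


def tiny_raster(values, lat0=47.0, lon0=-64.0, dlat=0.05, dlon=0.07, **kw):
    return Raster(np.asarray(values, dtype=float), lat0=lat0, lon0=lon0,
                  dlat=dlat, dlon=dlon, **kw)
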