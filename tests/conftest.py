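"""Shared fixtures: small synthetic datasets and oracle meshes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spaterich as sr


def triangular_lattice_strip(x0, x1, y0, y1, h):
    """Equilateral-lattice points filling a rectangle (FEM oracle meshes)."""
    pts = []
    ny = int(np.ceil((y1 - y0) / (h * np.sqrt(3) / 2)))
    for iy in range(ny + 1):
        y = y0 + iy * h * np.sqrt(3) / 2
        off = (iy % 2) * h / 2
        nx = int(np.ceil((x1 - x0) / h))
        for ix in range(nx + 1):
            x = x0 + ix * h + off
            if x <= x1 + 1e-12:
                pts.append([x, y])
    return np.asarray(pts)


@pytest.fixture(scope="session")
def glm_dataset():
    """400 plots, one covariate, no random effects: a plain Poisson GLM."""
    rng = np.random.default_rng(20100429)
    n = 400
    x = rng.normal(0.0, 1.0, n)
    eta = 2.0 + 0.3 * x
    return pd.DataFrame(
        {
            "easting": rng.uniform(0, 50_000, n),
            "northing": rng.uniform(0, 50_000, n),
            "richness": rng.poisson(np.exp(eta)),
            "x": x,
        }
    )


@pytest.fixture(scope="session")
def small_spatial_dataset():
    """150 plots in 30 clustered sites with identifiable variance components."""
    design = sr.SurveyDesign(
        layout="clustered", n_sites=30, plots_per_site=5,
        domain=(0.0, 0.0, 60_000.0, 60_000.0),
    )
    truth = sr.SyntheticTruth(
        covariate_names=("x1", "x2"),
        beta=(-0.05, 0.08),
        ranges=((0.0, 10.0), (0.0, 5.0)),
        divisors=(1.0, 1.0),
        correlation=np.array([[1.0, 0.4], [0.4, 1.0]]),
        mean_richness=20.0,
        theta2=0.15,
        matern_range=20_000.0,
        matern_sd=0.5,
    )
    df, echo = sr.simulate_survey(design, truth, seed=11)
    return df, echo


@pytest.fixture(scope="session")
def small_spatial_fit(small_spatial_dataset):
    df, _ = small_spatial_dataset
    spec = sr.ModelSpec(covariates=("x1", "x2"), structure="mesh_plus_square")
    return sr.fit(df, spec, mesh_options={"max_edge": 15_000.0})
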