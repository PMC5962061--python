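"""Shared fixtures: small synthetic landscapes and fitted-ready segment
tables, generated programmatically with fixed seeds."""

import numpy as np
import pandas as pd
import pytest

from stripdsm import (IntensityModel, ModelSpec, TermSpec,
                      build_segment_table, default_flight_paths,
                      simulate_landscape, simulate_population,
                      simulate_survey)


@pytest.fixture(scope="session")
def landscape():
    """384 km^2 coastal landscape, 700 m cells, elevation/coast r ~ 0.65."""
    return simulate_landscape(extent_km2=384.0, cell_size=700.0, seed=42)


@pytest.fixture(scope="session")
def elevation_model():
    return IntensityModel(intercept=np.log(0.9),
                          effects={"elevation": lambda e: -0.002 * (e - 450.0)},
                          group_size_mean=4.0)


@pytest.fixture(scope="session")
def survey_segments(landscape, elevation_model):
    """Segment table from one simulated survey (4 transects, ~56 segments)."""
    pop = simulate_population(landscape, elevation_model, seed=1)
    paths = default_flight_paths(landscape, n_transects=4)
    survey = simulate_survey(pop, paths, bandwidth=1400.0, seed=2)
    seg, _ = build_segment_table(paths, survey.detected_records, landscape,
                                 bandwidth=1400.0)
    return seg


@pytest.fixture()
def tiny_segments():
    """20 independent segments with an elevation covariate and Poisson-ish
    counts; small enough for brute-force oracles."""
    rng = np.random.default_rng(42)
    elev = rng.uniform(0.0, 1000.0, 20)
    area = np.full(20, 1.96)
    y = rng.poisson(np.exp(1.0 - 0.002 * elev) * area).astype(float)
    return pd.DataFrame({"count": y, "area": area, "elevation": elev})


@pytest.fixture()
def elevation_spec():
    return ModelSpec([TermSpec(("elevation",), k=4)], p=1.5)


def make_transect_segments(rho, seed, n_transects=12, n_segments=40,
                           sigma=1.2, intercept=3.0):
    """Segment table with AR(1) latent noise on the link scale within
    transects — the test bed for the autocorrelation machinery."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_transects):
        e = np.zeros(n_segments)
        e[0] = rng.normal()
        for i in range(1, n_segments):
            e[i] = rho * e[i - 1] + rng.normal(0.0, np.sqrt(1.0 - rho**2))
        elev = rng.uniform(0.0, 1000.0, n_segments)
        y = rng.poisson(np.exp(intercept - 0.001 * elev + sigma * e) * 1.96)
        for o in range(n_segments):
            rows.append({"transect": t, "order": o, "area": 1.96,
                         "length": 1400.0, "elevation": elev[o],
                         "count": float(y[o])})
    return pd.DataFrame(rows)
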