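import dataclasses

import numpy as np
import pandas as pd
import pytest

from forestcarbon import allometry, paired_stats, soil_carbon, synthetic_data


@pytest.fixture(scope="session")
def coefs():
    return allometry.placeholder_coefficient_table()


@pytest.fixture(scope="session")
def small_survey():
    """A small noisy survey shared across tests (seeded, generated once)."""
    cfg = synthetic_data.GeneratorConfig(n_sites=40, seed=11)
    return synthetic_data.generate_survey(cfg)


@pytest.fixture(scope="session")
def noiseless_survey():
    """Noise-free survey with the nitrogen hump disabled: pair deltas follow
    the configured species slopes exactly."""
    responses = {
        k: dataclasses.replace(v, hump_width=None)
        for k, v in synthetic_data.default_species_responses().items()
    }
    cfg = synthetic_data.noiseless(
        dataclasses.replace(
            synthetic_data.GeneratorConfig(n_sites=40, seed=13),
            species_responses=responses,
        )
    )
    return synthetic_data.generate_survey(cfg)


def survey_pair_table(survey):
    """Run the deterministic half of the pipeline: biomass, soil, pairs."""
    bio = allometry.plot_biomass_table(survey.trees, survey.plots, survey.coefficients)
    dens = soil_carbon.profile_density_table(survey.soil_samples)
    return paired_stats.build_pair_table(
        survey.plots, bio, survey.control_biomass, dens
    )


@pytest.fixture(scope="session")
def small_pairs(small_survey):
    return survey_pair_table(small_survey)


@pytest.fixture(scope="session")
def noiseless_pairs(noiseless_survey):
    return survey_pair_table(noiseless_survey)


def brute_force_bh(p_values):
    """Independent Benjamini–Hochberg oracle: sort, m*p/rank, running
    minimum from the largest, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adjusted[i] = running
    return np.minimum(adjusted, 1.0)
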