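"""Shared fixtures: one fixture universe and a mid-size simulated cohort
reused (read-only) across test modules to keep the suite fast."""

from __future__ import annotations

import warnings

import pytest

from nktime.gene_sets import make_fixture_universe
from nktime.germline import build_mutation_matrix
from nktime.simulate import CohortConfig, simulate_cohort
from nktime.subtypes import cluster_time_subtypes
from nktime.til import til_profile


@pytest.fixture(scope="session")
def universe_sets():
    sets, universe = make_fixture_universe(seed=0)
    return sets, universe


@pytest.fixture(scope="session")
def cohort(universe_sets):
    sets, universe = universe_sets
    return simulate_cohort(CohortConfig(n_samples=600, seed=7), sets, universe)


@pytest.fixture(scope="session")
def mutation_matrix(cohort, universe_sets):
    _, universe = universe_sets
    return build_mutation_matrix(
        cohort.variants, universe, list(cohort.expression.columns)
    )


@pytest.fixture(scope="session")
def assignment(cohort, universe_sets):
    sets, _ = universe_sets
    return cluster_time_subtypes(cohort.expression, sets["immune_panel"])


@pytest.fixture(scope="session")
def profile(cohort, universe_sets):
    sets, _ = universe_sets
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return til_profile(cohort.expression, sets.subset("til_"))
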