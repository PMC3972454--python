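"""Shared fixtures: the seed-42 default synthetic study and small views."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neurocohort.cohort import CohortTable, merge_tables, read_table
from neurocohort.dictionary import load_dictionary
from neurocohort.simulate import SimulationParams, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default-scale synthetic study (n=800, seed 42), generated once."""
    out = tmp_path_factory.mktemp("fixture42")
    return generate_cohort(SimulationParams(), out)


@pytest.fixture(scope="session")
def view(fixture_dir) -> CohortTable:
    """Merged imaging + super analysis view of the default fixture."""
    imaging = read_table(fixture_dir.imaging_csv)
    sup = read_table(fixture_dir.super_csv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return merge_tables(imaging, sup)


@pytest.fixture(scope="session")
def dictionary(fixture_dir):
    return load_dictionary(fixture_dir.dictionary_csv, fixture_dir.patterns_json)


@pytest.fixture()
def toy_csv(tmp_path):
    """Write a small session-by-measure CSV and return its path."""

    def _write(rows: list[dict], name: str = "toy.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
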