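"""Shared fixtures: one default synthetic experiment + its analysis, reused
across the suite (generation and the full pipeline are deterministic for the
default seed, so session scope is safe)."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kelpmetab import pipeline as pl
from kelpmetab import scenarios as sc


@pytest.fixture(scope="session")
def experiment():
    return sc.generate_experiment()


@pytest.fixture(scope="session")
def report(experiment):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.run_analyze(experiment)


@pytest.fixture(scope="session")
def hourly_timeline():
    return pd.date_range("2022-06-30", periods=23 * 24, freq="1h")


@pytest.fixture()
def rng():
    return np.random.default_rng(20220630)
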