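"""Shared fixtures: built-in search assets and a small synthetic library."""

import numpy as np
import pytest

from prospector.synthetic_data import (
    default_plan,
    generate_library,
    make_default_profiles,
    make_default_reference,
)


@pytest.fixture(scope="session")
def profiles():
    return make_default_profiles()


@pytest.fixture(scope="session")
def reference():
    return make_default_reference()


@pytest.fixture(scope="session")
def library_bundle():
    """One realized default library (seed 1) with its truth table."""
    return generate_library(default_plan(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20201019)
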