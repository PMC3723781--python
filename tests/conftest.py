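"""Shared fixtures: small synthetic targets generated at test time."""

import numpy as np
import pytest

from edafrag.energy import OracleScore
from edafrag.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """An 18-residue synthetic target: fast enough for end-to-end tests."""
    return make_fixture(FixtureSpec(length=18, frags_per_window=10, seed=7))


@pytest.fixture(scope="session")
def small_oracle(small_fixture):
    return OracleScore(native_ca=small_fixture.native_coords[:, 1, :])


@pytest.fixture(scope="session")
def bench_fixture():
    """The default study conditions (36 residues, 25 fragments/window)."""
    return make_fixture(FixtureSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
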