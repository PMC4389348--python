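import numpy as np
import pytest

from condact import build_rate_matrix, enumerate_microstates, equilibrium
from condact.fixtures import FixtureSpec, make_fixture


def build_system(kind: str, params: dict | None = None, base_rate: float = 1.0):
    """Fixture model -> (spec, cond, microstates, dist, rate_matrix)."""
    spec, cond = make_fixture(FixtureSpec(kind, params or {}))
    ms = enumerate_microstates(spec)
    dist = equilibrium(spec, ms, cond)
    rm = build_rate_matrix(spec, ms, dist, base_rate)
    return spec, cond, ms, dist, rm


@pytest.fixture(scope="session")
def single_site_31():
    """One two-configuration site with bind rate 3, unbind rate 1."""
    return build_system("single_site", {"k_bind": 3.0, "k_unbind": 1.0}, base_rate=3.0)


@pytest.fixture(scope="session")
def independent_pair():
    return build_system("independent_pair")


@pytest.fixture(scope="session")
def cooperative_pair():
    return build_system("cooperative_pair", {"dg_coop": -1.5})


@pytest.fixture(scope="session")
def chain4_excl():
    """Four-site chain with nearest-neighbor cooperativity and one steric
    exclusion between the end sites (12 microstates)."""
    return build_system(
        "chain_n", {"n": 4, "dg_coop": -1.5, "exclude_ends": True}
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
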