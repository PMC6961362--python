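import pytest

import amucost as a


@pytest.fixture(scope="session")
def dictionary():
    return a.load_builtin_dictionary()


@pytest.fixture(scope="session")
def ref_products():
    return a.load_reference_catalog()


@pytest.fixture(scope="session")
def small_cfg():
    return a.GeneratorConfig(n_farms=20, n_flocks=40, n_products=60,
                             n_price_records=160)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return a.simulate(small_cfg, 7)


@pytest.fixture(scope="session")
def small_weeks(small_cfg, small_bundle):
    return a.flock_weeks_from_frame(small_bundle["flock_weeks"], fx=small_cfg.fx)
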