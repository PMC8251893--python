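import numpy as np
import pytest

from mangrove_carbon.emissions_core import ModelConfig
from mangrove_carbon.province_data import EmissionFactor, ProvinceRecord
from mangrove_carbon.synthetic_data import SyntheticConfig, fixture_table1, generate


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def table1(default_config):
    """(records, expected printed decomposition) for the six-province fixture."""
    return fixture_table1(default_config)


@pytest.fixture(scope="session")
def synthetic37():
    return generate(SyntheticConfig(n_provinces=37, seed=11))


def make_province(
    province_id="P01",
    area=100_000.0,
    rate=0.004,
    soc_1m=331.3,
    soc_2m=646.7,
    abc=101.2,
    shares=(0.6, 0.2, 0.1, 0.05, 0.05),
    factors=(0.8, 0.6, 0.5, 0.3, 0.9),
    seq=1.5,
) -> ProvinceRecord:
    return ProvinceRecord(
        province_id=province_id,
        name=f"Test {province_id}",
        area_2010=area,
        deforestation_rate=rate,
        soc_1m=soc_1m,
        soc_2m=soc_2m,
        abc=abc,
        driver_shares=tuple(shares),
        emission_factors=tuple(EmissionFactor(f, 2) for f in factors),
        sequestration_rate=seq,
    )


@pytest.fixture
def province() -> ProvinceRecord:
    return make_province()
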