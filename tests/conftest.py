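import pytest

from tgfs import SeasonConfig, generate_synthetic_season, run_season
from tgfs.drivers import EnvForcing, compute_vpd
from tgfs.params import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def ten_day_forcing():
    return generate_synthetic_season(SeasonConfig(n_days=10, seed=42))


@pytest.fixture(scope="session")
def ten_day_result(ten_day_forcing, params):
    return run_season(ten_day_forcing, params)


@pytest.fixture
def make_env():
    """Factory for a single forcing hour; defaults are benign midday values."""

    def _make(**kw):
        base = dict(doy=180, hour=12.0, daa=30.0, Rs=2.5, Rn_prime=1.875,
                    Ta=26.0, RH=60.0, CO2=400.0, theta=0.32, N=120.0)
        base.update(kw)
        base.setdefault("VPD", compute_vpd(base["Ta"], base["RH"]))
        return EnvForcing(**base)

    return _make
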