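import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import copetherm as ct

settings.register_profile(
    "copetherm",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("copetherm")


CONTROL_TPC = ct.TPCParams(rmax=98.2, topt=26.4, tmin=6.0, tmax=32.1)
WARM_TPC = ct.TPCParams(rmax=83.5, topt=26.9, tmin=6.0, tmax=32.4)


@pytest.fixture(scope="session")
def control_tpc() -> ct.TPCParams:
    return CONTROL_TPC


@pytest.fixture(scope="session")
def warm_tpc() -> ct.TPCParams:
    return WARM_TPC


def survival_frame(params: ct.SurvivalParams, temps=ct.PAPER_GRID, n_bottles=3,
                   line=19.0, duration=24.0, n=20) -> pd.DataFrame:
    """Noiseless survival table: per-bottle alive fractions exactly on the curve."""
    rows = []
    for T in temps:
        s = ct.survival_predict(params, T)
        for k in range(n_bottles):
            rows.append(
                dict(rearing_temp=line, test_temp=float(T), duration_h=duration,
                     bottle_id=f"b{T}-{k}", n_started=n, n_alive=s * n)
            )
    return pd.DataFrame(rows)


def rate_frame(params: ct.TPCParams, temps=ct.PAPER_GRID, n_bottles=3,
               line=19.0) -> pd.DataFrame:
    """Noiseless egg-rate table: per-bottle rates exactly on the curve."""
    rows = []
    for T in temps:
        r = ct.tpc_predict(params, T)
        for k in range(n_bottles):
            rows.append(
                dict(rearing_temp=line, test_temp=float(T),
                     bottle_id=f"b{T}-{k}", rate=r)
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def noiseless_survival() -> pd.DataFrame:
    return survival_frame(ct.SurvivalParams(2.0, 32.5, 0.9))


@pytest.fixture(scope="session")
def noiseless_rates(control_tpc) -> pd.DataFrame:
    return rate_frame(control_tpc)


@pytest.fixture(scope="session")
def noiseless_tpc_fit(noiseless_rates) -> ct.TPCFit:
    return ct.fit_tpc(noiseless_rates, 19.0, boot_n=0)
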