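import numpy as np
import pandas as pd
import pytest

from peatline import (
    GenerationConfig,
    WaterTableFluxResults,
    generate_flux_table,
    reproduction_scenario,
)


@pytest.fixture(scope="session")
def printed_results() -> WaterTableFluxResults:
    """Results object built from the published regression coefficients."""
    return WaterTableFluxResults.from_coefficients()


@pytest.fixture(scope="session")
def repro():
    """The full printed-constant reproduction scenario."""
    return reproduction_scenario()


@pytest.fixture(scope="session")
def default_flux_table() -> pd.DataFrame:
    """One synthetic flux table at the study conditions (fixed seed)."""
    return generate_flux_table(GenerationConfig.default(seed=42))


def random_flux_frame(rng: np.random.Generator, n: int, peat_class: str = "bog") -> pd.DataFrame:
    """Small random plot table for oracle comparisons."""
    wt = rng.uniform(-60, 10, size=n)
    flux = 10 ** (rng.normal(0, 1) * 0.01 * wt + rng.normal(1, 0.5) + rng.normal(0, 0.3, n)) - 2
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "peat_class": peat_class,
            "water_table_cm": wt,
            "flux_mg_m2_d": flux,
        }
    )


def ols_normal_equations(wt: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Independent closed-form simple-regression oracle.

    Returns (slope, intercept, r_squared) from the textbook sums, not from
    any linear-model library.
    """
    n = len(wt)
    sx, sy = wt.sum(), y.sum()
    sxx, sxy = (wt * wt).sum(), (wt * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * wt)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return slope, intercept, r2
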