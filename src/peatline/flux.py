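"""Offset-log regression of peatland CH4 flux on water-table position.

The model, fitted separately for each peatland class (bog, fen, swamp), is

    log10(F + c) = a * WT + b + eps,   eps ~ N(0, s^2)

where F is mean daily CH4 flux (mg CH4 m-2 d-1), WT is mean summer
water-table position (cm, negative below the peat surface) and c = 2 is a
fixed offset that accommodates small negative (uptake) fluxes. Predictions
back-transform naively, F_hat = 10^(a*WT + b) - c, which bounds predicted
flux below by -c; a smearing correction is available but off by default
because the published emission factors are the naive back-transform.

Seasonal (== annual) emission factors integrate the daily flux over a fixed
emission period with dormant-season flux assumed zero:

    E = F_hat * D / 1000   [g CH4 m-2 per season],  D = 123 d by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (
    FLUX_OFFSET,
    MEAN_WATER_TABLE_CM,
    PEAT_CLASSES,
    REGRESSION_COEFFICIENTS,
    SEASON_DAYS,
)

__all__ = [
    "SeasonSpec",
    "ClassRegression",
    "WaterTableFluxModel",
    "WaterTableFluxResults",
    "fit_class_regression",
    "predict_daily_flux",
    "seasonal_flux",
    "mean_water_table",
]

#: Required columns of a plot-level flux table.
FLUX_COLUMNS = ("site_id", "peat_class", "water_table_cm", "flux_mg_m2_d")


@dataclass(frozen=True)
class SeasonSpec:
    """Emission period: daily fluxes are integrated over `days` days and
    winter flux is fixed at zero, so the seasonal total is also the annual
    total."""

    days: float = SEASON_DAYS

    def __post_init__(self) -> None:
        if not self.days > 0:
            raise ValueError(f"season length must be positive, got {self.days}")


@dataclass(frozen=True)
class ClassRegression:
    """Fitted (or published) offset-log flux model for one peatland class.

    Slope `a` is log10(mg m-2 d-1 + offset) per cm of water table; intercept
    `b` is in log10 units. Fit diagnostics (`r_squared`, `f_statistic`,
    `p_value`, `resid_se`, `cov_params`) are present when the model was fitted
    to data and None when built from published coefficients.
    `cov_params` is the 2x2 covariance of (intercept, slope).
    """

    peat_class: str
    slope: float
    intercept: float
    offset: float = FLUX_OFFSET
    r_squared: float | None = None
    f_statistic: float | None = None
    p_value: float | None = None
    resid_se: float | None = None
    nobs: int | None = None
    cov_params: np.ndarray | None = field(default=None, repr=False)

    @property
    def df_resid(self) -> int | None:
        return None if self.nobs is None else self.nobs - 2

    def predict_daily(
        self, water_table_cm: float | np.ndarray, smearing: bool = False
    ) -> float | np.ndarray:
        """Predicted daily CH4 flux, mg m-2 d-1.

        With ``smearing=True`` the lognormal retransformation bias correction
        exp((s*ln10)^2 / 2) is applied to the median prediction (requires a
        fitted residual scale). The naive default reproduces the published
        emission factors.
        """
        wt = np.asarray(water_table_cm, dtype=float)
        pred = 10.0 ** (self.slope * wt + self.intercept)
        if smearing:
            if self.resid_se is None:
                raise ValueError("smearing correction requires a fitted residual scale")
            pred = pred * np.exp(0.5 * (self.resid_se * np.log(10.0)) ** 2)
        out = pred - self.offset
        return float(out) if out.ndim == 0 else out

    def seasonal(
        self,
        water_table_cm: float | np.ndarray,
        season: SeasonSpec | None = None,
        smearing: bool = False,
    ) -> float | np.ndarray:
        """Seasonal emission factor, g CH4 m-2 per season."""
        season = season or SeasonSpec()
        return self.predict_daily(water_table_cm, smearing=smearing) * season.days / 1000.0


def _validate_flux_frame(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FLUX_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"flux table missing columns: {missing}")
    wt = pd.to_numeric(data["water_table_cm"], errors="raise")
    fx = pd.to_numeric(data["flux_mg_m2_d"], errors="raise")
    if not np.isfinite(wt).all():
        raise ValueError("non-finite water-table values in flux table")
    bad = data.loc[~data["peat_class"].isin(PEAT_CLASSES), "peat_class"].unique()
    if len(bad):
        raise ValueError(f"unknown peat_class labels: {sorted(bad)}")
    if not np.isfinite(fx).all():
        raise ValueError("non-finite flux values in flux table")
    return data


def fit_class_regression(
    observations: pd.DataFrame, peat_class: str, offset: float = FLUX_OFFSET
) -> ClassRegression:
    """OLS fit of log10(flux + offset) on water-table position for one class.

    Raises ValueError if fewer than 3 observations, any flux <= -offset
    (log undefined), or the water tables are all equal (singular design).
    """
    obs = _validate_flux_frame(observations)
    sub = obs[obs["peat_class"] == peat_class]
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 observations to fit class {peat_class!r}, got {len(sub)}"
        )
    flux = sub["flux_mg_m2_d"].to_numpy(dtype=float)
    wt = sub["water_table_cm"].to_numpy(dtype=float)
    if np.any(flux <= -offset):
        raise ValueError(
            f"flux values <= -{offset} in class {peat_class!r}: log-transform undefined"
        )
    if np.ptp(wt) == 0.0:
        raise ValueError(
            f"all water tables equal in class {peat_class!r}: singular fit"
        )
    y = np.log10(flux + offset)
    res = sm.OLS(y, sm.add_constant(wt)).fit()
    return ClassRegression(
        peat_class=peat_class,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        offset=offset,
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_value=float(res.f_pvalue),
        resid_se=float(np.sqrt(res.mse_resid)),
        nobs=int(res.nobs),
        cov_params=np.asarray(res.cov_params()),
    )


def mean_water_table(observations: pd.DataFrame, peat_class: str) -> float:
    """Arithmetic mean of plot-level water tables for one class, cm."""
    sub = observations[observations["peat_class"] == peat_class]
    if len(sub) == 0:
        raise ValueError(f"no observations for class {peat_class!r}")
    return float(sub["water_table_cm"].astype(float).mean())


def predict_daily_flux(
    model: ClassRegression, water_table_cm: float | np.ndarray, smearing: bool = False
) -> float | np.ndarray:
    """Daily CH4 flux (mg m-2 d-1) predicted by a fitted class model."""
    return model.predict_daily(water_table_cm, smearing=smearing)


def seasonal_flux(
    model: ClassRegression,
    water_table_cm: float | np.ndarray,
    season: SeasonSpec | None = None,
    smearing: bool = False,
) -> float | np.ndarray:
    """Seasonal emission factor (g CH4 m-2) predicted by a class model."""
    return model.seasonal(water_table_cm, season=season, smearing=smearing)


class WaterTableFluxModel:
    """Per-class offset-log flux~water-table model, statsmodels style.

    Built from a plot-level flux table (columns: site_id, peat_class,
    water_table_cm, flux_mg_m2_d); ``fit()`` returns a
    :class:`WaterTableFluxResults` carrying one :class:`ClassRegression` per
    peatland class present in the data, plus the per-class mean water tables.
    """

    def __init__(self, data: pd.DataFrame, offset: float = FLUX_OFFSET):
        self.data = _validate_flux_frame(data).reset_index(drop=True)
        self.offset = offset
        self.classes = [c for c in PEAT_CLASSES if (self.data["peat_class"] == c).any()]
        if not self.classes:
            raise ValueError("flux table contains no peatland observations")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, offset: float = FLUX_OFFSET) -> "WaterTableFluxModel":
        return cls(data, offset=offset)

    @classmethod
    def from_csv(cls, path, offset: float = FLUX_OFFSET) -> "WaterTableFluxModel":
        return cls(pd.read_csv(path), offset=offset)

    def fit(self) -> "WaterTableFluxResults":
        regs = {
            c: fit_class_regression(self.data, c, offset=self.offset)
            for c in self.classes
        }
        wts = {c: mean_water_table(self.data, c) for c in self.classes}
        return WaterTableFluxResults(regs, wts, model=self)


class WaterTableFluxResults:
    """Fitted per-class flux regressions with diagnostics and prediction.

    Also constructible directly from published coefficients
    (:meth:`from_coefficients`) for reproduction runs on printed constants;
    such results carry no covariance and cannot drive Monte-Carlo
    uncertainty propagation.
    """

    def __init__(
        self,
        regressions: Mapping[str, ClassRegression],
        mean_water_tables: Mapping[str, float],
        model: WaterTableFluxModel | None = None,
    ):
        self.regressions = dict(regressions)
        self.mean_water_tables = dict(mean_water_tables)
        self.model = model

    @classmethod
    def from_coefficients(
        cls,
        coefficients: Mapping[str, tuple[float, float]] | None = None,
        mean_water_tables: Mapping[str, float] | None = None,
        offset: float = FLUX_OFFSET,
    ) -> "WaterTableFluxResults":
        """Results object for the published western-Canada regressions.

        `coefficients` maps class -> (slope, intercept); defaults to the
        compiled literature values, as do the mean water tables.
        """
        coefficients = dict(coefficients or REGRESSION_COEFFICIENTS)
        wts = dict(mean_water_tables or MEAN_WATER_TABLE_CM)
        regs = {
            c: ClassRegression(peat_class=c, slope=a, intercept=b, offset=offset)
            for c, (a, b) in coefficients.items()
        }
        return cls(regs, {c: wts[c] for c in regs})

    def __getitem__(self, peat_class: str) -> ClassRegression:
        return self.regressions[peat_class]

    def __contains__(self, peat_class: str) -> bool:
        return peat_class in self.regressions

    @property
    def classes(self) -> list[str]:
        return [c for c in PEAT_CLASSES if c in self.regressions]

    def predict_daily(self, peat_class: str, water_table_cm, smearing: bool = False):
        return self.regressions[peat_class].predict_daily(water_table_cm, smearing=smearing)

    def seasonal_flux(
        self, peat_class: str, water_table_cm, season: SeasonSpec | None = None,
        smearing: bool = False,
    ):
        return self.regressions[peat_class].seasonal(
            water_table_cm, season=season, smearing=smearing
        )

    def summary(self) -> pd.DataFrame:
        """One row per class: coefficients, R2, F(1, n-2), p, residual SE, n."""
        rows = []
        for c in self.classes:
            r = self.regressions[c]
            rows.append(
                {
                    "peat_class": c,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "offset": r.offset,
                    "r_squared": r.r_squared,
                    "f_statistic": r.f_statistic,
                    "df_model": None if r.nobs is None else 1,
                    "df_resid": r.df_resid,
                    "p_value": r.p_value,
                    "resid_se": r.resid_se,
                    "n": r.nobs,
                    "mean_water_table_cm": self.mean_water_tables.get(c),
                    # coefficient covariance, (intercept, slope) ordering
                    "cov_bb": None if r.cov_params is None else r.cov_params[0, 0],
                    "cov_ba": None if r.cov_params is None else r.cov_params[0, 1],
                    "cov_aa": None if r.cov_params is None else r.cov_params[1, 1],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    @classmethod
    def from_summary_csv(cls, path) -> "WaterTableFluxResults":
        """Rebuild a Results object from a summary CSV written by `to_csv`,
        including the coefficient covariance when present."""
        df = pd.read_csv(path)
        regs, wts = {}, {}
        for _, row in df.iterrows():
            c = row["peat_class"]
            cov = None
            if "cov_aa" in row and not pd.isna(row["cov_aa"]):
                cov = np.array(
                    [
                        [float(row["cov_bb"]), float(row["cov_ba"])],
                        [float(row["cov_ba"]), float(row["cov_aa"])],
                    ]
                )
            regs[c] = ClassRegression(
                peat_class=c,
                slope=float(row["slope"]),
                intercept=float(row["intercept"]),
                offset=float(row["offset"]),
                r_squared=_opt(row, "r_squared"),
                f_statistic=_opt(row, "f_statistic"),
                p_value=_opt(row, "p_value"),
                resid_se=_opt(row, "resid_se"),
                nobs=None if pd.isna(row.get("n")) else int(row["n"]),
                cov_params=cov,
            )
            if "mean_water_table_cm" in row and not pd.isna(row["mean_water_table_cm"]):
                wts[c] = float(row["mean_water_table_cm"])
        return cls(regs, wts)

    def plot(self, ax=None, wt_grid: Iterable[float] | None = None):
        """Scatter of observed fluxes (when fitted from data) with the fitted
        back-transformed curves, one colour per class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.asarray(
            list(wt_grid) if wt_grid is not None else np.linspace(-60.0, 10.0, 200)
        )
        colors = {"bog": "C3", "fen": "C0", "swamp": "C2"}
        for c in self.classes:
            if self.model is not None:
                sub = self.model.data[self.model.data["peat_class"] == c]
                ax.scatter(
                    sub["water_table_cm"], sub["flux_mg_m2_d"],
                    s=12, alpha=0.5, color=colors.get(c), label=None,
                )
            ax.plot(grid, self.predict_daily(c, grid), color=colors.get(c), label=c)
        ax.set_xlabel("water table position (cm)")
        ax.set_ylabel("CH$_4$ flux (mg m$^{-2}$ d$^{-1}$)")
        ax.legend(title="peatland class")
        return ax


def _opt(row, key) -> float | None:
    v = row.get(key)
    return None if v is None or pd.isna(v) else float(v)
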