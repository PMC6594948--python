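"""Emission scenarios: provincial baseline, seismic-line enhancement, and
Monte-Carlo uncertainty propagation.

The baseline is the sum over peatland classes of class area times the
seasonal emission factor evaluated at the class mean water table:

    E0 = sum_c A_c [km2] * F_c(WT_c) [g m-2]  -> tonnes; /1000 -> kt CH4.

(1 g m-2 over 1 km2 is 1 tonne, so kt = g m-2 x km2 x 1e-3.)

The disturbance scenario shifts each class's mean water table toward the
surface by a fixed amount (two point scenarios, 13.9 and 15.4 cm, from field
measurements on seismic lines) over the line footprint area only; the
enhancement is footprint x (disturbed - undisturbed emission factor).
Shifted water tables are deliberately not capped at the surface: the fen
scenario places the water table above ground, and the regression is
extrapolated there (a cap-at-zero option exists for sensitivity).

Uncertainty is propagated by parametric Monte Carlo: regression coefficient
pairs are drawn from each fitted model's estimated sampling distribution,
a class-level residual-scale prediction error is added on the log10 scale
(shared between the undisturbed and disturbed prediction of a draw, since it
represents how far the class's true mean flux sits from the regression
line), and the whole emission arithmetic is recomputed per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    CLASS_AREA_KM2,
    PEAT_CLASSES,
    SEISMIC_FOOTPRINT_KM2,
    SEISMIC_LINE_LENGTH_KM,
    WT_SHIFTS_CM,
)
from .flux import ClassRegression, SeasonSpec, WaterTableFluxResults
from .footprint import FootprintSummary

__all__ = [
    "DisturbanceSpec",
    "RegionInventory",
    "ScenarioResult",
    "baseline_emissions",
    "disturbed_flux",
    "enhancement",
    "reproduction_scenario",
    "propagate_uncertainty",
]

#: g CH4 m-2 x km2 -> kt CH4 (1 g m-2 km2 = 1 t; 1000 t = 1 kt).
G_M2_KM2_TO_KT = 1e-3


@dataclass(frozen=True)
class DisturbanceSpec:
    """Water-table shifts on the line footprint, cm toward the surface."""

    shifts_cm: tuple[float, ...] = WT_SHIFTS_CM

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.shifts_cm):
            raise ValueError("water-table shifts must be >= 0")


@dataclass(frozen=True)
class RegionInventory:
    """Total peatland area per class, km2 (defaults: Alberta inventory)."""

    class_areas_km2: dict[str, float] = field(
        default_factory=lambda: dict(CLASS_AREA_KM2)
    )

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.class_areas_km2.values()):
            raise ValueError("class areas must be >= 0")

    def __getitem__(self, peat_class: str) -> float:
        return self.class_areas_km2[peat_class]


def _resolve_wts(
    results: WaterTableFluxResults, mean_wts: Mapping[str, float] | None
) -> dict[str, float]:
    wts = dict(mean_wts) if mean_wts is not None else dict(results.mean_water_tables)
    missing = [c for c in results.classes if c not in wts]
    if missing:
        raise ValueError(f"no mean water table for classes: {missing}")
    return wts


def _footprint_areas(footprint) -> dict[str, float]:
    if isinstance(footprint, FootprintSummary):
        return footprint.peatland_area_km2.to_dict()
    return dict(footprint)


def baseline_emissions(
    results: WaterTableFluxResults,
    inventory: RegionInventory | None = None,
    season: SeasonSpec | None = None,
    mean_wts: Mapping[str, float] | None = None,
) -> float:
    """Province-wide undisturbed peatland CH4 emission, kt per year."""
    inventory = inventory or RegionInventory()
    season = season or SeasonSpec()
    wts = _resolve_wts(results, mean_wts)
    total = 0.0
    for c, area in inventory.class_areas_km2.items():
        if c not in results:
            raise ValueError(f"no fitted model for inventory class {c!r}")
        total += area * results.seasonal_flux(c, wts[c], season) * G_M2_KM2_TO_KT
    return total


def disturbed_flux(
    model: ClassRegression,
    mean_wt: float,
    delta_cm: float,
    season: SeasonSpec | None = None,
    cap_at_surface: bool = False,
) -> float:
    """Seasonal emission factor (g m-2) with the water table raised by
    `delta_cm`; `cap_at_surface` limits the shifted water table to 0 cm."""
    if delta_cm < 0:
        raise ValueError("water-table shift must be >= 0")
    wt = mean_wt + delta_cm
    if cap_at_surface:
        wt = min(wt, 0.0)
    return float(model.seasonal(wt, season=season))


@dataclass
class ScenarioResult:
    """Per-class emission factors and enhancement totals for a shift bracket."""

    season_days: float
    shifts_cm: tuple[float, ...]
    mean_water_tables: dict[str, float]
    class_areas_km2: dict[str, float]
    footprint_km2: dict[str, float]
    undisturbed_g_m2: dict[str, float]
    disturbed_g_m2: dict[float, dict[str, float]]
    enhancement_kt: dict[float, dict[str, float]]
    baseline_kt: float
    line_lengths_km: dict[str, float] | None = None

    @property
    def classes(self) -> list[str]:
        return [c for c in PEAT_CLASSES if c in self.undisturbed_g_m2]

    def enhancement_total_kt(self, delta_cm: float) -> float:
        return float(sum(self.enhancement_kt[delta_cm].values()))

    @property
    def enhancement_range_kt(self) -> tuple[float, float]:
        totals = [self.enhancement_total_kt(d) for d in self.shifts_cm]
        return (min(totals), max(totals))

    def to_frame(self) -> pd.DataFrame:
        """Report table: classes as columns plus a total column; rows are the
        inventory areas, line lengths/footprint, undisturbed and disturbed
        emission factors (bracket low-high), and the enhancement bracket."""
        classes = self.classes
        lo, hi = min(self.shifts_cm), max(self.shifts_cm)
        rows = {
            "total_area_km2": {c: self.class_areas_km2.get(c) for c in classes},
            "seismic_line_length_km": {
                c: (self.line_lengths_km or {}).get(c, np.nan) for c in classes
            },
            "seismic_footprint_km2": {c: self.footprint_km2.get(c, 0.0) for c in classes},
            "undisturbed_flux_g_m2": self.undisturbed_g_m2,
            f"disturbed_flux_g_m2_shift_{lo}": self.disturbed_g_m2[lo],
            f"disturbed_flux_g_m2_shift_{hi}": self.disturbed_g_m2[hi],
            f"enhancement_kt_shift_{lo}": self.enhancement_kt[lo],
            f"enhancement_kt_shift_{hi}": self.enhancement_kt[hi],
        }
        df = pd.DataFrame(rows).T[classes]
        df["total"] = df.sum(axis=1, skipna=False)
        # Emission factors are intensive; their row totals are meaningless.
        for r in df.index:
            if "flux_g_m2" in r:
                df.loc[r, "total"] = np.nan
        return df

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "quantity"
        df.to_csv(path)

    def summary(self) -> str:
        lo, hi = self.enhancement_range_kt
        lines = [
            f"Provincial undisturbed baseline: {self.baseline_kt:.1f} kt CH4 yr-1",
            f"Seismic-line enhancement ({min(self.shifts_cm)}-{max(self.shifts_cm)} cm "
            f"water-table rise): {lo:.2f}-{hi:.2f} kt CH4 yr-1",
        ]
        for c in self.classes:
            per = ", ".join(
                f"{self.enhancement_kt[d][c]:.2f} kt @ +{d} cm" for d in self.shifts_cm
            )
            lines.append(f"  {c}: {per}")
        return "\n".join(lines)


def enhancement(
    results: WaterTableFluxResults,
    footprint,
    deltas: DisturbanceSpec | None = None,
    inventory: RegionInventory | None = None,
    season: SeasonSpec | None = None,
    mean_wts: Mapping[str, float] | None = None,
    cap_at_surface: bool = False,
    line_lengths_km: Mapping[str, float] | None = None,
) -> ScenarioResult:
    """Seismic-line emission enhancement for each water-table shift.

    `footprint` is a :class:`~peatline.footprint.FootprintSummary` or a
    mapping class -> disturbed area km2. Enhancement per class and shift is
    footprint area x (disturbed - undisturbed seasonal flux), in kt.
    """
    deltas = deltas or DisturbanceSpec()
    inventory = inventory or RegionInventory()
    season = season or SeasonSpec()
    wts = _resolve_wts(results, mean_wts)
    fp = _footprint_areas(footprint)
    classes = results.classes

    undisturbed = {c: float(results.seasonal_flux(c, wts[c], season)) for c in classes}
    disturbed: dict[float, dict[str, float]] = {}
    enh: dict[float, dict[str, float]] = {}
    for d in deltas.shifts_cm:
        disturbed[d] = {
            c: disturbed_flux(results[c], wts[c], d, season, cap_at_surface)
            for c in classes
        }
        enh[d] = {
            c: fp.get(c, 0.0) * (disturbed[d][c] - undisturbed[c]) * G_M2_KM2_TO_KT
            for c in classes
        }
    return ScenarioResult(
        season_days=season.days,
        shifts_cm=tuple(deltas.shifts_cm),
        mean_water_tables={c: wts[c] for c in classes},
        class_areas_km2=dict(inventory.class_areas_km2),
        footprint_km2={c: fp.get(c, 0.0) for c in classes},
        undisturbed_g_m2=undisturbed,
        disturbed_g_m2=disturbed,
        enhancement_kt=enh,
        baseline_kt=baseline_emissions(results, inventory, season, wts),
        line_lengths_km=dict(line_lengths_km) if line_lengths_km else None,
    )


def reproduction_scenario(
    season: SeasonSpec | None = None,
    deltas: DisturbanceSpec | None = None,
) -> ScenarioResult:
    """The full printed-constant reproduction run: compiled regression
    coefficients, class mean water tables, inventory areas and line
    footprint, 123-day season, 13.9/15.4 cm shift bracket."""
    results = WaterTableFluxResults.from_coefficients()
    return enhancement(
        results,
        footprint=SEISMIC_FOOTPRINT_KM2,
        deltas=deltas,
        inventory=RegionInventory(),
        season=season,
        line_lengths_km=SEISMIC_LINE_LENGTH_KM,
    )


def propagate_uncertainty(
    results: WaterTableFluxResults,
    footprint,
    deltas: DisturbanceSpec | None = None,
    inventory: RegionInventory | None = None,
    season: SeasonSpec | None = None,
    mean_wts: Mapping[str, float] | None = None,
    n_draws: int = 2000,
    seed: int = 0,
    coef_scale: float = 1.0,
    resid_scale: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo percentile intervals for the baseline and enhancement.

    Per draw and class, (intercept, slope) is sampled from the fitted
    coefficient covariance (scaled by `coef_scale`) and a shared residual
    error ~ N(0, (resid_scale * resid_se)^2) is added to the log10 linear
    predictor of both the undisturbed and the shifted prediction. Negative
    baseline draws are truncated at zero for reporting. Returns a DataFrame
    indexed by quantity with columns point, p2.5, p50, p97.5. Requires
    fitted models (with covariance and residual scale); results built from
    published coefficients alone raise ValueError.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    deltas = deltas or DisturbanceSpec()
    inventory = inventory or RegionInventory()
    season = season or SeasonSpec()
    wts = _resolve_wts(results, mean_wts)
    fp = _footprint_areas(footprint)
    classes = results.classes
    for c in classes:
        r = results[c]
        if r.cov_params is None or r.resid_se is None:
            raise ValueError(
                f"class {c!r} lacks a coefficient covariance / residual scale; "
                "fit the model to data to propagate uncertainty"
            )

    rng = np.random.default_rng(seed)
    baseline = np.zeros(n_draws)
    enh_tot = {d: np.zeros(n_draws) for d in deltas.shifts_cm}
    for c in classes:
        r = results[c]
        cov = np.asarray(r.cov_params, dtype=float) * coef_scale**2
        params = rng.multivariate_normal([r.intercept, r.slope], cov, size=n_draws)
        eps = rng.normal(0.0, resid_scale * r.resid_se, size=n_draws)
        b, a = params[:, 0], params[:, 1]
        fac = season.days / 1000.0
        undist = (10.0 ** (a * wts[c] + b + eps) - r.offset) * fac
        baseline += inventory.class_areas_km2.get(c, 0.0) * undist * G_M2_KM2_TO_KT
        for d in deltas.shifts_cm:
            dist = (10.0 ** (a * (wts[c] + d) + b + eps) - r.offset) * fac
            enh_tot[d] += fp.get(c, 0.0) * (dist - undist) * G_M2_KM2_TO_KT

    point = enhancement(
        results, fp, deltas, inventory, season, wts
    )
    rows = {}

    def pct(draws: np.ndarray, point_value: float) -> dict[str, float]:
        q = np.percentile(draws, [2.5, 50.0, 97.5])
        return {"point": point_value, "p2.5": q[0], "p50": q[1], "p97.5": q[2]}

    rows["baseline_kt"] = pct(np.maximum(baseline, 0.0), point.baseline_kt)
    for d in deltas.shifts_cm:
        rows[f"enhancement_kt_shift_{d}"] = pct(enh_tot[d], point.enhancement_total_kt(d))
    return pd.DataFrame(rows).T[["point", "p2.5", "p50", "p97.5"]]
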