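"""Literature constants for the Alberta seismic-line methane assessment.

These are the published inputs the reproduction mode runs on: per-class
flux~water-table regression coefficients compiled from western-Canadian
chamber studies, provincial wetland-inventory areas, human-footprint
seismic-line lengths and widths, and the hydrologic disturbance bracket
measured on seismic lines in Alberta peatlands.
"""

from __future__ import annotations

#: Peatland classes carried through the whole analysis. Marsh and open water
#: occur in the wetland inventory but are not peatland and are excluded from
#: emission totals.
PEAT_CLASSES: tuple[str, ...] = ("bog", "fen", "swamp")

#: Non-peatland wetland classes present in the polygon inventory.
OTHER_WETLAND_CLASSES: tuple[str, ...] = ("marsh", "open_water")

WETLAND_CLASSES: tuple[str, ...] = PEAT_CLASSES + OTHER_WETLAND_CLASSES

#: Seismic-line types in the human-footprint inventory. "legacy" = pre-1990s
#: bulldozed lines, "LIS" = low-impact seismic, "trail" = industrial or
#: recreational linear features of similar appearance.
LINE_TYPES: tuple[str, ...] = ("legacy", "LIS", "trail")

#: Fixed offset c in the log10(flux + c) transform; accommodates small
#: negative (uptake) fluxes. A model constant, never estimated.
FLUX_OFFSET: float = 2.0

#: Emission period in days (May-August growing season); dormant-season
#: emissions are assumed zero, so seasonal == annual.
SEASON_DAYS: float = 123.0

#: Water-table shift on seismic lines, cm toward the surface. Two point
#: scenarios from field measurements on disturbed fens (13.9) and bogs (15.4).
WT_SHIFTS_CM: tuple[float, float] = (13.9, 15.4)

#: (slope, intercept) of log10(flux_mg_m2_d + 2) = slope * WT_cm + intercept.
REGRESSION_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "bog": (0.022, 1.53),
    "fen": (0.025, 1.67),
    "swamp": (0.015, 0.99),
}

#: Sample sizes behind the compiled regressions (from the F-test degrees of
#: freedom: F(1, n-2)).
REGRESSION_N: dict[str, int] = {"bog": 57, "fen": 176, "swamp": 34}

#: Coefficients of determination of the compiled regressions.
REGRESSION_R2: dict[str, float] = {"bog": 0.42, "fen": 0.17, "swamp": 0.16}

#: Mean summer water-table position (cm, negative below surface) of
#: undisturbed plots in the flux compilation.
MEAN_WATER_TABLE_CM: dict[str, float] = {"bog": -22.0, "fen": -8.0, "swamp": -18.0}

#: Total peatland area in Alberta by class, km2 (merged wetland inventory).
CLASS_AREA_KM2: dict[str, float] = {
    "bog": 30_050.0,
    "fen": 58_580.0,
    "swamp": 46_160.0,
}

#: Total seismic-line and trail length crossing each peatland class, km.
SEISMIC_LINE_LENGTH_KM: dict[str, float] = {
    "bog": 88_580.0,
    "fen": 144_580.0,
    "swamp": 112_480.0,
}

#: Seismic-line footprint area within each peatland class, km2 (lengths
#: converted to areas with the type widths below).
SEISMIC_FOOTPRINT_KM2: dict[str, float] = {
    "bog": 490.0,
    "fen": 790.0,
    "swamp": 630.0,
}

#: Average cleared width per line type, metres.
LINE_WIDTH_M: dict[str, float] = {"legacy": 6.0, "LIS": 3.0, "trail": 4.0}
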