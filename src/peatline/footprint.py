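"""Seismic-line footprint: clipped lengths per wetland class and disturbed
areas per line type.

The line network is intersected with the wetland polygon mosaic; clipped
length is attributed to the class of the polygon it falls in (segments
outside every wetland polygon, or inside marsh/open water, are tallied but
excluded from peatland totals). Lengths convert to disturbed area either by
the length x width product (the reproduction method, consistent with the
provincial totals) or by geometric buffering with overlap dissolve (a
sensitivity option: buffering each line by width/2 with flat caps and
dissolving overlaps can only reduce area relative to length x width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box
from shapely.ops import unary_union

from .constants import LINE_TYPES, LINE_WIDTH_M, PEAT_CLASSES, WETLAND_CLASSES
from .synthetic import OUTSIDE_LABEL, LandscapeBundle

__all__ = [
    "WidthSpec",
    "FootprintSummary",
    "intersect_lines_with_classes",
    "lengths_to_areas",
    "buffered_areas",
    "density_grid",
]

_ROW_ORDER = list(WETLAND_CLASSES) + [OUTSIDE_LABEL]


@dataclass(frozen=True)
class WidthSpec:
    """Average cleared width per line type, metres."""

    widths_m: dict[str, float] = field(default_factory=lambda: dict(LINE_WIDTH_M))

    def __post_init__(self) -> None:
        missing = set(LINE_TYPES) - set(self.widths_m)
        if missing:
            raise ValueError(f"missing widths for line types: {sorted(missing)}")
        if any(w <= 0 for w in self.widths_m.values()):
            raise ValueError("all line widths must be > 0")

    def __getitem__(self, line_type: str) -> float:
        return self.widths_m[line_type]


@dataclass
class FootprintSummary:
    """Per (wetland class x line type) line length and disturbed area.

    `lengths_km` and `areas_km2` are DataFrames with one row per wetland
    class plus an 'outside' row, one column per line type. Peatland totals
    exclude marsh, open water and outside-wetland segments. `method` records
    how areas were derived ("length_x_width" or "buffer_dissolve").
    """

    lengths_km: pd.DataFrame
    areas_km2: pd.DataFrame
    widths: WidthSpec
    method: str = "length_x_width"
    include_swamp: bool = True

    @property
    def peat_classes(self) -> list[str]:
        classes = list(PEAT_CLASSES)
        if not self.include_swamp:
            classes.remove("swamp")
        return classes

    @property
    def peatland_length_km(self) -> pd.Series:
        """Total line length per peatland class (km), summed over types."""
        return self.lengths_km.loc[self.peat_classes].sum(axis=1)

    @property
    def peatland_area_km2(self) -> pd.Series:
        """Disturbed area per peatland class (km2), summed over types."""
        return self.areas_km2.loc[self.peat_classes].sum(axis=1)

    @property
    def total_length_km(self) -> float:
        return float(self.peatland_length_km.sum())

    @property
    def total_area_km2(self) -> float:
        return float(self.peatland_area_km2.sum())

    def to_csv(self, path) -> None:
        """Length and area tables side by side, classes as rows."""
        out = pd.concat(
            {"length_km": self.lengths_km, "area_km2": self.areas_km2}, axis=1
        )
        out.index.name = "wetland_class"
        out.to_csv(path)


def _check_bundle(bundle: LandscapeBundle) -> None:
    for i, (geom, label) in enumerate(bundle.polygons):
        if label not in WETLAND_CLASSES:
            raise ValueError(f"polygon {i}: unknown wetland class {label!r}")
        if not geom.is_valid:
            raise ValueError(f"polygon {i} (class {label!r}): invalid geometry")
    for i, (geom, label) in enumerate(bundle.lines):
        if label not in LINE_TYPES:
            raise ValueError(f"line {i}: unknown line type {label!r}")
        if not geom.is_valid:
            raise ValueError(f"line {i} (type {label!r}): invalid geometry")


def intersect_lines_with_classes(bundle: LandscapeBundle) -> pd.DataFrame:
    """Clipped line length (km) per wetland class x line type.

    Each polyline is clipped against every wetland polygon it touches and the
    clipped length attributed to that polygon's class; the residual (outside
    every wetland polygon) goes to the 'outside' row. Assumes polygons are
    mutually non-overlapping, as the wetland inventory guarantees.
    """
    _check_bundle(bundle)
    lengths = pd.DataFrame(0.0, index=_ROW_ORDER, columns=list(LINE_TYPES))
    if not bundle.lines:
        return lengths
    geoms = [g for g, _ in bundle.polygons]
    tree = STRtree(geoms) if geoms else None
    for line, line_type in bundle.lines:
        inside = 0.0
        if tree is not None:
            for j in tree.query(line):
                poly, label = bundle.polygons[int(j)]
                seg = line.intersection(poly)
                if not seg.is_empty:
                    lengths.loc[label, line_type] += seg.length / 1000.0
                    inside += seg.length
        lengths.loc[OUTSIDE_LABEL, line_type] += max(line.length - inside, 0.0) / 1000.0
    return lengths


def lengths_to_areas(
    lengths_km: pd.DataFrame,
    widths: WidthSpec | None = None,
    include_swamp: bool = True,
) -> FootprintSummary:
    """Convert clipped lengths to disturbed areas by length x width.

    area_km2[class, type] = length_km * width_m / 1000. This is the
    reproduction method; see :func:`buffered_areas` for the geometric
    alternative.
    """
    widths = widths or WidthSpec()
    lengths = lengths_km.reindex(index=_ROW_ORDER, columns=list(LINE_TYPES)).fillna(0.0)
    areas = lengths.copy()
    for lt in LINE_TYPES:
        areas[lt] = lengths[lt] * widths[lt] / 1000.0
    return FootprintSummary(
        lengths_km=lengths,
        areas_km2=areas,
        widths=widths,
        method="length_x_width",
        include_swamp=include_swamp,
    )


def buffered_areas(
    bundle: LandscapeBundle,
    widths: WidthSpec | None = None,
    include_swamp: bool = True,
) -> FootprintSummary:
    """Disturbed areas by geometric buffering with overlap dissolve.

    Each line is buffered by width/2 with flat end caps; buffers of the same
    type are dissolved (so crossings and re-runs are not double counted) and
    intersected with the class polygons. Always <= the length x width area,
    cell by cell.
    """
    _check_bundle(bundle)
    widths = widths or WidthSpec()
    lengths = intersect_lines_with_classes(bundle)
    areas = pd.DataFrame(0.0, index=_ROW_ORDER, columns=list(LINE_TYPES))
    class_union = {
        label: unary_union([g for g, lab in bundle.polygons if lab == label])
        for label in {lab for _, lab in bundle.polygons}
    }
    wetland_union = unary_union([g for g, _ in bundle.polygons]) if bundle.polygons else None
    for lt in LINE_TYPES:
        group = [g for g, t in bundle.lines if t == lt]
        if not group:
            continue
        dissolved = unary_union([g.buffer(widths[lt] / 2.0, cap_style="flat") for g in group])
        for label, cu in class_union.items():
            areas.loc[label, lt] = dissolved.intersection(cu).area / 1e6
        if wetland_union is not None:
            areas.loc[OUTSIDE_LABEL, lt] = dissolved.difference(wetland_union).area / 1e6
        else:
            areas.loc[OUTSIDE_LABEL, lt] = dissolved.area / 1e6
    return FootprintSummary(
        lengths_km=lengths,
        areas_km2=areas,
        widths=widths,
        method="buffer_dissolve",
        include_swamp=include_swamp,
    )


def density_grid(
    bundle: LandscapeBundle, cell_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Line density (km per km2) on a regular grid over the bundle extent.

    Returns (density array [nrows, ncols], x edges, y edges); rows index y
    from the bottom. All line types are pooled.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be > 0")
    if bundle.metadata.get("region_extent"):
        xmin, ymin, xmax, ymax = bundle.metadata["region_extent"]
    else:
        geoms = [g for g, _ in bundle.polygons] + [g for g, _ in bundle.lines]
        if not geoms:
            return np.zeros((0, 0)), np.array([]), np.array([])
        bounds = np.array([g.bounds for g in geoms])
        xmin, ymin = bounds[:, :2].min(axis=0)
        xmax, ymax = bounds[:, 2:].max(axis=0)
    x_edges = np.arange(xmin, xmax + cell_size / 2, cell_size)
    y_edges = np.arange(ymin, ymax + cell_size / 2, cell_size)
    if x_edges[-1] < xmax:
        x_edges = np.append(x_edges, xmax)
    if y_edges[-1] < ymax:
        y_edges = np.append(y_edges, ymax)
    dens = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    lines = [g for g, _ in bundle.lines]
    tree = STRtree(lines) if lines else None
    for i in range(dens.shape[0]):
        for j in range(dens.shape[1]):
            cell = box(x_edges[j], y_edges[i], x_edges[j + 1], y_edges[i + 1])
            cell_km2 = cell.area / 1e6
            if tree is None or cell_km2 == 0:
                continue
            total = sum(lines[int(k)].intersection(cell).length for k in tree.query(cell))
            dens[i, j] = (total / 1000.0) / cell_km2
    return dens, x_edges, y_edges
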