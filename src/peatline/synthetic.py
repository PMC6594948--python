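"""Synthetic flux tables and vector landscapes for end-to-end testing.

Real inputs to the analysis are (a) a literature compilation of plot-level
CH4 flux and water-table pairs and (b) provincial wetland-polygon and
seismic-line vector inventories. Neither is redistributable, so this module
generates stand-ins with the statistical and spatial structure the pipeline
assumes:

* ``generate_flux_table`` draws plots per class from the generating model
  flux = 10^(a*WT + b + eps) - 2, eps ~ N(0, sd), with WT from a truncated
  normal — so the regression stage can be validated by parameter recovery.
* ``generate_landscape`` tiles a rectangular region into labelled wetland
  polygons and lays a line network over it: straight full-span legacy and
  trail grids plus dense serpentine low-impact-seismic (LIS) paths confined
  to tiles. Because tiles are axis-aligned, the exact clipped length of
  every line in every class is computed at construction time by interval
  arithmetic (independent of any geometry library) and recorded in the
  bundle metadata as ground truth for the footprint stage.

All randomness flows from a single integer seed; identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Polygon, box, mapping, shape

from .constants import (
    LINE_TYPES,
    MEAN_WATER_TABLE_CM,
    PEAT_CLASSES,
    REGRESSION_COEFFICIENTS,
    REGRESSION_N,
    WETLAND_CLASSES,
)

__all__ = [
    "ClassGenSpec",
    "GenerationConfig",
    "generate_flux_table",
    "LandscapeBundle",
    "generate_landscape",
    "write_bundle",
    "read_bundle",
    "BundleParseError",
]

#: Label used in truth metadata for line length outside every wetland polygon.
OUTSIDE_LABEL = "outside"

#: Default residual standard deviations (log10 units), set by inverting
#: R^2 = a^2 var(WT) / (a^2 var(WT) + sd^2) at the compiled regressions'
#: R^2 values with the default 10-cm water-table spread.
DEFAULT_RESID_SD = {"bog": 0.26, "fen": 0.55, "swamp": 0.34}


@dataclass(frozen=True)
class ClassGenSpec:
    """Generating model for one peatland class.

    slope/intercept parameterise log10(flux+2) = slope*WT + intercept;
    resid_sd is the residual scale in log10 units; water tables are drawn
    from Normal(wt_mean, wt_sd) truncated to wt_range (cm).
    """

    slope: float
    intercept: float
    resid_sd: float
    n: int
    wt_mean: float
    wt_sd: float = 10.0
    wt_range: tuple[float, float] = (-60.0, 10.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"need n >= 3 per class, got {self.n}")
        if not self.resid_sd > 0:
            raise ValueError(f"residual sd must be > 0, got {self.resid_sd}")
        if not self.wt_sd > 0:
            raise ValueError("water-table spread must be > 0")


@dataclass(frozen=True)
class GenerationConfig:
    """Per-class generating specs plus the seed fixing all randomness."""

    classes: dict[str, ClassGenSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(PEAT_CLASSES)
        if bad:
            raise ValueError(f"unknown peat classes in config: {sorted(bad)}")

    @classmethod
    def default(cls, seed: int = 0, resid_scale: float = 1.0) -> "GenerationConfig":
        """Study conditions: compiled-regression coefficients, sample sizes
        and class mean water tables; residual sd per class matched to the
        compiled R^2 (optionally scaled by `resid_scale`)."""
        specs = {}
        for c in PEAT_CLASSES:
            a, b = REGRESSION_COEFFICIENTS[c]
            specs[c] = ClassGenSpec(
                slope=a,
                intercept=b,
                resid_sd=DEFAULT_RESID_SD[c] * resid_scale,
                n=REGRESSION_N[c],
                wt_mean=MEAN_WATER_TABLE_CM[c],
            )
        return cls(classes=specs, seed=seed)


def generate_flux_table(config: GenerationConfig) -> pd.DataFrame:
    """Draw a plot-level flux table from the generating model.

    Returns a DataFrame with columns site_id, peat_class, water_table_cm,
    flux_mg_m2_d. Every flux exceeds -2 by construction of the
    back-transform. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for c in sorted(config.classes):
        spec = config.classes[c]
        lo, hi = spec.wt_range
        a_std = (lo - spec.wt_mean) / spec.wt_sd
        b_std = (hi - spec.wt_mean) / spec.wt_sd
        wt = stats.truncnorm.rvs(
            a_std, b_std, loc=spec.wt_mean, scale=spec.wt_sd, size=spec.n,
            random_state=rng,
        )
        eps = rng.normal(0.0, spec.resid_sd, size=spec.n)
        flux = 10.0 ** (spec.slope * wt + spec.intercept + eps) - 2.0
        frames.append(
            pd.DataFrame(
                {
                    "site_id": [f"{c}_{i:03d}" for i in range(spec.n)],
                    "peat_class": c,
                    "water_table_cm": wt,
                    "flux_mg_m2_d": flux,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Vector landscape
# ---------------------------------------------------------------------------


@dataclass
class LandscapeBundle:
    """Wetland polygons + typed line network in planar metres.

    polygons: list of (shapely Polygon, wetland class label);
    lines: list of (shapely LineString, line type label);
    metadata: generation parameters and the construction-truth clipped
    lengths (km) per label x line type under key ``"truth_lengths_km"``.
    """

    polygons: list[tuple[Polygon, str]]
    lines: list[tuple[LineString, str]]
    metadata: dict = field(default_factory=dict)

    def truth_lengths(self) -> pd.DataFrame:
        """Construction-truth clipped lengths (km): rows = wetland classes
        plus 'outside', columns = line types."""
        truth = self.metadata.get("truth_lengths_km", {})
        idx = list(WETLAND_CLASSES) + [OUTSIDE_LABEL]
        df = pd.DataFrame(0.0, index=idx, columns=list(LINE_TYPES))
        for label, per_type in truth.items():
            for lt, km in per_type.items():
                df.loc[label, lt] = km
        return df


DEFAULT_CLASS_FRACTIONS = {
    "bog": 0.25,
    "fen": 0.30,
    "swamp": 0.15,
    "marsh": 0.05,
    "open_water": 0.05,
}

#: km of line per km2 of landscape; LIS grids are an order of magnitude
#: denser than conventional lines where present.
DEFAULT_LINE_DENSITIES = {"legacy": 1.5, "LIS": 3.0, "trail": 0.5}


def generate_landscape(
    region_extent: tuple[float, float, float, float] = (0.0, 0.0, 10_000.0, 10_000.0),
    class_fractions: dict[str, float] | None = None,
    line_densities: dict[str, float] | None = None,
    tile_size: float = 1000.0,
    seed: int = 0,
) -> LandscapeBundle:
    """Generate a labelled wetland mosaic crossed by a seismic-line network.

    The region (metres) is tiled into a grid of square-ish cells, each
    assigned a wetland class (or left unlabelled upland) so that class areas
    approximate ``class_fractions`` (which must sum to <= 1). Legacy and
    trail lines are straight full-span horizontal/vertical grids; LIS lines
    are serpentine paths laid within individual tiles. Line counts are chosen
    so each type's total length approximates density x area.

    Truth metadata records, for every (wetland class | outside) x line type,
    the exact length of line inside that class, computed from the grid
    geometry by interval arithmetic.
    """
    xmin, ymin, xmax, ymax = map(float, region_extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"empty region extent {region_extent}")
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    bad = set(fractions) - set(WETLAND_CLASSES)
    if bad:
        raise ValueError(f"unknown wetland classes: {sorted(bad)}")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")
    densities = dict(DEFAULT_LINE_DENSITIES if line_densities is None else line_densities)
    if any(d < 0 for d in densities.values()):
        raise ValueError("line densities must be >= 0")

    rng = np.random.default_rng(seed)
    w, h = xmax - xmin, ymax - ymin
    ncols = max(1, int(round(w / tile_size)))
    nrows = max(1, int(round(h / tile_size)))
    tile_w, tile_h = w / ncols, h / nrows
    ntiles = nrows * ncols

    # Assign labels to tiles: largest-remainder apportionment, then shuffle.
    labels_flat: list[str | None] = []
    targets = {c: fractions[c] * ntiles for c in sorted(fractions)}
    counts = {c: int(np.floor(t)) for c, t in targets.items()}
    leftover = ntiles - sum(counts.values()) - int(round((1.0 - sum(fractions.values())) * ntiles))
    remainders = sorted(targets, key=lambda c: targets[c] - counts[c], reverse=True)
    for c in remainders:
        if leftover <= 0:
            break
        counts[c] += 1
        leftover -= 1
    for c, k in counts.items():
        labels_flat.extend([c] * k)
    labels_flat.extend([None] * (ntiles - len(labels_flat)))
    labels = np.array(labels_flat, dtype=object)[rng.permutation(ntiles)].reshape(nrows, ncols)

    polygons: list[tuple[Polygon, str]] = []
    for r in range(nrows):
        for cidx in range(ncols):
            lab = labels[r, cidx]
            if lab is None:
                continue
            x0, y0 = xmin + cidx * tile_w, ymin + r * tile_h
            polygons.append((box(x0, y0, x0 + tile_w, y0 + tile_h), str(lab)))

    area_km2 = (w / 1000.0) * (h / 1000.0)
    truth: dict[str, dict[str, float]] = {}

    def add_truth(label: str, line_type: str, metres: float) -> None:
        truth.setdefault(label, {}).setdefault(line_type, 0.0)
        truth[label][line_type] += metres / 1000.0

    lines: list[tuple[LineString, str]] = []

    def off_boundary(coord: float, origin: float, step: float) -> float:
        # Nudge coordinates off tile edges so clipped lengths are unambiguous.
        frac = (coord - origin) / step
        if abs(frac - round(frac)) < 1e-9:
            coord += 1e-3 * step
        return coord

    def span_lines(line_type: str, horizontal: bool) -> None:
        d = densities.get(line_type, 0.0)
        if d <= 0:
            return
        span_km = (w if horizontal else h) / 1000.0
        n = int(round(d * area_km2 / span_km))
        for k in range(n):
            if horizontal:
                y = off_boundary(ymin + (k + 0.5) * h / n, ymin, tile_h)
                lines.append((LineString([(xmin, y), (xmax, y)]), line_type))
                row = min(int((y - ymin) / tile_h), nrows - 1)
                for cidx in range(ncols):
                    lab = labels[row, cidx]
                    add_truth(OUTSIDE_LABEL if lab is None else str(lab), line_type, tile_w)
            else:
                x = off_boundary(xmin + (k + 0.5) * w / n, xmin, tile_w)
                lines.append((LineString([(x, ymin), (x, ymax)]), line_type))
                col = min(int((x - xmin) / tile_w), ncols - 1)
                for r in range(nrows):
                    lab = labels[r, col]
                    add_truth(OUTSIDE_LABEL if lab is None else str(lab), line_type, tile_h)

    span_lines("legacy", horizontal=True)
    span_lines("trail", horizontal=False)

    d_lis = densities.get("LIS", 0.0)
    if d_lis > 0:
        target_m = d_lis * (tile_w / 1000.0) * (tile_h / 1000.0) * 1000.0
        margin_w, margin_h = 0.05 * tile_w, 0.05 * tile_h
        for r in range(nrows):
            for cidx in range(ncols):
                x0 = xmin + cidx * tile_w + margin_w
                y0 = ymin + r * tile_h + margin_h
                wi, hi = tile_w - 2 * margin_w, tile_h - 2 * margin_h
                path = _serpentine(x0, y0, wi, hi, target_m)
                if path is None:
                    continue
                pts = np.asarray(path)
                length_m = float(np.hypot(*np.diff(pts, axis=0).T).sum())
                lines.append((LineString(path), "LIS"))
                lab = labels[r, cidx]
                add_truth(OUTSIDE_LABEL if lab is None else str(lab), "LIS", length_m)

    metadata = {
        "seed": int(seed),
        "region_extent": [xmin, ymin, xmax, ymax],
        "tile_size_m": tile_size,
        "grid": [nrows, ncols],
        "class_fractions": fractions,
        "line_densities_km_per_km2": densities,
        "truth_lengths_km": truth,
    }
    return LandscapeBundle(polygons=polygons, lines=lines, metadata=metadata)


def _serpentine(x0: float, y0: float, w: float, h: float, target_m: float) -> list | None:
    """Vertices of a serpentine path of total length `target_m` (exact, up to
    float rounding) inside the rectangle (x0, y0, w, h); None if the target
    is not positive."""
    if target_m <= 0:
        return None
    if target_m <= h:
        xc = x0 + w / 2.0
        return [(xc, y0), (xc, y0 + target_m)]
    # Square wave with n vertical passes joined by horizontal jogs totalling
    # w; n chosen so the full wave is at least target_m, then the walk is cut
    # at exactly target_m.
    n = max(2, int(np.ceil((target_m - w) / h)))
    xs = np.linspace(x0, x0 + w, n)
    verts = []
    for i, x in enumerate(xs):
        if i % 2 == 0:
            verts.extend([(x, y0), (x, y0 + h)])
        else:
            verts.extend([(x, y0 + h), (x, y0)])
    pts = [verts[0]]
    remaining = target_m
    for (xa, ya), (xb, yb) in zip(verts, verts[1:]):
        seg = float(np.hypot(xb - xa, yb - ya))
        if seg <= 0:
            continue
        if seg >= remaining:
            f = remaining / seg
            pts.append((xa + f * (xb - xa), ya + f * (yb - ya)))
            remaining = 0.0
            break
        pts.append((xb, yb))
        remaining -= seg
    return pts


# ---------------------------------------------------------------------------
# GeoJSON round-trip
# ---------------------------------------------------------------------------


class BundleParseError(ValueError):
    """A landscape bundle file is missing, malformed, or has a bad feature."""


_POLY_FILE, _LINE_FILE, _META_FILE = "wetlands.geojson", "lines.geojson", "metadata.json"


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_bundle(bundle: LandscapeBundle, directory) -> None:
    """Serialise a bundle: wetlands.geojson (property ``peat_class``),
    lines.geojson (property ``line_type``), metadata.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    polys = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"peat_class": lab}}
        for g, lab in bundle.polygons
    ]
    lns = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"line_type": lab}}
        for g, lab in bundle.lines
    ]
    (d / _POLY_FILE).write_text(json.dumps(_feature_collection(polys)))
    (d / _LINE_FILE).write_text(json.dumps(_feature_collection(lns)))
    (d / _META_FILE).write_text(json.dumps(bundle.metadata, indent=1))


def _read_features(path: Path, prop: str, allowed: tuple[str, ...], geom_types: tuple[str, ...]):
    if not path.exists():
        raise BundleParseError(f"missing bundle file: {path}")
    try:
        fc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise BundleParseError(f"{path.name}: not valid JSON ({e})") from e
    if fc.get("type") != "FeatureCollection" or "features" not in fc:
        raise BundleParseError(f"{path.name}: not a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(fc["features"]):
        try:
            geom = shape(feat["geometry"])
        except (KeyError, TypeError, AttributeError, ValueError) as e:
            raise BundleParseError(f"{path.name} feature {i}: bad geometry ({e})") from e
        if geom.geom_type not in geom_types:
            raise BundleParseError(
                f"{path.name} feature {i}: expected {geom_types}, got {geom.geom_type}"
            )
        label = (feat.get("properties") or {}).get(prop)
        if label not in allowed:
            raise BundleParseError(
                f"{path.name} feature {i}: property {prop!r} must be one of "
                f"{allowed}, got {label!r}"
            )
        out.append((geom, label))
    return out


def read_bundle(directory) -> LandscapeBundle:
    """Parse a bundle directory written by :func:`write_bundle`; raises
    :class:`BundleParseError` naming the offending file/feature."""
    d = Path(directory)
    polygons = _read_features(d / _POLY_FILE, "peat_class", WETLAND_CLASSES, ("Polygon",))
    lines = _read_features(d / _LINE_FILE, "line_type", LINE_TYPES, ("LineString",))
    meta_path = d / _META_FILE
    metadata = {}
    if meta_path.exists():
        try:
            metadata = json.loads(meta_path.read_text())
        except json.JSONDecodeError as e:
            raise BundleParseError(f"metadata.json: not valid JSON ({e})") from e
    return LandscapeBundle(polygons=polygons, lines=lines, metadata=metadata)
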