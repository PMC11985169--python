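"""Suitability classification, habitat-change accounting and centroid tracks.

The continuous habitat suitability index (0-1) is cut into four classes
with right-closed bins: unsuitable (<= the sensitivity+specificity
threshold), generally suitable (<= 0.4), moderately suitable (<= 0.6) and
highly suitable (> 0.6).  Change between two classified maps partitions
the union of suitable cells into expansion, stability and contraction,
with percentages against an explicit, printed reference area; the headline
net change rate is increase% minus contraction%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km
from .rasters import GeometryError, RasterGeometry

UNSUITABLE, GENERAL, MODERATE, HIGH = 0, 1, 2, 3
CLASS_NAMES = {0: "unsuitable", 1: "general", 2: "moderate", 3: "high"}


@dataclass
class ClassifiedMap:
    classes: np.ndarray            # int codes 0-3, -1 for nodata
    geometry: RasterGeometry
    thresholds: tuple[float, float, float]  # (mtsps, 0.4, 0.6)
    areas_km2: dict[int, float] = field(default_factory=dict)

    def suitable_mask(self, selector: str = "suitable") -> np.ndarray:
        if selector == "suitable":
            return self.classes >= GENERAL
        if selector == "high":
            return self.classes == HIGH
        raise ValueError(selector)

    def suitable_area_km2(self, selector: str = "suitable") -> float:
        areas = self.geometry.row_cell_areas_km2()[:, None]
        return float((self.suitable_mask(selector) * areas).sum())


def classify(suitability: np.ndarray, geometry: RasterGeometry,
             mtsps: float, upper: tuple[float, float] = (0.4, 0.6)
             ) -> ClassifiedMap:
    """Cut a 0-1 suitability surface into the four classes.

    Bins are right-closed: score <= mtsps is unsuitable, <= 0.4 general,
    <= 0.6 moderate, above that high.  Nodata (NaN) maps to code -1.
    """
    if not (0.0 <= mtsps < upper[0]):
        raise ValueError(f"mtsps {mtsps} must lie in [0, {upper[0]})")
    s = np.asarray(suitability, dtype=float)
    valid = np.isfinite(s)
    if valid.any() and (np.nanmin(s) < 0 or np.nanmax(s) > 1):
        raise ValueError("suitability scores must lie in [0, 1]")
    codes = np.full(s.shape, -1, dtype=int)
    codes[valid & (s <= mtsps)] = UNSUITABLE
    codes[valid & (s > mtsps) & (s <= upper[0])] = GENERAL
    codes[valid & (s > upper[0]) & (s <= upper[1])] = MODERATE
    codes[valid & (s > upper[1])] = HIGH

    areas = geometry.row_cell_areas_km2()[:, None]
    areas_km2 = {c: float(((codes == c) * areas).sum())
                 for c in (UNSUITABLE, GENERAL, MODERATE, HIGH)}
    return ClassifiedMap(classes=codes, geometry=geometry,
                         thresholds=(mtsps, *upper), areas_km2=areas_km2)


def cell_area_km2(geometry: RasterGeometry, row: int) -> float:
    """Geodesic cell area at a grid row (spherical-quad closed form)."""
    return geometry.cell_area_km2(row)


@dataclass
class ChangeSummary:
    reference_area_km2: float
    increase_km2: float
    reserved_km2: float
    contraction_km2: float

    def _pct(self, a: float) -> float:
        return 100.0 * a / self.reference_area_km2 if self.reference_area_km2 else 0.0

    @property
    def increase_pct(self) -> float:
        return self._pct(self.increase_km2)

    @property
    def reserved_pct(self) -> float:
        return self._pct(self.reserved_km2)

    @property
    def contraction_pct(self) -> float:
        return self._pct(self.contraction_km2)

    @property
    def net_change_pct(self) -> float:
        return self.increase_pct - self.contraction_pct

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "reference_area_km2": self.reference_area_km2,
            "increase_km2": self.increase_km2,
            "reserved_km2": self.reserved_km2,
            "contraction_km2": self.contraction_km2,
            "increase_pct": round(self.increase_pct, 2),
            "reserved_pct": round(self.reserved_pct, 2),
            "contraction_pct": round(self.contraction_pct, 2),
            "net_change_pct": round(self.net_change_pct, 2),
        }])


def net_change_pct(increase_pct: float, contraction_pct: float) -> float:
    """The headline change-rate identity: increase% - contraction%."""
    return round(increase_pct - contraction_pct, 2)


def area_reduction_pct(area_a: float, area_b: float) -> float:
    """(a - b) / a * 100, rounded to 2 decimals (habitat loss rate)."""
    if area_a == 0:
        raise ValueError("reference area is zero")
    return round((area_a - area_b) / area_a * 100.0, 2)


# change-raster codes
CHANGE_NONE, CHANGE_RESERVED, CHANGE_EXPANSION, CHANGE_CONTRACTION = 0, 1, 2, 3


def change_map(baseline: ClassifiedMap, comparison: ClassifiedMap,
               reference_area_km2: float | None = None
               ) -> tuple[ChangeSummary, np.ndarray]:
    """Expansion / stability / contraction between two classified maps.

    "Suitable" means class >= generally suitable.  Percentages are taken
    against ``reference_area_km2`` (default: the baseline suitable area;
    the denominator actually used is stored on the summary).
    """
    if not baseline.geometry.approx_equal(comparison.geometry):
        raise GeometryError("classified maps are not co-registered")
    b = baseline.suitable_mask()
    c = comparison.suitable_mask()
    areas = baseline.geometry.row_cell_areas_km2()[:, None]
    increase = float((((~b) & c) * areas).sum())
    reserved = float(((b & c) * areas).sum())
    contraction = float(((b & ~c) * areas).sum())
    if reference_area_km2 is None:
        reference_area_km2 = baseline.suitable_area_km2()
    raster = np.full(b.shape, CHANGE_NONE, dtype=int)
    raster[b & c] = CHANGE_RESERVED
    raster[~b & c] = CHANGE_EXPANSION
    raster[b & ~c] = CHANGE_CONTRACTION
    return ChangeSummary(reference_area_km2=reference_area_km2,
                         increase_km2=increase, reserved_km2=reserved,
                         contraction_km2=contraction), raster


def centroid(cmap: ClassifiedMap, selector: str = "suitable"
             ) -> tuple[float, float]:
    """Area-weighted mean position (lon, lat) of selected cells."""
    mask = cmap.suitable_mask(selector)
    if not mask.any():
        raise ValueError(f"no {selector} cells to take a centroid of")
    lon, lat = cmap.geometry.cell_centers()
    w = np.broadcast_to(cmap.geometry.row_cell_areas_km2()[:, None],
                        mask.shape)[mask]
    return (float(np.average(lon[mask], weights=w)),
            float(np.average(lat[mask], weights=w)))


@dataclass
class CentroidTrack:
    periods: list[str]
    longitudes: list[float]
    latitudes: list[float]
    step_km: list[float]  # step_km[0] = 0 by convention

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period": self.periods,
                             "longitude": self.longitudes,
                             "latitude": self.latitudes,
                             "step_km": self.step_km})


def track_migration(maps: list[ClassifiedMap], selector: str = "suitable",
                    periods: list[str] | None = None) -> CentroidTrack:
    """Centroid per period plus geodesic step distances (km)."""
    if periods is None:
        periods = [f"period_{i}" for i in range(len(maps))]
    lons, lats, steps = [], [], []
    for i, m in enumerate(maps):
        lon, lat = centroid(m, selector)
        if i == 0:
            steps.append(0.0)
        else:
            steps.append(float(haversine_km(lons[-1], lats[-1], lon, lat)))
        lons.append(lon)
        lats.append(lat)
    return CentroidTrack(periods=list(periods), longitudes=lons,
                         latitudes=lats, step_km=steps)
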