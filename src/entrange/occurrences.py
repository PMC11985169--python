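"""Occurrence records and two-pass spatial thinning.

Dense herbarium/GBIF point sets inflate presence-only models; the standard
remedy is (1) keeping one record per cell of a coarse grid and (2) a second
greedy pass enforcing a minimum pairwise distance.  Both passes here are
order-dependent and keep the first-seen record, so results are reproducible
from the input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import KM_PER_DEGREE, haversine_km


@dataclass
class OccurrenceSet:
    """Georeferenced presence records (decimal degrees, WGS-84 style)."""

    records: pd.DataFrame  # columns: id, longitude, latitude
    provenance: str = ""
    n_dropped: int = 0  # rows lost to unparseable/out-of-range coordinates

    def __post_init__(self):
        req = {"id", "longitude", "latitude"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def longitude(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(dtype=float)

    @property
    def latitude(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(dtype=float)

    def to_csv(self, path, species: str = "species") -> None:
        out = pd.DataFrame({
            "species": species,
            "longitude": self.records["longitude"],
            "latitude": self.records["latitude"],
        })
        out.to_csv(path, index=False)


def from_arrays(longitude, latitude, provenance: str = "") -> OccurrenceSet:
    longitude = np.asarray(longitude, dtype=float)
    latitude = np.asarray(latitude, dtype=float)
    df = pd.DataFrame({
        "id": [str(i) for i in range(len(longitude))],
        "longitude": longitude,
        "latitude": latitude,
    })
    df = df.drop_duplicates(subset=["longitude", "latitude"], keep="first")
    return OccurrenceSet(records=df.reset_index(drop=True), provenance=provenance)


def read_occurrences(path) -> OccurrenceSet:
    """Parse an occurrence CSV with longitude/latitude columns.

    Rows with missing, unparseable, or out-of-range coordinates are dropped
    and counted in ``n_dropped``; exact duplicate coordinate pairs are
    de-duplicated keeping the first.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    cols = {c.lower().strip(): c for c in df.columns}
    lon_col = next((cols[k] for k in ("longitude", "lon", "x") if k in cols), None)
    lat_col = next((cols[k] for k in ("latitude", "lat", "y") if k in cols), None)
    if lon_col is None or lat_col is None:
        raise ValueError(f"{path}: missing longitude/latitude columns "
                         f"(found {list(df.columns)})")
    n_in = len(df)
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    out = pd.DataFrame({
        "id": df.index[ok].astype(str),
        "longitude": lon[ok].to_numpy(),
        "latitude": lat[ok].to_numpy(),
    })
    out = out.drop_duplicates(subset=["longitude", "latitude"], keep="first")
    return OccurrenceSet(records=out.reset_index(drop=True),
                         provenance=str(path),
                         n_dropped=n_in - int(ok.sum()))


def grid_thin(occ: OccurrenceSet, cell_km: float = 5.0) -> OccurrenceSet:
    """Keep at most one record per cell of a ``cell_km`` square grid.

    The grid is anchored at (-180 deg, -90 deg) and laid out in local
    equirectangular kilometres (east-west distances scaled by cos(latitude)),
    so cells are approximately square on the ground.  The first record seen
    in each cell (input order) is kept.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    lon, lat = occ.longitude, occ.latitude
    y_km = (lat + 90.0) * KM_PER_DEGREE
    x_km = (lon + 180.0) * KM_PER_DEGREE * np.cos(np.radians(lat))
    ix = np.floor(x_km / cell_km).astype(np.int64)
    iy = np.floor(y_km / cell_km).astype(np.int64)
    seen: set[tuple[int, int]] = set()
    keep = np.zeros(len(occ), dtype=bool)
    for i, key in enumerate(zip(ix, iy)):
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return OccurrenceSet(records=occ.records[keep].reset_index(drop=True),
                         provenance=occ.provenance, n_dropped=occ.n_dropped)


def distance_thin(occ: OccurrenceSet, buffer_km: float = 5.0) -> OccurrenceSet:
    """Greedy minimum-distance pass: keep a record iff its great-circle
    distance to every previously kept record exceeds ``buffer_km``."""
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    lon, lat = occ.longitude, occ.latitude
    kept_idx: list[int] = []
    for i in range(len(occ)):
        if kept_idx:
            d = haversine_km(lon[kept_idx], lat[kept_idx], lon[i], lat[i])
            if np.min(d) <= buffer_km:
                continue
        kept_idx.append(i)
    return OccurrenceSet(records=occ.records.iloc[kept_idx].reset_index(drop=True),
                         provenance=occ.provenance, n_dropped=occ.n_dropped)


def thin(occ: OccurrenceSet, cell_km: float = 5.0,
         buffer_km: float = 5.0) -> OccurrenceSet:
    """Grid pass then distance pass — the full screening pipeline."""
    return distance_thin(grid_thin(occ, cell_km), buffer_km)
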