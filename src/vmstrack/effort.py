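"""Spatial fishing-pressure aggregation and DCF indicators.

Fishing set positions are counted per cell of a spatial partition (a
regular lon/lat graticule or arbitrary polygons); counts convert to
effort hours through the interpolation interval.  DCF pressure
indicator 5 (distribution of fishing activities) is the total area of
cells receiving any effort; indicator 6 (aggregation) is the total area
of the top-effort cells jointly accounting for 90% of the effort.
Trawled area is trajectory length times the overall gear width (OWG).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geo import EARTH_RADIUS_KM, haversine_km


@dataclass(frozen=True)
class RegularGridSpec:
    """Graticule partition: cells of ``cell_deg`` degrees covering the extent.

    Cell ids are row-major integers from the lower-left (south-west) corner.
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cell_deg: float

    @property
    def ncols(self) -> int:
        return int(np.ceil((self.lon_max - self.lon_min) / self.cell_deg - 1e-9))

    @property
    def nrows(self) -> int:
        return int(np.ceil((self.lat_max - self.lat_min) / self.cell_deg - 1e-9))

    def cell_bounds(self, cid: int) -> tuple[float, float, float, float]:
        r, c = divmod(cid, self.ncols)
        lon0 = self.lon_min + c * self.cell_deg
        lat0 = self.lat_min + r * self.cell_deg
        return lon0, lat0, lon0 + self.cell_deg, lat0 + self.cell_deg


def graticule_cell_area_km2(lon0, lat0, lon1, lat1) -> float:
    """Area of a lon/lat graticule cell on the sphere:
    R^2 * dlambda * |sin(lat1) - sin(lat0)|."""
    dlam = np.radians(abs(lon1 - lon0))
    return float(EARTH_RADIUS_KM ** 2 * dlam *
                 abs(np.sin(np.radians(lat1)) - np.sin(np.radians(lat0))))


@dataclass
class EffortGrid:
    """Polygon cells with per-cell fishing-ping counts, effort hours and area."""

    cell_ids: list
    polygons: list
    counts: np.ndarray
    areas_km2: np.ndarray
    interval_h: float
    outside_count: int = 0

    @property
    def hours(self) -> np.ndarray:
        return self.counts * self.interval_h

    @property
    def total_effort_h(self) -> float:
        return float(self.hours.sum())


def _cells_from_spec(spec: RegularGridSpec):
    ids = list(range(spec.nrows * spec.ncols))
    polys = []
    areas = []
    for cid in ids:
        lon0, lat0, lon1, lat1 = spec.cell_bounds(cid)
        polys.append(shapely.box(lon0, lat0, lon1, lat1))
        areas.append(graticule_cell_area_km2(lon0, lat0, lon1, lat1))
    return ids, polys, np.array(areas)


def grid_effort(pings, cells, interval_min: float = 10.0) -> EffortGrid:
    """Count fishing pings per cell; effort hours = count x interval.

    ``cells`` is a :class:`RegularGridSpec` or a list of (id, polygon)
    pairs.  A ping on a shared boundary goes to the cell with the lowest
    id.  Counts conserve: sum(cell counts) + outside = number of fishing
    pings.
    """
    fishing = [p for p in pings if p.is_fishing]
    interval_h = interval_min / 60.0

    if isinstance(cells, RegularGridSpec):
        spec = cells
        ids, polys, areas = _cells_from_spec(spec)
        counts = np.zeros(len(ids))
        outside = 0
        for p in fishing:
            x = (p.lon - spec.lon_min) / spec.cell_deg
            y = (p.lat - spec.lat_min) / spec.cell_deg
            c = int(np.floor(x))
            r = int(np.floor(y))
            # boundary pings belong to the lower-id (south/west) cell
            if c > 0 and x == c:
                c -= 1
            if r > 0 and y == r:
                r -= 1
            if 0 <= c < spec.ncols and 0 <= r < spec.nrows:
                counts[r * spec.ncols + c] += 1
            else:
                outside += 1
        return EffortGrid(cell_ids=ids, polygons=polys, counts=counts,
                          areas_km2=areas, interval_h=interval_h,
                          outside_count=outside)

    items = sorted(cells, key=lambda t: str(t[0]))
    ids = [i for i, _ in items]
    polys = [pg for _, pg in items]
    for i, pg in zip(ids, polys):
        if not pg.is_valid or pg.is_empty:
            raise ValueError(f"degenerate cell polygon {i!r}")
    areas = np.array([_polygon_area_km2(pg) for pg in polys])
    counts = np.zeros(len(ids))
    outside = 0
    for p in fishing:
        pt = shapely.Point(p.lon, p.lat)
        for j, pg in enumerate(polys):  # id order: first hit = lowest id
            if pg.covers(pt):
                counts[j] += 1
                break
        else:
            outside += 1
    return EffortGrid(cell_ids=ids, polygons=polys, counts=counts,
                      areas_km2=areas, interval_h=interval_h,
                      outside_count=outside)


def _polygon_area_km2(poly) -> float:
    """Planar polygon area scaled to km^2 at the polygon's mean latitude."""
    lat = poly.centroid.y
    kx = np.pi * EARTH_RADIUS_KM / 180.0 * np.cos(np.radians(lat))
    ky = np.pi * EARTH_RADIUS_KM / 180.0
    return float(poly.area * kx * ky)


def dcf_indicator5(grid: EffortGrid) -> float:
    """Distribution of fishing activities: total area (km^2) of cells with
    any fishing effort."""
    return float(grid.areas_km2[grid.counts > 0].sum())


def dcf_indicator6(grid: EffortGrid, q: float = 0.9) -> float:
    """Aggregation of fishing activities: total area (km^2) of the
    top-effort cells jointly scoring ``q`` (default 90%) of total effort.

    Cells are taken in descending effort order (ties by cell id) until the
    cumulative effort first reaches q x total; the crossing cell is
    included.
    """
    hours = grid.hours
    total = hours.sum()
    if total <= 0:
        raise ValueError("indicator 6 undefined with zero total effort")
    order = sorted(range(len(hours)), key=lambda i: (-hours[i], str(grid.cell_ids[i])))
    target = q * total
    cum = 0.0
    area = 0.0
    for i in order:
        if hours[i] <= 0:
            break
        cum += hours[i]
        area += grid.areas_km2[i]
        if cum >= target - 1e-12:
            break
    return float(area)


@dataclass
class GearSpec:
    """Overall gear width for a vessel: a constant or a function of depth (m) -> km."""

    vessel_id: str
    owg: object  # float km, or callable(mean_abs_depth_m) -> km

    def width_km(self, depth_m: float | None) -> float:
        w = self.owg(depth_m) if callable(self.owg) else float(self.owg)
        if not w > 0:
            raise ValueError(f"OWG must be positive (vessel {self.vessel_id})")
        return w


def trawled_area(track, gear: GearSpec) -> float:
    """Swept surface of one track in km^2: sum over consecutive fishing-ping
    segments of great-circle length x OWG at the segment's mean depth."""
    area = 0.0
    pings = track.pings
    for a, b in zip(pings, pings[1:]):
        if not (a.is_fishing and b.is_fishing):
            continue
        length = float(haversine_km(a.lon, a.lat, b.lon, b.lat))
        depths = [abs(d) for d in (a.depth, b.depth) if d is not None]
        mean_depth = float(np.mean(depths)) if depths else None
        area += length * gear.width_km(mean_depth)
    return area


def export_csv(grid: EffortGrid, path) -> None:
    """Write cell id, count, effort hours, area and WKT geometry to CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "count", "effort_hours", "area_km2", "wkt"])
        for cid, cnt, hrs, area, poly in zip(grid.cell_ids, grid.counts,
                                             grid.hours, grid.areas_km2, grid.polygons):
            w.writerow([cid, int(cnt), f"{hrs:.9f}", f"{area:.9f}", poly.wkt])


def import_csv(path, interval_min: float = 10.0) -> EffortGrid:
    import shapely.wkt
    ids, polys, counts, areas = [], [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ids.append(row["cell_id"])
            counts.append(float(row["count"]))
            areas.append(float(row["area_km2"]))
            polys.append(shapely.wkt.loads(row["wkt"]))
    return EffortGrid(cell_ids=ids, polygons=polys, counts=np.array(counts),
                      areas_km2=np.array(areas), interval_h=interval_min / 60.0)
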