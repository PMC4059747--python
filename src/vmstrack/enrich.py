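"""Environmental enrichment: sea-bottom depth and management-area assignment.

Depth comes from a local regular lon/lat elevation grid (ESRI ASCII text
or lon,lat,z triples) sampled bilinearly at each ping.  Tracks are
assigned to named management polygons (e.g. GSA rectangles) by the
polygon containing the track's focal point — the mean coordinates of its
native pings.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import shapely.wkt
from scipy.interpolate import RegularGridInterpolator


@dataclass
class BathyGrid:
    """Regular lon/lat elevation grid; z[i, j] is metres at (lat[i], lon[j]),
    negative below sea level."""

    lon: np.ndarray
    lat: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("grid axes must be strictly ascending")
        if self.z.shape != (len(self.lat), len(self.lon)):
            raise ValueError("elevation matrix shape does not match axes")
        self._interp = RegularGridInterpolator(
            (self.lat, self.lon), self.z, method="linear",
            bounds_error=False, fill_value=np.nan)

    def sample(self, lon, lat) -> np.ndarray:
        """Bilinear elevation at points (vectorised); NaN outside the grid."""
        pts = np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)])
        return self._interp(pts)

    @classmethod
    def from_xyz(cls, path) -> "BathyGrid":
        """Load from delimited lon,lat,z triples covering a full regular grid."""
        data = np.loadtxt(path, delimiter=",")
        lon = np.unique(data[:, 0])
        lat = np.unique(data[:, 1])
        z = np.full((len(lat), len(lon)), np.nan)
        ilat = np.searchsorted(lat, data[:, 1])
        ilon = np.searchsorted(lon, data[:, 0])
        z[ilat, ilon] = data[:, 2]
        if np.isnan(z).any():
            raise ValueError("xyz triples do not cover a complete regular grid")
        return cls(lon=lon, lat=lat, z=z)

    @classmethod
    def from_ascii_grid(cls, path) -> "BathyGrid":
        """Load an ESRI ASCII raster (ncols/nrows/xllcorner/yllcorner/cellsize)."""
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"]
        z = np.array(rows)
        if z.shape != (nrows, ncols):
            raise ValueError("ASCII grid body does not match header dimensions")
        nodata = header.get("nodata_value")
        if nodata is not None:
            z[z == nodata] = np.nan
        # node registration at cell centres; file rows run north -> south
        lon = x0 + cell * (np.arange(ncols) + 0.5)
        lat = y0 + cell * (np.arange(nrows) + 0.5)
        return cls(lon=lon, lat=lat, z=z[::-1, :])

    def to_ascii_grid(self, path) -> None:
        cell = float(self.lon[1] - self.lon[0])
        lines = [f"ncols {len(self.lon)}", f"nrows {len(self.lat)}",
                 f"xllcorner {self.lon[0] - cell / 2}",
                 f"yllcorner {self.lat[0] - cell / 2}",
                 f"cellsize {cell}", "NODATA_value -9999"]
        body = np.where(np.isnan(self.z[::-1, :]), -9999.0, self.z[::-1, :])
        for row in body:
            lines.append(" ".join(f"{v:g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class AreaLayer:
    """Named management polygons (unique ids, valid geometry)."""

    areas: list[tuple[str, object]]  # (id, shapely polygon)

    def __post_init__(self):
        ids = [a for a, _ in self.areas]
        if len(set(ids)) != len(ids):
            raise ValueError("area ids must be unique")
        for i, (aid, poly) in enumerate(self.areas):
            if not poly.is_valid:
                raise ValueError(f"invalid polygon geometry for area {aid!r}")

    @classmethod
    def from_csv(cls, path) -> "AreaLayer":
        """Load from a CSV with columns id, wkt."""
        areas = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                areas.append((row["id"], shapely.wkt.loads(row["wkt"])))
        return cls(areas=areas)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "wkt"])
            for aid, poly in self.areas:
                w.writerow([aid, poly.wkt])


def assign_depth(pings, grid: BathyGrid) -> int:
    """Set ping depth by bilinear interpolation; returns the number of pings
    outside the grid (depth left unset)."""
    if not pings:
        return 0
    lon = np.array([p.lon for p in pings])
    lat = np.array([p.lat for p in pings])
    z = grid.sample(lon, lat)
    outside = 0
    for p, v in zip(pings, z):
        if np.isnan(v):
            p.depth = None
            outside += 1
        else:
            p.depth = float(v)
    return outside


def assign_area(tracks, layer: AreaLayer) -> int:
    """Assign each track the id of the polygon containing its focal point.

    Overlapping polygons: first containing polygon in id order wins, with a
    warning.  Returns the number of unassigned tracks.
    """
    ordered = sorted(layer.areas, key=lambda t: t[0])
    unassigned = 0
    for tr in tracks:
        lon, lat = tr.focal_point
        pt = shapely.Point(lon, lat)
        hits = [aid for aid, poly in ordered if poly.covers(pt)]
        if not hits:
            tr.area_id = None
            unassigned += 1
        else:
            if len(hits) > 1:
                warnings.warn(f"focal point of track {tr.track_id} falls in "
                              f"overlapping areas {hits}; using {hits[0]}")
            tr.area_id = hits[0]
    return unassigned
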