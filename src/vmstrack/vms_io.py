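"""Reading, validating and persisting VMS pings and logbook records.

Input files are delimited text in a configurable dialect (column names,
separator, datetime format, decimal or DMS coordinates); TACSAT2 and
EFLALO column presets are provided for interoperability.  Parsing is
total: every input row either yields a record or is counted in a
categorised rejection report.  The canonical store is a single-file
SQLite database with a schema-version row.
"""

from __future__ import annotations

import json
import math
import re
import sqlite3
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import WarningCode

SCHEMA_VERSION = "1"

_SEP_NAMES = {",": "comma", ";": "semicolon", "\t": "tab"}
_SEP_FROM_NAME = {v: k for k, v in _SEP_NAMES.items()}


@dataclass
class VmsPing:
    """One positional report from a vessel's blue box."""

    vessel_id: str
    timestamp: datetime  # UTC, second precision
    lon: float  # decimal degrees WGS84
    lat: float
    speed: float  # knots, as received
    heading: float  # degrees, [0, 360) when valid
    flags: set = field(default_factory=set)
    source: str = "native"  # or "interpolated"
    track_id: int | None = None
    harbour_id: str | None = None
    depth: float | None = None  # metres, negative below sea level
    metier: str | None = None
    is_fishing: bool | None = None

    def copy(self) -> "VmsPing":
        return replace(self, flags=set(self.flags))


@dataclass
class LogbookRecord:
    """One fishing trip's catch composition over FAO 3-alpha species codes."""

    vessel_id: str
    departure: datetime
    arrival: datetime
    catches: dict[str, float]  # species code -> kg
    gear: str | None = None
    metier: str | None = None

    @property
    def duration_days(self) -> float:
        return (self.arrival - self.departure).total_seconds() / 86400.0


@dataclass
class LoaderConfig:
    """Dialect description for a delimited VMS or logbook text file."""

    column_map: dict[str, str]
    sep: str = ","
    datetime_format: str | None = None
    coord_format: str = "decimal"  # or "dms"
    dialect: str = "custom"

    VMS_MANDATORY = ("vessel_id", "timestamp", "lon", "lat", "speed", "heading")
    LOGBOOK_MANDATORY = ("vessel_id", "departure", "arrival", "species", "quantity")

    @classmethod
    def preset(cls, name: str) -> "LoaderConfig":
        """TACSAT2 / EFLALO presets: pure column-name mappings."""
        if name.upper() == "TACSAT2":
            return cls(
                column_map={"vessel_id": "VE_REF", "timestamp": "SI_DATE SI_TIME",
                            "lon": "SI_LONG", "lat": "SI_LATI",
                            "speed": "SI_SP", "heading": "SI_HE"},
                sep=",", datetime_format="%d/%m/%Y %H:%M", dialect="TACSAT2")
        if name.upper() == "EFLALO":
            return cls(
                column_map={"vessel_id": "VE_REF", "departure": "FT_DDATIM",
                            "arrival": "FT_LDATIM", "species": "LE_SPE",
                            "quantity": "LE_KG", "gear": "LE_GEAR"},
                sep=",", datetime_format="%d/%m/%Y %H:%M", dialect="EFLALO")
        raise ValueError(f"unknown dialect preset: {name}")


class ConfigError(ValueError):
    pass


@dataclass
class ParseReport:
    """Per-category tally of malformed rows, reconciling with rows seen."""

    rows_in: int = 0
    emitted: int = 0
    rejected: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    def bump(self, category: str, n: int = 1) -> None:
        self.counts[category] = self.counts.get(category, 0) + n

    def summary(self) -> str:
        lines = [f"{v} {k}" for k, v in sorted(self.counts.items())]
        lines.append(f"{self.rows_in} rows in, {self.emitted} emitted, {self.rejected} rejected")
        return "; ".join(lines)


_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°dD]\s*(\d+)\s*[′'mM]\s*([\d.]+)\s*[″"sS]?\s*([NSEWnsew])\s*$"""
)


def parse_dms(text: str) -> float:
    """Degrees-minutes-seconds with hemisphere letter -> signed decimal degrees."""
    m = _DMS_RE.match(str(text))
    if not m:
        return math.nan
    deg, minute, sec, hemi = m.groups()
    value = float(deg) + float(minute) / 60.0 + float(sec) / 3600.0
    if hemi.upper() in ("S", "W"):
        value = -value
    return value


def _require(config: LoaderConfig, fields: tuple[str, ...]) -> None:
    missing = [f for f in fields if f not in config.column_map]
    if missing:
        raise ConfigError(f"unmapped mandatory columns: {', '.join(missing)}")


def _read_table(path, config: LoaderConfig) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=config.sep, dtype=str, keep_default_na=False,
                           na_values=[""], engine="python")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _column(df: pd.DataFrame, name: str) -> pd.Series:
    """Resolve a mapped column name; a space-separated name concatenates columns."""
    parts = name.split(" ")
    for part in parts:
        if part not in df.columns:
            raise ConfigError(f"column '{part}' not present in input file")
    if len(parts) == 1:
        return df[parts[0]]
    out = df[parts[0]].astype(str)
    for part in parts[1:]:
        out = out + " " + df[part].astype(str)
    return out


def _parse_times(series: pd.Series, fmt: str | None) -> pd.Series:
    return pd.to_datetime(series, format=fmt, errors="coerce", utc=True)


def read_vms(path, config: LoaderConfig) -> tuple[list[VmsPing], ParseReport]:
    """Parse a delimited VMS file into pings plus a categorised parse report.

    Rows whose timestamp or coordinates cannot be parsed are rejected and
    counted; out-of-range coordinates are emitted with an OUT_OF_RANGE flag.
    Input order is preserved.
    """
    _require(config, LoaderConfig.VMS_MANDATORY)
    df = _read_table(path, config)
    report = ParseReport(rows_in=len(df))
    if df.empty:
        return [], report

    cm = config.column_map
    ts = _parse_times(_column(df, cm["timestamp"]), config.datetime_format)
    if config.coord_format == "dms":
        lon = _column(df, cm["lon"]).map(parse_dms)
        lat = _column(df, cm["lat"]).map(parse_dms)
    else:
        lon = pd.to_numeric(_column(df, cm["lon"]), errors="coerce")
        lat = pd.to_numeric(_column(df, cm["lat"]), errors="coerce")
    speed = pd.to_numeric(_column(df, cm["speed"]), errors="coerce")
    heading = pd.to_numeric(_column(df, cm["heading"]), errors="coerce")
    vessel = _column(df, cm["vessel_id"]).astype(str)

    pings: list[VmsPing] = []
    for i in range(len(df)):
        if pd.isna(ts.iloc[i]):
            report.bump("bad or missing dates")
            report.rejected += 1
            continue
        lo, la = lon.iloc[i], lat.iloc[i]
        if pd.isna(lo) or pd.isna(la):
            report.bump("unparseable coordinates")
            report.rejected += 1
            continue
        flags = set()
        if not (-90.0 <= la <= 90.0):
            flags.add(WarningCode.OUT_OF_RANGE)
            report.bump("latitudes out of range (-90/90)")
        if not (-180.0 <= lo <= 180.0):
            flags.add(WarningCode.OUT_OF_RANGE)
            report.bump("longitudes out of range (-180/180)")
        sp, hd = speed.iloc[i], heading.iloc[i]
        if pd.isna(sp):
            report.bump("NAs found in knots speed")
            sp = math.nan
        if pd.isna(hd):
            report.bump("NAs found in degrees heading")
            hd = math.nan
        pings.append(VmsPing(vessel_id=vessel.iloc[i],
                             timestamp=ts.iloc[i].to_pydatetime(),
                             lon=float(lo), lat=float(la),
                             speed=float(sp), heading=float(hd), flags=flags))
        report.emitted += 1
    return pings, report


_SPECIES_RE = re.compile(r"^[A-Z]{3}$")


def read_logbook(path, config: LoaderConfig) -> tuple[list[LogbookRecord], ParseReport]:
    """Parse long-form logbook rows and pivot them to one record per trip.

    A trip is keyed by (vessel, departure, arrival); repeated species rows
    within a trip are summed.  Rows with unparseable or inverted time limits
    or non-3-alpha species codes are rejected and counted.
    """
    _require(config, LoaderConfig.LOGBOOK_MANDATORY)
    df = _read_table(path, config)
    report = ParseReport(rows_in=len(df))
    if df.empty:
        return [], report

    cm = config.column_map
    dep = _parse_times(_column(df, cm["departure"]), config.datetime_format)
    arr = _parse_times(_column(df, cm["arrival"]), config.datetime_format)
    vessel = _column(df, cm["vessel_id"]).astype(str)
    species = _column(df, cm["species"]).astype(str).str.strip().str.upper()
    qty = pd.to_numeric(_column(df, cm["quantity"]), errors="coerce")
    gear = _column(df, cm["gear"]).astype(str) if "gear" in cm and cm["gear"] in df.columns else None
    metier = _column(df, cm["metier"]).astype(str) if "metier" in cm and cm["metier"] in df.columns else None

    trips: dict[tuple, LogbookRecord] = {}
    rows_per_trip: dict[tuple, int] = {}
    order: list[tuple] = []
    for i in range(len(df)):
        if pd.isna(dep.iloc[i]) or pd.isna(arr.iloc[i]):
            report.bump("missing start/end times")
            report.rejected += 1
            continue
        d, a = dep.iloc[i].to_pydatetime(), arr.iloc[i].to_pydatetime()
        if a <= d:
            report.bump("arrival not after departure")
            report.rejected += 1
            continue
        sp = species.iloc[i]
        if not _SPECIES_RE.match(sp):
            report.bump("invalid species codes")
            report.rejected += 1
            continue
        q = qty.iloc[i]
        if pd.isna(q) or q < 0:
            report.bump("bad catch quantities")
            report.rejected += 1
            continue
        key = (vessel.iloc[i], d, a)
        if key not in trips:
            trips[key] = LogbookRecord(vessel_id=key[0], departure=d, arrival=a, catches={},
                                       gear=gear.iloc[i] if gear is not None else None,
                                       metier=metier.iloc[i] if metier is not None else None)
            order.append(key)
        trips[key].catches[sp] = trips[key].catches.get(sp, 0.0) + float(q)
        rows_per_trip[key] = rows_per_trip.get(key, 0) + 1

    records = []
    for key in order:
        rec = trips[key]
        if not any(v > 0 for v in rec.catches.values()):
            report.bump("trips with no positive catch")
            report.rejected += rows_per_trip[key]
            continue
        records.append(rec)
        report.emitted += rows_per_trip[key]
    return records, report


# ---------------------------------------------------------------------------
# loader-config persistence (flat key=value text)

def save_config(config: LoaderConfig, path) -> None:
    lines = [
        f"dialect={config.dialect}",
        f"sep={_SEP_NAMES.get(config.sep, config.sep)}",
        f"datetime_format={config.datetime_format or ''}",
        f"coord_format={config.coord_format}",
    ]
    for k, v in config.column_map.items():
        lines.append(f"map.{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> LoaderConfig:
    column_map: dict[str, str] = {}
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        if k.startswith("map."):
            column_map[k[4:]] = v
        else:
            kv[k] = v
    return LoaderConfig(
        column_map=column_map,
        sep=_SEP_FROM_NAME.get(kv.get("sep", "comma"), kv.get("sep", ",")),
        datetime_format=kv.get("datetime_format") or None,
        coord_format=kv.get("coord_format", "decimal"),
        dialect=kv.get("dialect", "custom"),
    )


# ---------------------------------------------------------------------------
# SQLite store

_PING_COLS = ("vessel_id", "timestamp", "lon", "lat", "speed", "heading", "flags",
              "source", "track_id", "harbour_id", "depth", "metier", "is_fishing")


def _connect(path) -> sqlite3.Connection:
    con = sqlite3.connect(str(path))
    con.execute("CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)")
    return con


def _check_version(con: sqlite3.Connection) -> None:
    row = con.execute("SELECT value FROM meta WHERE key='schema_version'").fetchone()
    if row is None:
        raise ValueError("store has no schema_version row")
    if row[0] != SCHEMA_VERSION:
        raise ValueError(f"store schema version {row[0]} != supported version {SCHEMA_VERSION}")


def _f(x):
    """float-or-None for SQLite (NaN stored as NULL)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def save_pings(pings, path) -> None:
    con = _connect(path)
    with con:
        con.execute("INSERT OR REPLACE INTO meta VALUES ('schema_version', ?)", (SCHEMA_VERSION,))
        con.execute("DROP TABLE IF EXISTS pings")
        con.execute(f"""CREATE TABLE pings (idx INTEGER PRIMARY KEY,
            vessel_id TEXT, timestamp TEXT, lon REAL, lat REAL, speed REAL,
            heading REAL, flags TEXT, source TEXT, track_id INTEGER,
            harbour_id TEXT, depth REAL, metier TEXT, is_fishing INTEGER)""")
        rows = []
        for i, p in enumerate(pings):
            rows.append((i, p.vessel_id, p.timestamp.isoformat(),
                         p.lon, p.lat, _f(p.speed), _f(p.heading),
                         ",".join(sorted(c.value for c in p.flags)), p.source,
                         p.track_id, p.harbour_id, _f(p.depth), p.metier,
                         None if p.is_fishing is None else int(p.is_fishing)))
        con.executemany(f"INSERT INTO pings VALUES ({','.join('?' * 14)})", rows)
    con.close()


def load_pings(path, vessel_id: str | None = None) -> list[VmsPing]:
    con = _connect(path)
    _check_version(con)
    q = f"SELECT {','.join(_PING_COLS)} FROM pings"
    args: tuple = ()
    if vessel_id is not None:
        q += " WHERE vessel_id = ?"
        args = (vessel_id,)
    q += " ORDER BY idx"
    out = []
    for row in con.execute(q, args):
        (vid, ts, lon, lat, speed, heading, flags, source, track_id,
         harbour_id, depth, metier, is_fishing) = row
        out.append(VmsPing(
            vessel_id=vid, timestamp=datetime.fromisoformat(ts),
            lon=lon, lat=lat,
            speed=math.nan if speed is None else speed,
            heading=math.nan if heading is None else heading,
            flags={WarningCode(c) for c in flags.split(",") if c},
            source=source, track_id=track_id, harbour_id=harbour_id,
            depth=depth, metier=metier,
            is_fishing=None if is_fishing is None else bool(is_fishing)))
    con.close()
    return out


def save_logbook(records, path) -> None:
    con = _connect(path)
    with con:
        con.execute("INSERT OR REPLACE INTO meta VALUES ('schema_version', ?)", (SCHEMA_VERSION,))
        con.execute("DROP TABLE IF EXISTS logbook")
        con.execute("""CREATE TABLE logbook (idx INTEGER PRIMARY KEY,
            vessel_id TEXT, departure TEXT, arrival TEXT, catches TEXT,
            gear TEXT, metier TEXT)""")
        rows = [(i, r.vessel_id, r.departure.isoformat(), r.arrival.isoformat(),
                 json.dumps(r.catches, sort_keys=True), r.gear, r.metier)
                for i, r in enumerate(records)]
        con.executemany("INSERT INTO logbook VALUES (?,?,?,?,?,?,?)", rows)
    con.close()


def load_logbook(path, vessel_id: str | None = None) -> list[LogbookRecord]:
    con = _connect(path)
    _check_version(con)
    q = "SELECT vessel_id, departure, arrival, catches, gear, metier FROM logbook"
    args: tuple = ()
    if vessel_id is not None:
        q += " WHERE vessel_id = ?"
        args = (vessel_id,)
    q += " ORDER BY idx"
    out = [LogbookRecord(vessel_id=v, departure=datetime.fromisoformat(d),
                         arrival=datetime.fromisoformat(a), catches=json.loads(c),
                         gear=g, metier=m)
           for v, d, a, c, g, m in con.execute(q, args)]
    con.close()
    return out


def store_save(collection, path) -> None:
    """Persist a ping or logbook collection (dispatch on element type)."""
    items = list(collection)
    if items and isinstance(items[0], LogbookRecord):
        save_logbook(items, path)
    else:
        save_pings(items, path)


def store_load(path, kind: str = "pings", vessel_id: str | None = None):
    if kind == "pings":
        return load_pings(path, vessel_id)
    if kind == "logbook":
        return load_logbook(path, vessel_id)
    raise ValueError(f"unknown collection kind: {kind}")


def utc(year, month, day, hour=0, minute=0, second=0) -> datetime:
    """Convenience constructor for tz-aware UTC datetimes."""
    return datetime(year, month, day, hour, minute, second, tzinfo=timezone.utc)
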