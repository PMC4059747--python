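"""Quality flagging of VMS pings.

Erroneous pings (duplicates, on-land positions, impossible speeds or
headings, physically incoherent jumps) are *flagged*, never silently
deleted; a retention policy then decides what to drop.  In-harbour pings
are flagged with the identity of the nearest harbour inside a 2 km buffer
(customisable) because trip cutting needs them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely

from .geo import KNOT_KMH, haversine_km


class WarningCode(enum.Enum):
    """Stable identifiers for ping irregularities, persisted in the store."""

    DUPLICATE = "DUPLICATE"
    ON_LAND = "ON_LAND"
    BAD_SPEED = "BAD_SPEED"
    BAD_HEADING = "BAD_HEADING"
    IN_HARBOUR = "IN_HARBOUR"
    NOT_COHERENT = "NOT_COHERENT"
    OUT_OF_RANGE = "OUT_OF_RANGE"


@dataclass(frozen=True)
class Harbour:
    id: str
    name: str
    lon: float
    lat: float


def load_harbours(path) -> list[Harbour]:
    """Read a harbour point layer from CSV columns id,name,lon,lat."""
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Harbour(id=row["id"], name=row.get("name", row["id"]),
                               lon=float(row["lon"]), lat=float(row["lat"])))
    if len({h.id for h in out}) != len(out):
        raise ValueError("harbour ids must be unique")
    return out


#: default retention policy: drop what cannot be placed or trusted positionally,
#: keep in-harbour pings (trip cutting needs them) and speed/heading oddities
#: (position is still usable).
DEFAULT_POLICY: dict[WarningCode, str] = {
    WarningCode.DUPLICATE: "drop",
    WarningCode.ON_LAND: "drop",
    WarningCode.NOT_COHERENT: "drop",
    WarningCode.OUT_OF_RANGE: "drop",
    WarningCode.BAD_SPEED: "keep",
    WarningCode.BAD_HEADING: "keep",
    WarningCode.IN_HARBOUR: "keep",
}

DEFAULT_MAX_SPEED_KN = 25.0
DEFAULT_COHERENCE_CEILING_KN = 30.0
DEFAULT_HARBOUR_RADIUS_KM = 2.0


def flag_duplicates(pings: Sequence) -> int:
    """Set DUPLICATE on all but the first ping of each (vessel, timestamp) group.

    Returns the number of pings flagged.  Idempotent.
    """
    seen: set[tuple[str, object]] = set()
    n = 0
    for p in pings:
        key = (p.vessel_id, p.timestamp)
        if key in seen:
            if WarningCode.DUPLICATE not in p.flags:
                p.flags.add(WarningCode.DUPLICATE)
            n += 1
        else:
            seen.add(key)
    return n


def flag_on_land(pings: Sequence, coastline: Iterable) -> int:
    """Set ON_LAND on pings strictly inside any land polygon.

    Boundary points are not flagged.  Raises ``ValueError`` naming the index
    of any invalid polygon.
    """
    polys = list(coastline)
    for i, poly in enumerate(polys):
        if not poly.is_valid:
            raise ValueError(f"invalid polygon geometry at index {i}")
    if not pings:
        return 0
    lon = np.array([p.lon for p in pings])
    lat = np.array([p.lat for p in pings])
    inside = np.zeros(len(pings), dtype=bool)
    for poly in polys:
        # contains_xy is strict interior containment: boundary excluded
        inside |= shapely.contains_xy(poly, lon, lat)
    n = 0
    for p, hit in zip(pings, inside):
        if hit:
            p.flags.add(WarningCode.ON_LAND)
            n += 1
    return int(inside.sum())


def flag_speed_heading(pings: Sequence, max_speed: float = DEFAULT_MAX_SPEED_KN) -> tuple[int, int]:
    """Set BAD_SPEED (speed < 0, > max_speed, or not finite) and BAD_HEADING
    (heading outside the half-open compass range [0, 360)).

    ``max_speed`` itself is a valid speed (inclusive bound).
    Returns (n_bad_speed, n_bad_heading).
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be positive")
    ns = nh = 0
    for p in pings:
        if not np.isfinite(p.speed) or p.speed < 0 or p.speed > max_speed:
            p.flags.add(WarningCode.BAD_SPEED)
            ns += 1
        if not np.isfinite(p.heading) or not (0.0 <= p.heading < 360.0):
            p.flags.add(WarningCode.BAD_HEADING)
            nh += 1
    return ns, nh


def flag_not_coherent(pings: Sequence, ceiling_kn: float = DEFAULT_COHERENCE_CEILING_KN) -> int:
    """Set NOT_COHERENT where the implied great-circle speed from the previous
    retained ping of the same vessel exceeds ``ceiling_kn``.

    A ping exactly at the ceiling is coherent.  Pings already flagged
    DUPLICATE, and pings flagged NOT_COHERENT, never serve as the reference
    "previous" ping; this op is documented to run after duplicate flagging.
    """
    n = 0
    prev: dict[str, object] = {}
    for p in pings:
        if WarningCode.DUPLICATE in p.flags:
            continue
        q = prev.get(p.vessel_id)
        if q is not None:
            dt_h = (p.timestamp - q.timestamp).total_seconds() / 3600.0
            if dt_h > 0:
                implied_kn = haversine_km(q.lon, q.lat, p.lon, p.lat) / dt_h / KNOT_KMH
                # inclusive boundary, robust to round-trip rounding
                if implied_kn > ceiling_kn * (1.0 + 1e-9):
                    p.flags.add(WarningCode.NOT_COHERENT)
                    n += 1
                    continue  # do not use as reference
        prev[p.vessel_id] = p
    return n


def flag_in_harbour(pings: Sequence, harbours: Sequence[Harbour],
                    radius_km: float = DEFAULT_HARBOUR_RADIUS_KM) -> int:
    """Set IN_HARBOUR (+ harbour_id of the nearest harbour) on pings within
    ``radius_km`` (inclusive) of any harbour.

    Distance ties are broken lexicographically by harbour id.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    hs = sorted(harbours, key=lambda h: h.id)
    if not hs:
        raise ValueError("harbour list is empty")
    if not pings:
        return 0
    hlon = np.array([h.lon for h in hs])
    hlat = np.array([h.lat for h in hs])
    n = 0
    for p in pings:
        d = haversine_km(p.lon, p.lat, hlon, hlat)
        j = int(np.argmin(d))  # first minimum -> lexicographically smallest id
        if d[j] <= radius_km:
            p.flags.add(WarningCode.IN_HARBOUR)
            p.harbour_id = hs[j].id
            n += 1
    return n


def apply_policy(pings: Sequence, policy: dict[WarningCode, str] | None = None):
    """Filter pings according to a per-code keep/drop policy.

    A ping carrying *any* dropped code is dropped (OR semantics).  Returns
    ``(kept_pings, counts)`` where counts maps each code to the number of
    dropped pings carrying it.  Raises if a code present in the data is not
    covered by the policy.
    """
    if policy is None:
        policy = DEFAULT_POLICY
    counts: dict[WarningCode, int] = {}
    kept = []
    for p in pings:
        drop = False
        for code in p.flags:
            if code not in policy:
                raise ValueError(f"policy does not cover warning code {code.value}")
            if policy[code] == "drop":
                drop = True
        if drop:
            for code in p.flags:
                if policy.get(code) == "drop":
                    counts[code] = counts.get(code, 0) + 1
        else:
            kept.append(p)
    return kept, counts


def nearest_harbour_km(lon: float, lat: float, harbours: Sequence[Harbour]) -> tuple[str, float]:
    """Nearest harbour id and its distance in km (lexicographic tie-break)."""
    hs = sorted(harbours, key=lambda h: h.id)
    d = haversine_km(lon, lat, np.array([h.lon for h in hs]), np.array([h.lat for h in hs]))
    j = int(np.argmin(d))
    return hs[j].id, float(d[j])


def clean_pipeline(pings, harbours=None, coastline=None,
                   max_speed: float = DEFAULT_MAX_SPEED_KN,
                   ceiling_kn: float = DEFAULT_COHERENCE_CEILING_KN,
                   radius_km: float = DEFAULT_HARBOUR_RADIUS_KM,
                   policy: dict[WarningCode, str] | None = None):
    """Standard cleaning order: duplicates, land, speed/heading flags; drop per
    policy; then coherence on the retained series; finally harbour buffering.

    Returns (kept_pings, tally) where tally is a name -> count dict in the
    style of a cleaning report.
    """
    tally: dict[str, int] = {}
    tally["duplicated pings"] = flag_duplicates(pings)
    if coastline is not None:
        tally["pings on land"] = flag_on_land(pings, coastline)
    ns, nh = flag_speed_heading(pings, max_speed)
    tally["bad speed values"] = ns
    tally["bad heading values"] = nh
    kept, _ = apply_policy(pings, policy)
    tally["not coherent pings"] = flag_not_coherent(kept, ceiling_kn)
    kept = [p for p in kept if WarningCode.NOT_COHERENT not in p.flags]
    if harbours:
        tally["pings in harbour"] = flag_in_harbour(kept, harbours, radius_km)
    return kept, tally
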