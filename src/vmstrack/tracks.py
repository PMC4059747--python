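"""Trip cutting and time-grid trajectory interpolation.

A *track* is the ping series of one harbour-to-harbour fishing trip.
Per-vessel ping streams are cut at maximal runs of in-harbour pings and
at temporal gaps larger than a threshold; within a track only one
in-harbour ping is retained at each end.  Tracks are then interpolated
onto a global time grid (multiples of the chosen frequency since the
Unix epoch) with a cubic Hermite spline per coordinate whose knot
tangents come from the reported speed and heading, so that all vessels'
interpolated positions are simultaneous snapshots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .cleaning import Harbour, WarningCode, nearest_harbour_km
from .geo import deg_per_s_to_knots, knots_to_deg_per_s
from .vms_io import VmsPing

DEFAULT_MAX_GAP_H = 12.0
EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


@dataclass
class Track:
    track_id: int
    vessel_id: str
    pings: list[VmsPing]
    departure_harbour: str | None = None
    arrival_harbour: str | None = None
    area_id: str | None = None
    metier: str | None = None

    @property
    def start(self):
        return self.pings[0].timestamp

    @property
    def end(self):
        return self.pings[-1].timestamp

    @property
    def focal_point(self) -> tuple[float, float]:
        """Arithmetic mean of the *native* member pings' coordinates."""
        native = [p for p in self.pings if p.source == "native"]
        lon = float(np.mean([p.lon for p in native]))
        lat = float(np.mean([p.lat for p in native]))
        return lon, lat

    def native_pings(self) -> list[VmsPing]:
        return [p for p in self.pings if p.source == "native"]


def _ts(ping: VmsPing) -> float:
    return ping.timestamp.timestamp()


def cut_tracks(pings, max_gap_h: float = DEFAULT_MAX_GAP_H,
               min_pings: int = 3, first_track_id: int = 1):
    """Partition cleaned, per-vessel, time-sorted pings into tracks.

    A new track starts after a maximal run of IN_HARBOUR pings or after a
    temporal gap > ``max_gap_h`` hours.  Within each track only the first
    and last in-harbour pings are retained.  Tracks with fewer than
    ``min_pings`` pings are discarded and counted.

    Returns ``(tracks, n_discarded)``.  Ping ``track_id`` fields are set on
    the member pings.
    """
    by_vessel: dict[str, list[VmsPing]] = {}
    for p in pings:
        by_vessel.setdefault(p.vessel_id, []).append(p)

    tracks: list[Track] = []
    n_discarded = 0
    next_id = first_track_id

    for vessel in sorted(by_vessel):
        vp = sorted(by_vessel[vessel], key=_ts)
        cur: list[VmsPing] = []  # departure-harbour ping (optional) + sea pings
        pending_harbour: VmsPing | None = None
        prev: VmsPing | None = None

        def close(arrival: VmsPing | None):
            nonlocal cur, next_id, n_discarded
            members = cur + ([arrival] if arrival is not None else [])
            has_sea = any(WarningCode.IN_HARBOUR not in p.flags for p in members)
            if has_sea:
                if len(members) >= min_pings:
                    for p in members:
                        p.track_id = next_id
                    tracks.append(Track(track_id=next_id, vessel_id=vessel, pings=members))
                    next_id += 1
                else:
                    n_discarded += 1
            cur = []

        for p in vp:
            in_harbour = WarningCode.IN_HARBOUR in p.flags
            gap = prev is not None and (_ts(p) - _ts(prev)) / 3600.0 > max_gap_h
            if gap:
                close(None)
                pending_harbour = None
            if in_harbour:
                if cur:
                    close(p)  # arrival ping ends the trip
                pending_harbour = p  # latest harbour ping is the next departure
            else:
                if not cur:
                    cur = [pending_harbour] if pending_harbour is not None else []
                    pending_harbour = None
                cur.append(p)
            prev = p
        close(None)

    return tracks, n_discarded


def infer_harbours(track: Track, harbours) -> Track:
    """Fill departure/arrival harbour ids from endpoint flags, else by the
    nearest-harbour rule."""
    first, last = track.pings[0], track.pings[-1]
    if WarningCode.IN_HARBOUR in first.flags and first.harbour_id:
        track.departure_harbour = first.harbour_id
    else:
        track.departure_harbour = nearest_harbour_km(first.lon, first.lat, harbours)[0]
    if WarningCode.IN_HARBOUR in last.flags and last.harbour_id:
        track.arrival_harbour = last.harbour_id
    else:
        track.arrival_harbour = nearest_harbour_km(last.lon, last.lat, harbours)[0]
    return track


def _tangents(t, lon, lat, speed, heading):
    """Per-knot velocity in degree space from reported speed/heading, with a
    chord (finite-difference) fallback where speed or heading is unusable."""
    n = len(t)
    dlon = np.empty(n)
    dlat = np.empty(n)
    for i in range(n):
        ok = (np.isfinite(speed[i]) and speed[i] >= 0
              and np.isfinite(heading[i]) and 0.0 <= heading[i] < 360.0)
        if ok:
            dlon[i], dlat[i] = knots_to_deg_per_s(speed[i], heading[i], lat[i])
        else:
            j0 = max(0, i - 1)
            j1 = min(n - 1, i + 1)
            dt = t[j1] - t[j0]
            dlon[i] = (lon[j1] - lon[j0]) / dt
            dlat[i] = (lat[j1] - lat[j0]) / dt
    return dlon, dlat


def interpolate_track(track: Track, freq_min: float = 10.0) -> Track:
    """Resample a track onto the epoch-anchored global time grid.

    Output pings are the multiples of ``freq_min`` minutes since
    1970-01-01T00:00Z falling within [start, end], plus the native pings
    (exact passthrough), each marked ``source``.  Positions follow a cubic
    Hermite spline per coordinate with tangents from reported speed and
    heading; interpolated speed/heading come from the spline derivative.
    """
    if freq_min <= 0:
        raise ValueError("freq_min must be positive")
    native = track.native_pings()
    # collapse any equal-timestamp leftovers (duplicates should be cleaned)
    seen: set[float] = set()
    uniq = []
    for p in native:
        ts = _ts(p)
        if ts not in seen:
            seen.add(ts)
            uniq.append(p)
    if len(uniq) < 2:
        raise ValueError(f"track {track.track_id} has fewer than 2 native pings")

    t = np.array([_ts(p) for p in uniq])
    lon = np.array([p.lon for p in uniq])
    lat = np.array([p.lat for p in uniq])
    speed = np.array([p.speed for p in uniq])
    heading = np.array([p.heading for p in uniq])
    dlon, dlat = _tangents(t, lon, lat, speed, heading)
    sp_lon = CubicHermiteSpline(t, lon, dlon)
    sp_lat = CubicHermiteSpline(t, lat, dlat)

    step = freq_min * 60.0
    first = math.ceil(t[0] / step) * step
    grid = np.arange(first, t[-1] + 1e-9, step)
    native_times = set(t.tolist())
    grid = [g for g in grid.tolist() if g not in native_times]

    from datetime import datetime, timezone

    out: list[VmsPing] = list(uniq)
    for g in grid:
        glon = float(sp_lon(g))
        glat = float(sp_lat(g))
        kn, hd = deg_per_s_to_knots(float(sp_lon(g, 1)), float(sp_lat(g, 1)), glat)
        out.append(VmsPing(
            vessel_id=track.vessel_id,
            timestamp=datetime.fromtimestamp(g, tz=timezone.utc),
            lon=glon, lat=glat, speed=kn, heading=hd,
            source="interpolated", track_id=track.track_id,
            metier=track.metier))
    out.sort(key=_ts)
    return Track(track_id=track.track_id, vessel_id=track.vessel_id, pings=out,
                 departure_harbour=track.departure_harbour,
                 arrival_harbour=track.arrival_harbour,
                 area_id=track.area_id, metier=track.metier)


def tracks_from_pings(pings) -> list[Track]:
    """Rebuild Track objects from pings carrying track_id (e.g. from the store)."""
    groups: dict[int, list[VmsPing]] = {}
    for p in pings:
        if p.track_id is not None:
            groups.setdefault(p.track_id, []).append(p)
    out = []
    for tid in sorted(groups):
        members = sorted(groups[tid], key=_ts)
        out.append(Track(track_id=tid, vessel_id=members[0].vessel_id,
                         pings=members, metier=members[0].metier))
    return out


def interpolate_tracks(tracks, freq_min: float = 10.0):
    """Interpolate many tracks; too-short tracks are skipped with a warning.

    Returns (interpolated_tracks, n_skipped)."""
    out = []
    skipped = 0
    for tr in tracks:
        try:
            out.append(interpolate_track(tr, freq_min))
        except ValueError:
            warnings.warn(f"track {tr.track_id}: too short to interpolate, skipped")
            skipped += 1
    return out, skipped
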