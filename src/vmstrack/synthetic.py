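"""Synthetic mixed-fleet generator with full ground truth.

Emulates a small Mediterranean-style fleet: vessels dwell in harbours on
the edge of a rectangular landmass, steam out at ~10 kn to gear-specific
fishing grounds (trawlers tow at 2.5-4.5 kn over 50-450 m bottoms;
purse seiners alternate near-zero drifts with ~8 kn searches), and
return, transmitting pings on a ~2 h cadence with small Gaussian
position noise.  Each trip yields a logbook record whose catches are
drawn from the métier's Dirichlet catch profile scaled by trip length.
Duplicate, on-land and bad-speed errors are injected at configurable
rates, and every ping, trip and fishing interval is recorded in truth
tables so each pipeline stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import shapely

from .cleaning import Harbour
from .enrich import AreaLayer, BathyGrid
from .geo import KNOT_KMH, bearing_deg, haversine_km
from .linkage import FishingThresholds
from .vms_io import LogbookRecord, VmsPing


@dataclass(frozen=True)
class MetierSpec:
    """Speed/depth regime and catch composition of one métier."""

    name: str  # DCF code
    speed_mode: str  # "uniform" (towed gear) or "bimodal" (purse seine)
    fishing_speed: tuple[float, float]  # kn: (lo, hi) or (drift, search)
    depth_range: tuple[float, float]  # fishing-ground |depth| band, metres
    alpha: dict[str, float]  # Dirichlet concentrations per FAO code
    trip_duration_h: tuple[float, float]
    thresholds: FishingThresholds
    catch_rate_kg_per_day: float = 400.0

    def mean_profile(self) -> dict[str, float]:
        total = sum(self.alpha.values())
        return {s: a / total for s, a in self.alpha.items()}


OTB_SPEC = MetierSpec(
    name="OTB_DES_>=40_0_0", speed_mode="uniform", fishing_speed=(2.5, 4.5),
    depth_range=(50.0, 450.0),
    alpha={"HKE": 8.0, "MUT": 5.0, "DPS": 6.0, "NEP": 3.0, "PIL": 0.3, "ANE": 0.3},
    trip_duration_h=(26.0, 36.0),
    thresholds=FishingThresholds(2.0, 5.0, d_min=40.0, d_max=500.0))

PS_SPEC = MetierSpec(
    name="PS_SPF_>=14_0_0", speed_mode="bimodal", fishing_speed=(0.2, 8.0),
    depth_range=(60.0, 200.0),
    alpha={"ANE": 10.0, "PIL": 7.0, "MAC": 2.0, "HKE": 0.2},
    trip_duration_h=(10.0, 16.0),
    thresholds=FishingThresholds(0.0, 8.7, min_harbour_km=5.0))

LLD_SPEC = MetierSpec(
    name="LLD_LPF_0_0_0", speed_mode="uniform", fishing_speed=(1.5, 3.0),
    depth_range=(300.0, 800.0),
    alpha={"SWO": 10.0, "ALB": 3.0, "BSH": 1.0},
    trip_duration_h=(14.0, 24.0),
    thresholds=FishingThresholds(1.0, 3.5))


@dataclass(frozen=True)
class ErrorRates:
    duplicate: float = 0.0
    on_land: float = 0.0
    bad_speed: float = 0.0
    gap: float = 0.0

    def __post_init__(self):
        for r in (self.duplicate, self.on_land, self.bad_speed, self.gap):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class FleetScenario:
    """Study conditions for one simulated fleet."""

    n_vessels: int = 13
    start: datetime = datetime(2012, 6, 1, tzinfo=timezone.utc)
    n_days: int = 30
    ping_interval_min: float = 120.0
    metiers: tuple[MetierSpec, ...] = (OTB_SPEC, PS_SPEC)
    error_rates: ErrorRates = ErrorRates(duplicate=0.03, on_land=0.03, bad_speed=0.02)
    position_noise_deg: float = 2e-4
    speed_noise_kn: float = 0.15
    logbook_jitter_h: float = 1.0
    seed: int = 0


# World geometry: sea box west of a rectangular landmass whose west edge
# (lon = 10) carries the harbours; depth increases linearly seaward at
# 500 m per degree of longitude.
COAST_LON = 10.0
SEA_LON = (8.0, COAST_LON)
SEA_LAT = (42.0, 44.0)
DEPTH_M_PER_DEG = 500.0


def default_world():
    land = shapely.box(COAST_LON, 41.5, 11.0, 44.5)
    # harbour points sit just off the coast so position noise never lands them
    harbours = [Harbour("H1", "Porto Uno", COAST_LON - 0.01, 42.4),
                Harbour("H2", "Porto Due", COAST_LON - 0.01, 43.0),
                Harbour("H3", "Porto Tre", COAST_LON - 0.01, 43.6)]
    lon = np.arange(7.8, 11.01, 0.05)
    lat = np.arange(41.4, 44.61, 0.05)
    z = (lon[None, :] - COAST_LON) * DEPTH_M_PER_DEG * np.ones((len(lat), 1))
    bathy = BathyGrid(lon=lon, lat=lat, z=z)
    areas = AreaLayer(areas=[
        ("GSA-N", shapely.box(7.5, 43.0, COAST_LON, 44.5)),
        ("GSA-S", shapely.box(7.5, 41.5, COAST_LON, 43.0))])
    return land, harbours, bathy, areas


def lon_at_depth(depth_m: float) -> float:
    """Longitude of the isobath at |depth| metres in the default world."""
    return COAST_LON - depth_m / DEPTH_M_PER_DEG


@dataclass
class TripTruth:
    trip_id: int
    vessel_id: str
    metier: str
    start: datetime
    end: datetime
    fishing_intervals: list[tuple[datetime, datetime]]


@dataclass
class PingTruth:
    trip_id: int | None  # None while dwelling in harbour
    is_fishing: bool
    injected: str | None = None  # "duplicate" | "on_land" | "bad_speed"


@dataclass
class SimulationResult:
    scenario: FleetScenario
    pings: list[VmsPing]
    ping_truth: list[PingTruth]
    logbook: list[LogbookRecord]
    trips: list[TripTruth]
    harbours: list[Harbour]
    coastline: list
    bathy: BathyGrid
    areas: AreaLayer
    thresholds: dict[str, FishingThresholds]

    def truth_by_ping_id(self) -> dict[int, PingTruth]:
        return {id(p): t for p, t in zip(self.pings, self.ping_truth)}


class _Schedule:
    """Piecewise-linear waypoint trajectory with per-segment speed and state."""

    def __init__(self):
        self.t: list[float] = []
        self.lon: list[float] = []
        self.lat: list[float] = []
        self.speed: list[float] = []  # segment speed, kn
        self.fishing: list[bool] = []

    def start_at(self, t0: float, lon: float, lat: float):
        self.t = [t0]
        self.lon = [lon]
        self.lat = [lat]

    def leg_to(self, lon: float, lat: float, speed_kn: float, fishing: bool):
        d_km = float(haversine_km(self.lon[-1], self.lat[-1], lon, lat))
        dt_s = d_km / (speed_kn * KNOT_KMH) * 3600.0
        self.t.append(self.t[-1] + max(dt_s, 1.0))
        self.lon.append(lon)
        self.lat.append(lat)
        self.speed.append(speed_kn)
        self.fishing.append(fishing)

    def drift(self, duration_s: float, speed_kn: float, bearing: float, fishing: bool):
        d_km = speed_kn * KNOT_KMH * duration_s / 3600.0
        dlat = d_km / 111.195 * np.cos(np.radians(bearing))
        dlon = d_km / (111.195 * np.cos(np.radians(self.lat[-1]))) * np.sin(np.radians(bearing))
        self.t.append(self.t[-1] + duration_s)
        self.lon.append(self.lon[-1] + dlon)
        self.lat.append(self.lat[-1] + dlat)
        self.speed.append(speed_kn)
        self.fishing.append(fishing)

    @property
    def end(self) -> float:
        return self.t[-1]

    def sample(self, when: float):
        """(lon, lat, speed, heading, fishing) at epoch-seconds ``when``."""
        i = int(np.searchsorted(self.t, when, side="right")) - 1
        i = min(max(i, 0), len(self.t) - 2)
        f = (when - self.t[i]) / (self.t[i + 1] - self.t[i])
        lon = self.lon[i] + f * (self.lon[i + 1] - self.lon[i])
        lat = self.lat[i] + f * (self.lat[i + 1] - self.lat[i])
        hd = float(bearing_deg(self.lon[i], self.lat[i], self.lon[i + 1], self.lat[i + 1]))
        return lon, lat, self.speed[i], hd, self.fishing[i]


def _fishing_bout(sched: _Schedule, spec: MetierSpec, budget_s: float, rng,
                  center: tuple[float, float]) -> None:
    """Append fishing-phase segments consuming ``budget_s`` seconds.

    Towed gears work long straight legs (1-2.5 h) whose heading drifts
    gently; purse seiners alternate near-stationary sets with straight
    searches.  Legs that would exit the métier's depth band turn back
    toward the ground centre.
    """
    lon_lo = lon_at_depth(spec.depth_range[1]) + 0.01
    lon_hi = lon_at_depth(spec.depth_range[0]) - 0.01
    lat_lo, lat_hi = SEA_LAT[0] + 0.05, SEA_LAT[1] - 0.05
    heading = rng.uniform(0, 360)
    spent = 0.0
    while spent < budget_s:
        if spec.speed_mode == "bimodal" and rng.random() < 0.5:
            dur = min(rng.uniform(3600, 7200), budget_s - spent)
            sched.drift(dur, spec.fishing_speed[0], rng.uniform(0, 360), True)
            spent += dur
            continue
        if spec.speed_mode == "bimodal":
            speed = max(spec.fishing_speed[1] + rng.normal(0, 0.2), 1.0)
        else:
            speed = rng.uniform(*spec.fishing_speed)
        dur = min(rng.uniform(3600, 2.5 * 3600), budget_s - spent)
        heading = (heading + rng.normal(0, 15.0)) % 360
        d_km = speed * KNOT_KMH * dur / 3600.0
        dlat = d_km / 111.195 * np.cos(np.radians(heading))
        dlon = d_km / (111.195 * np.cos(np.radians(sched.lat[-1]))) * np.sin(np.radians(heading))
        if not (lon_lo <= sched.lon[-1] + dlon <= lon_hi
                and lat_lo <= sched.lat[-1] + dlat <= lat_hi):
            # turn back toward the ground centre, stopping there at the latest
            heading = float(bearing_deg(sched.lon[-1], sched.lat[-1], *center))
            to_centre_km = float(haversine_km(sched.lon[-1], sched.lat[-1], *center))
            dur = min(dur, max(to_centre_km / (speed * KNOT_KMH) * 3600.0, 600.0))
        sched.drift(dur, speed, heading, True)
        spent += dur


def simulate(scenario: FleetScenario) -> SimulationResult:
    """Generate a full synthetic fleet with ground truth (deterministic per seed)."""
    rng = np.random.default_rng(scenario.seed)
    land, harbours, bathy, areas = default_world()
    span_s = scenario.n_days * 86400.0
    t_start = scenario.start.timestamp()
    t_end = t_start + span_s

    trips: list[TripTruth] = []
    logbook: list[LogbookRecord] = []
    pings: list[VmsPing] = []
    truth: list[PingTruth] = []

    lon_lo_by_spec = {m.name: lon_at_depth(m.depth_range[1]) for m in scenario.metiers}
    lon_hi_by_spec = {m.name: lon_at_depth(m.depth_range[0]) for m in scenario.metiers}

    for v in range(scenario.n_vessels):
        vessel_id = f"V{v + 1:03d}"
        spec = scenario.metiers[v % len(scenario.metiers)]
        harbour = harbours[v % len(harbours)]

        # vessel timeline: alternating dwell / trip schedules
        schedules: list[tuple[float, float, _Schedule | None, int | None]] = []
        t = t_start + rng.uniform(0, 5 * 3600)
        while t < t_end:
            dwell = rng.uniform(6, 14) * 3600.0
            t_dep = t + dwell
            if t_dep >= t_end:
                schedules.append((t, t_end, None, None))
                break
            target_h = rng.uniform(*spec.trip_duration_h)
            glon = rng.uniform(lon_lo_by_spec[spec.name] + 0.02,
                               lon_hi_by_spec[spec.name] - 0.02)
            glat = float(np.clip(harbour.lat + rng.uniform(-0.3, 0.3),
                                 SEA_LAT[0] + 0.1, SEA_LAT[1] - 0.1))
            sched = _Schedule()
            sched.start_at(t_dep, harbour.lon, harbour.lat)
            steam_out = float(np.clip(rng.normal(10, 1), 7, 13))
            sched.leg_to(glon, glat, steam_out, False)
            t_fish_start = sched.end
            transit_h = (t_fish_start - t_dep) / 3600.0
            budget_h = max(target_h - 2.0 * transit_h, 2.0)
            _fishing_bout(sched, spec, budget_h * 3600.0, rng, (glon, glat))
            t_fish_end = sched.end
            steam_back = float(np.clip(rng.normal(10, 1), 7, 13))
            sched.leg_to(harbour.lon, harbour.lat, steam_back, False)
            if sched.end > t_end:
                schedules.append((t, t_end, None, None))
                break
            trip_id = len(trips)
            trips.append(TripTruth(
                trip_id=trip_id, vessel_id=vessel_id, metier=spec.name,
                start=datetime.fromtimestamp(t_dep, tz=timezone.utc),
                end=datetime.fromtimestamp(sched.end, tz=timezone.utc),
                fishing_intervals=[(datetime.fromtimestamp(t_fish_start, tz=timezone.utc),
                                    datetime.fromtimestamp(t_fish_end, tz=timezone.utc))]))
            days = (sched.end - t_dep) / 86400.0
            total = spec.catch_rate_kg_per_day * days * rng.lognormal(0, 0.2)
            comp = rng.dirichlet([spec.alpha[s] for s in sorted(spec.alpha)])
            jit = scenario.logbook_jitter_h
            dep_j = t_dep + (rng.uniform(-jit, jit) * 3600.0 if jit else 0.0)
            arr_j = sched.end + (rng.uniform(-jit, jit) * 3600.0 if jit else 0.0)
            if arr_j <= dep_j:
                arr_j = dep_j + 3600.0
            logbook.append(LogbookRecord(
                vessel_id=vessel_id,
                departure=datetime.fromtimestamp(dep_j, tz=timezone.utc),
                arrival=datetime.fromtimestamp(arr_j, tz=timezone.utc),
                catches={s: float(total * c)
                         for s, c in zip(sorted(spec.alpha), comp)}))
            schedules.append((t, t_dep, None, None))  # dwell before departure
            schedules.append((t_dep, sched.end, sched, trip_id))
            t = sched.end
        # pings on the vessel's cadence
        phase = rng.uniform(0, scenario.ping_interval_min * 60.0)
        tau = t_start + phase
        step = scenario.ping_interval_min * 60.0
        si = 0
        while tau < t_end and schedules:
            while si < len(schedules) - 1 and tau >= schedules[si][1]:
                si += 1
            lo, hi, sched, trip_id = schedules[si]
            if tau < lo or tau >= hi:
                tau += step
                continue
            if sched is None:
                lon, lat, speed, hd, fishing = harbour.lon, harbour.lat, 0.0, 0.0, False
            else:
                lon, lat, speed, hd, fishing = sched.sample(tau)
            if scenario.position_noise_deg:
                lon += rng.normal(0, scenario.position_noise_deg)
                lat += rng.normal(0, scenario.position_noise_deg)
            speed = max(0.0, speed + (rng.normal(0, scenario.speed_noise_kn)
                                      if scenario.speed_noise_kn else 0.0))
            if scenario.error_rates.gap and rng.random() < scenario.error_rates.gap:
                tau += step
                continue
            ping = VmsPing(vessel_id=vessel_id,
                           timestamp=datetime.fromtimestamp(round(tau), tz=timezone.utc),
                           lon=lon, lat=lat, speed=float(speed), heading=hd)
            pings.append(ping)
            truth.append(PingTruth(trip_id=trip_id, is_fishing=fishing))
            # error injection
            er = scenario.error_rates
            if er.duplicate and rng.random() < er.duplicate:
                dup = ping.copy()
                pings.append(dup)
                truth.append(PingTruth(trip_id=trip_id, is_fishing=fishing,
                                       injected="duplicate"))
            if er.on_land and trip_id is not None and rng.random() < er.on_land:
                ping.lon = rng.uniform(10.3, 10.8)
                truth[-1 if truth[-1].injected is None else -2].injected = "on_land"
            elif er.bad_speed and trip_id is not None and rng.random() < er.bad_speed:
                ping.speed = -rng.uniform(1.0, 5.0)
                idx = -1 if truth[-1].injected is None else -2
                truth[idx].injected = "bad_speed"
            tau += step

    thresholds = {m.name: m.thresholds for m in scenario.metiers}
    return SimulationResult(scenario=scenario, pings=pings, ping_truth=truth,
                            logbook=logbook, trips=trips, harbours=harbours,
                            coastline=[land], bathy=bathy, areas=areas,
                            thresholds=thresholds)


def planted_logbook(specs, n_trips: int, seed: int = 0,
                    start: datetime | None = None):
    """Logbook records with known métier labels (for recovery experiments).

    Trips are assigned to métiers uniformly at random; catches are Dirichlet
    draws scaled by a lognormal trip total.  Returns (records, true_labels).
    """
    rng = np.random.default_rng(seed)
    start = start or datetime(2012, 6, 1, tzinfo=timezone.utc)
    records = []
    labels = []
    for i in range(n_trips):
        spec = specs[int(rng.integers(len(specs)))]
        dur_h = rng.uniform(*spec.trip_duration_h)
        dep = start + timedelta(hours=float(i * 36))
        total = spec.catch_rate_kg_per_day * dur_h / 24.0 * rng.lognormal(0, 0.2)
        comp = rng.dirichlet([spec.alpha[s] for s in sorted(spec.alpha)])
        records.append(LogbookRecord(
            vessel_id=f"V{i % 97:03d}", departure=dep,
            arrival=dep + timedelta(hours=float(dur_h)),
            catches={s: float(total * c) for s, c in zip(sorted(spec.alpha), comp)}))
        labels.append(spec.name)
    return records, labels


def truth_compare(sim: SimulationResult, tracks, match_result=None,
                  interp_tracks=None) -> dict[str, float]:
    """Score pipeline outputs against the generator's truth tables.

    Returns a dict with track_recovery, metier_agreement (adjusted Rand),
    fishing_precision, fishing_recall and match_recovery, each in [0, 1]
    (NaN where the corresponding output was not supplied).
    """
    from sklearn.metrics import adjusted_rand_score

    truth_by_id = sim.truth_by_ping_id()
    eval_tracks = interp_tracks if interp_tracks is not None else tracks

    # map each recovered track to the true trip owning most of its sea pings
    track_trip: dict[int, int] = {}
    trip_hits: dict[int, dict[int, int]] = {}
    for tr in tracks:
        votes: dict[int, int] = {}
        for p in tr.native_pings():
            t = truth_by_id.get(id(p))
            if t is None or t.trip_id is None or t.injected is not None:
                continue
            votes[t.trip_id] = votes.get(t.trip_id, 0) + 1
        if votes:
            best = max(votes, key=lambda k: (votes[k], -k))
            track_trip[tr.track_id] = best
            trip_hits.setdefault(best, {})[tr.track_id] = votes[best]

    # clean sea-ping count per trip
    trip_n: dict[int, int] = {}
    for t in sim.ping_truth:
        if t.trip_id is not None and t.injected is None:
            trip_n[t.trip_id] = trip_n.get(t.trip_id, 0) + 1

    recovered = 0
    evaluable = 0
    for trip in sim.trips:
        n_expected = trip_n.get(trip.trip_id, 0)
        if n_expected < 3:
            continue
        evaluable += 1
        hits = trip_hits.get(trip.trip_id, {})
        if len(hits) == 1:
            coverage = next(iter(hits.values())) / n_expected
            if coverage >= 0.9:
                recovered += 1
    scores = {"track_recovery": recovered / evaluable if evaluable else float("nan")}

    # métier agreement over tracks that received a label
    y_true, y_pred = [], []
    for tr in eval_tracks:
        trip_id = track_trip.get(tr.track_id)
        if trip_id is None or tr.metier is None:
            continue
        y_true.append(sim.trips[trip_id].metier)
        y_pred.append(tr.metier)
    scores["metier_agreement"] = (float(adjusted_rand_score(y_true, y_pred))
                                  if len(set(y_true)) > 1 else float("nan"))

    # fishing-state precision/recall over marked pings of the evaluated tracks
    tp = fp = fn = 0
    for tr in eval_tracks:
        trip_id = track_trip.get(tr.track_id)
        if trip_id is None:
            continue
        intervals = sim.trips[trip_id].fishing_intervals
        for p in tr.pings:
            if p.is_fishing is None:
                continue
            truth_state = any(a <= p.timestamp <= b for a, b in intervals)
            if p.is_fishing and truth_state:
                tp += 1
            elif p.is_fishing and not truth_state:
                fp += 1
            elif truth_state:
                fn += 1
    scores["fishing_precision"] = tp / (tp + fp) if (tp + fp) else float("nan")
    scores["fishing_recall"] = tp / (tp + fn) if (tp + fn) else float("nan")

    # matching recovery: the true pair of a track is its trip's logbook record
    if match_result is not None:
        good = total = 0
        for tid, trip_id in track_trip.items():
            total += 1
            if match_result.pairs.get(tid) == trip_id:
                good += 1
        scores["match_recovery"] = good / total if total else float("nan")
    return scores


def write_files(sim: SimulationResult, outdir) -> dict[str, str]:
    """Write the scenario to the same plain-text formats the loaders read."""
    import csv
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out / "vms.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vessel", "datetime", "lon", "lat", "speed", "heading"])
        for ping in sim.pings:
            w.writerow([ping.vessel_id, ping.timestamp.strftime("%Y-%m-%d %H:%M:%S"),
                        f"{ping.lon:.6f}", f"{ping.lat:.6f}",
                        f"{ping.speed:.2f}", f"{ping.heading:.1f}"])
    paths["vms"] = str(p)

    p = out / "logbook.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vessel", "departure", "arrival", "species", "kg"])
        for rec in sim.logbook:
            for s, q in sorted(rec.catches.items()):
                w.writerow([rec.vessel_id, rec.departure.strftime("%Y-%m-%d %H:%M:%S"),
                            rec.arrival.strftime("%Y-%m-%d %H:%M:%S"), s, f"{q:.3f}"])
    paths["logbook"] = str(p)

    p = out / "harbours.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "lon", "lat"])
        for h in sim.harbours:
            w.writerow([h.id, h.name, h.lon, h.lat])
    paths["harbours"] = str(p)

    p = out / "coastline.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "wkt"])
        for i, poly in enumerate(sim.coastline):
            w.writerow([f"L{i}", poly.wkt])
    paths["coastline"] = str(p)

    sim.bathy.to_ascii_grid(out / "bathy.asc")
    paths["bathy"] = str(out / "bathy.asc")
    sim.areas.to_csv(out / "areas.csv")
    paths["areas"] = str(out / "areas.csv")

    from .metier import save_reference_profiles

    p = out / "reference_profiles.csv"
    save_reference_profiles({m.name: m.alpha for m in sim.scenario.metiers}, p)
    paths["references"] = str(p)

    p = out / "thresholds.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metier", "vmin", "vmax", "dmin", "dmax", "min_harbour_km"])
        for name, th in sim.thresholds.items():
            w.writerow([name, th.v_min, th.v_max,
                        "" if th.d_min is None else th.d_min,
                        "" if th.d_max is None else th.d_max,
                        "" if th.min_harbour_km is None else th.min_harbour_km])
    paths["thresholds"] = str(p)
    return paths
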