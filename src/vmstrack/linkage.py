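"""VMS-logbook linkage, behaviour-based métier prediction, and fishing-point
detection.

Tracks and logbook records are paired by temporal interval overlap within
the same vessel: several tracks may share one logbook record; a track
overlapping several records takes the one with the largest overlap.  The
métier of tracks without any logbook match is predicted from the vessel's
behaviour (speed profile, depth, duration) with a small feed-forward
neural network trained on the matched tracks.  Finally, fishing set
positions are marked by per-métier thresholds on speed, optionally
sea-bottom depth and distance from the nearest harbour.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .cleaning import nearest_harbour_km


@dataclass(frozen=True)
class TripInterval:
    owner: str
    start: object  # UTC datetime
    end: object

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("interval start must precede end")


def interval_overlap(a: TripInterval, b: TripInterval) -> float:
    """Overlap of two intervals in hours (0 for disjoint or touching)."""
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0.0, (hi - lo).total_seconds() / 3600.0)


@dataclass
class FishingThresholds:
    """Per-métier fishing-mode thresholds; bounds are inclusive."""

    v_min: float
    v_max: float
    d_min: float | None = None  # |depth| metres
    d_max: float | None = None
    min_harbour_km: float | None = None

    def __post_init__(self):
        if self.v_min > self.v_max:
            raise ValueError("v_min must be <= v_max")
        if self.d_min is not None and self.d_max is not None and self.d_min > self.d_max:
            raise ValueError("d_min must be <= d_max")


#: Shipped defaults for common towed gears; user files override.
DEFAULT_THRESHOLDS: dict[str, FishingThresholds] = {
    "OTB": FishingThresholds(2.5, 4.5),
    "TBB": FishingThresholds(2.5, 4.5),
    "PTM": FishingThresholds(2.5, 4.5),
}


def load_thresholds(path) -> dict[str, FishingThresholds]:
    """Read a delimited thresholds file: metier,vmin,vmax[,dmin,dmax,min_harbour_km]."""
    out: dict[str, FishingThresholds] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            def opt(key):
                v = row.get(key, "")
                return float(v) if v not in ("", None) else None
            out[row["metier"]] = FishingThresholds(
                v_min=float(row["vmin"]), v_max=float(row["vmax"]),
                d_min=opt("dmin"), d_max=opt("dmax"),
                min_harbour_km=opt("min_harbour_km"))
    return out


@dataclass
class MatchResult:
    pairs: dict[int, int]  # track_id -> record index
    unmatched_tracks: list[int]
    unmatched_records: list[int]

    @property
    def match_rate_pct(self) -> float:
        n = len(self.pairs) + len(self.unmatched_tracks)
        return 100.0 * len(self.pairs) / n if n else 0.0


def match(tracks, records) -> MatchResult:
    """Pair tracks with logbook records by same-vessel interval overlap.

    A candidate pair needs overlap > 0; each track takes the record with
    the largest overlap (ties: earliest record start, then lowest record
    index); one record may absorb several tracks.  Métier and gear are
    copied from the record onto the track.
    """
    by_vessel: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_vessel.setdefault(r.vessel_id, []).append(i)

    pairs: dict[int, int] = {}
    matched_records: set[int] = set()
    unmatched_tracks: list[int] = []
    for tr in tracks:
        best: tuple[float, object, int] | None = None  # (-overlap, start, idx)
        for i in by_vessel.get(tr.vessel_id, ()):
            r = records[i]
            lo = max(tr.start, r.departure)
            hi = min(tr.end, r.arrival)
            ov = (hi - lo).total_seconds() / 3600.0
            if ov <= 0:
                continue
            key = (-ov, r.departure, i)
            if best is None or key < best:
                best = key
        if best is None:
            unmatched_tracks.append(tr.track_id)
        else:
            i = best[2]
            pairs[tr.track_id] = i
            matched_records.add(i)
            tr.metier = records[i].metier
            for p in tr.pings:
                p.metier = tr.metier
    unmatched_records = [i for i in range(len(records)) if i not in matched_records]
    return MatchResult(pairs=pairs, unmatched_tracks=unmatched_tracks,
                       unmatched_records=unmatched_records)


#: documented feature layout: 11 speed quantiles (0..100% by 10), 15 speed-bin
#: fractions ([0,1) .. [14,15) kn), trip duration (h), mean |depth| (m),
#: night-ping fraction (22:00-06:00 UTC).
N_FEATURES = 29


def track_features(track) -> np.ndarray:
    """Deterministic, ping-order-invariant behaviour descriptor of a track."""
    speeds = np.array([p.speed for p in track.pings if np.isfinite(p.speed)])
    if speeds.size == 0:
        speeds = np.zeros(1)
    q = np.quantile(speeds, np.linspace(0, 1, 11))
    bins = np.histogram(speeds, bins=np.arange(16))[0] / speeds.size
    times = [p.timestamp for p in track.pings]
    duration_h = (max(times) - min(times)).total_seconds() / 3600.0
    depths = [abs(p.depth) for p in track.pings if p.depth is not None]
    mean_depth = float(np.mean(depths)) if depths else 0.0
    hours = np.array([p.timestamp.hour for p in track.pings])
    night = float(np.mean((hours >= 22) | (hours < 6)))
    return np.concatenate([q, bins, [duration_h, mean_depth, night]])


def predict_metier(labelled_tracks, unlabelled_tracks, seed: int = 0,
                   hidden_units: int = 32, test_fraction: float = 0.2):
    """Métier prediction from VMS behaviour with a single-hidden-layer ANN.

    Trains on the labelled tracks' standardized feature vectors with a
    stratified 80/20 split to report held-out accuracy, then refits on all
    labelled tracks and labels the unlabelled ones.

    Returns (predicted_labels, confidences, holdout_accuracy).
    """
    y = [tr.metier for tr in labelled_tracks]
    if len(set(y)) < 2:
        raise ValueError("need at least 2 métier classes to train")
    X = np.vstack([track_features(tr) for tr in labelled_tracks])
    scaler = StandardScaler().fit(X)

    Xtr, Xte, ytr, yte = train_test_split(
        scaler.transform(X), y, test_size=test_fraction,
        stratify=y, random_state=seed)
    net = MLPClassifier(hidden_layer_sizes=(hidden_units,), max_iter=2000,
                        random_state=seed)
    net.fit(Xtr, ytr)
    acc = float(accuracy_score(yte, net.predict(Xte)))

    final = MLPClassifier(hidden_layer_sizes=(hidden_units,), max_iter=2000,
                          random_state=seed)
    final.fit(scaler.transform(X), y)
    if unlabelled_tracks:
        Xu = scaler.transform(np.vstack([track_features(tr) for tr in unlabelled_tracks]))
        proba = final.predict_proba(Xu)
        idx = np.argmax(proba, axis=1)
        labels = [final.classes_[i] for i in idx]
        conf = proba[np.arange(len(idx)), idx].tolist()
        for tr, lab in zip(unlabelled_tracks, labels):
            tr.metier = lab
            for p in tr.pings:
                p.metier = lab
    else:
        labels, conf = [], []
    return labels, conf, acc


def mark_fishing(pings, thresholds: dict[str, FishingThresholds], harbours=None) -> dict:
    """Set ``is_fishing`` on pings from their métier's thresholds.

    A ping is fishing iff speed is inside [v_min, v_max] (inclusive), AND
    (no depth range OR |depth| inside it — missing depth fails), AND (no
    harbour-distance rule OR nearest harbour >= the minimum).  Pings whose
    métier has no thresholds are left unmarked and counted.
    """
    counts = {"fishing": 0, "not_fishing": 0, "no_thresholds": 0}
    for p in pings:
        th = thresholds.get(p.metier)
        if th is None:
            p.is_fishing = None
            counts["no_thresholds"] += 1
            continue
        ok = np.isfinite(p.speed) and th.v_min <= p.speed <= th.v_max
        if ok and (th.d_min is not None or th.d_max is not None):
            if p.depth is None:
                ok = False
            else:
                d = abs(p.depth)
                if th.d_min is not None and d < th.d_min:
                    ok = False
                if th.d_max is not None and d > th.d_max:
                    ok = False
        if ok and th.min_harbour_km is not None:
            if not harbours:
                raise ValueError("harbour-distance rule requires a harbour list")
            _, dist = nearest_harbour_km(p.lon, p.lat, harbours)
            ok = dist >= th.min_harbour_km
        p.is_fishing = bool(ok)
        counts["fishing" if ok else "not_fishing"] += 1
    return counts
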