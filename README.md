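# vmstrack

Processing chain for satellite **Vessel Monitoring System (VMS)** pings and
**logbook** catch records in fisheries spatial ecology, with the
multi-gear, multi-species Mediterranean fleet in mind. It takes raw
position reports (vessel id, timestamp, lon/lat, speed, heading at a ~2 h
cadence) and per-trip catch declarations by FAO 3-alpha species code, and
turns them into cleaned harbour-to-harbour fishing trips, time-aligned
interpolated trajectories, métier assignments, fishing set positions and
spatial pressure indicators — as a library plus a thin `vmstrack` CLI over
a single-file SQLite store.

## What it computes

1. **Cleaning** — pings are *flagged*, never silently deleted:
   duplicates (same vessel + instant), on-land positions, speeds outside
   [0, 25 kn], headings outside [0°, 360°), physically incoherent jumps
   (implied great-circle speed > 30 kn), and in-harbour pings within a 2 km
   buffer of the nearest harbour. A per-code keep/drop policy then filters.
2. **Trip cutting & interpolation** — per-vessel streams are cut at
   maximal in-harbour runs and at gaps > 12 h, keeping one harbour ping at
   each end of every track. Tracks are resampled onto a *global* time grid
   (multiples of the chosen frequency since the Unix epoch, so all vessels
   share snapshot instants) with a cubic Hermite spline per coordinate
   whose knot tangents come from each ping's reported speed and course:
   native pings pass through exactly and no tuning parameter is needed.
3. **Enrichment** — sea-bottom depth per ping by bilinear interpolation of
   a local bathymetry grid; management-area assignment (e.g. GSA
   rectangles) by the polygon containing the track's focal point (the mean
   of its native ping coordinates).
4. **Métier discovery & classification** — trips' catch profiles are
   clustered with k-medoids (PAM, run CLARA-style on random subsamples for
   large datasets) under the Bray–Curtis dissimilarity

   ```
   BCD(i, j) = 1 − 2·C_ij / (S_i + S_j)
   ```

   with `C_ij = Σ_s min(x_is, x_js)` and `S_i = Σ_s x_is`; the number of
   métiers maximises the average silhouette width (ASW). Records are then
   assigned by fuzzy membership `u_c ∝ d_c^(−2/(m−1))` to the medoids
   (m = 2 by default; m → 1⁺ recovers the crisp nearest-medoid rule).
5. **VMS–logbook linkage** — tracks and records pair by same-vessel
   temporal interval overlap: several tracks may share a record, and a
   track overlapping several records takes the largest overlap. Tracks
   without any logbook match get a métier from a single-hidden-layer
   neural network trained on the matched tracks' behaviour (speed
   quantiles and histogram, duration, depth, night fraction).
6. **Fishing pressure** — fishing set positions are marked by per-métier
   thresholds on speed (optionally depth and distance from harbour);
   fishing pings are counted per grid cell (count × interpolation interval
   = effort hours); DCF **indicator 5** is the total area of cells with any
   effort and **indicator 6** the area of the top cells holding 90% of it;
   **trawled area** is trajectory length × overall gear width (OWG).

A first-class synthetic module (`vmstrack.synthetic`) generates a full
mixed fleet — harbours, coastline, bathymetry, pings, logbooks — with
ground-truth tracks, métiers, fishing states and injected errors, so every
stage is testable offline and scorable with `truth_compare`.

## Worked example

```python
from vmstrack.synthetic import FleetScenario, simulate, truth_compare
from vmstrack.pipeline import run_pipeline

sim = simulate(FleetScenario(n_vessels=13, n_days=30, seed=7))
res = run_pipeline(sim, seed=7)
print(f"tracks detected: {res.tally['tracks detected']}")
print(f"silhouette profile: {[(k, round(s, 3)) for k, s in res.silhouette_profile]}")
print(f"metiers: {res.model.labels}")
print(f"match rate: {res.match_result.match_rate_pct:.1f}%")
print(f"indicator 5: {res.indicator5_km2:.0f} km^2, indicator 6: {res.indicator6_km2:.0f} km^2")
print("truth scores:", {k: round(v, 3) for k, v in
                        truth_compare(sim, res.tracks, res.match_result,
                                      res.interp_tracks).items()})
```

prints

```
tracks detected: 294
silhouette profile: [(2, 0.751), (3, 0.449), (4, 0.448), (5, 0.446), (6, 0.221)]
metiers: ['OTB_DES_>=40_0_0', 'PS_SPF_>=14_0_0']
match rate: 100.0%
indicator 5: 15915 km^2, indicator 6: 10409 km^2
truth scores: {'track_recovery': 1.0, 'metier_agreement': 1.0,
               'fishing_precision': 0.94, 'fishing_recall': 0.935, 'match_recovery': 1.0}
```

All 294 simulated trips are recovered as tracks; the ASW search picks 2
métiers (the trawl and purse-seine fleets planted by the generator) and
labels them against the reference profiles; every track matches its true
logbook record; speed/depth/harbour-distance thresholds recover ~94% of
the true fishing positions on the 10-minute interpolated trajectories; the
indicators say fishing touched ~15 900 km² of 0.1° cells, with 90% of the
effort concentrated on ~10 400 km².

The same chain is available from a shell:

```sh
vmstrack simulate --vessels 13 --days 30 --seed 7 --out scn/
vmstrack load-vms scn/vms.csv vms.db
vmstrack clean --harbours scn/harbours.csv --land scn/coastline.csv vms.db clean.db
vmstrack cut --harbours scn/harbours.csv clean.db cut.db
vmstrack interp --freq-min 10 cut.db interp.db
vmstrack enrich --bathy scn/bathy.asc --areas scn/areas.csv interp.db enriched.db
vmstrack load-logbook scn/logbook.csv log.db
vmstrack metier-discover --k 2:6 --references scn/reference_profiles.csv log.db model.csv
vmstrack metier-classify --model model.csv log.db
vmstrack match enriched.db log.db
vmstrack mark-fishing --thresholds scn/thresholds.csv --harbours scn/harbours.csv enriched.db
vmstrack grid --extent 8 42 10 44 enriched.db effort.csv
vmstrack dcf effort.csv
```

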