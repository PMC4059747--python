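# Methods

This note documents the models and procedures implemented in `vmstrack`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Geodesy

All distances are great-circle distances on a sphere of mean radius
R = 6371.0088 km; speeds are knots (1 kn = 1.852 km/h). One degree of arc
is πR/180 ≈ 111.195 km; east displacements scale with cos(latitude).
Graticule cell areas use the closed form R²·Δλ·|sin φ₂ − sin φ₁|;
arbitrary polygon cells use planar area scaled at the polygon's mean
latitude (adequate for management-scale cells, increasingly biased for
cells spanning many degrees of latitude).

## Cleaning

Irregular pings are flagged with stable warning codes and only removed by
an explicit policy (default: drop DUPLICATE, ON_LAND, NOT_COHERENT,
OUT_OF_RANGE; keep BAD_SPEED, BAD_HEADING — the position is still usable —
and IN_HARBOUR, which trip cutting needs). Conventions:

- *Duplicate*: same vessel and timestamp, regardless of position — two
  positions at one instant are physically impossible, and requiring
  identical coordinates would miss transmitter echoes with jitter. The
  first occurrence is kept.
- *Speed/heading*: speed valid in [0, max] with max = 25 kn by default
  (inclusive); heading valid in the half-open compass range [0°, 360°).
  Fishing vessels rarely exceed ~16 kn; 25 kn leaves headroom without
  admitting satellite-relay artefacts. CLI-overridable.
- *Coherence*: a ping is incoherent when the implied great-circle speed
  from the previous retained ping of the same vessel exceeds 30 kn
  (inclusive boundary, with a 1e-9 relative guard against round-trip
  rounding). The criterion behind the "not coherent" category is not
  standardised; this implied-speed reading is our rule and runs after
  duplicate and on-land removal so that relocated or echoed pings do not
  poison their neighbours.
- *Harbour buffer*: 2 km radius (customisable), nearest harbour wins,
  exact distance ties break lexicographically by harbour id.
- *On land*: strict interior containment in the supplied coastline
  polygons; boundary points are not flagged. No world coastline is
  bundled; the synthetic module provides one.

## Trip cutting and interpolation

A new track starts after a maximal run of in-harbour pings or after a gap
larger than `max_gap_h` (default 12 h; the native cadence is ~2 h, so 12 h
means at least five consecutive missed transmissions). Only the first and
last in-harbour pings of a trip are retained; candidates with fewer than
3 pings are discarded and counted. Endpoint harbours come from the
in-harbour flag when present, else from the nearest harbour; endpoints are
labelled, never moved or fabricated.

Interpolation resamples each track onto the multiples of the chosen
frequency since 1970-01-01T00:00Z, so that the interpolated databases of
different vessels share snapshot instants across runs. Positions follow a
cubic Hermite spline per coordinate whose knot tangents are the reported
velocity vectors, speed·(sin h, cos h), converted to degrees/second at the
ping's latitude; where speed or heading is missing or flagged invalid the
tangent falls back to the chord (finite-difference) direction. Speeds and
headings of interpolated pings come from the spline's first derivative.
The interpolant passes through native pings exactly and needs no tuning
parameter. On straight constant-speed segments it reduces to linear
interpolation (verified to 1e-6°); around genuine manoeuvres between
2-hourly knots it smooths the true piecewise-linear path, which is the
dominant error source for downstream fishing-point detection near
activity transitions. The domain is [first ping, last ping]; nothing is
extrapolated.

## Enrichment

Depth is bilinear in the four surrounding bathymetry nodes (exact for
planar fields to 1e-9 m); pings outside the grid keep no depth and are
counted. Area assignment uses only the track's focal point — the
arithmetic mean of its *native* ping coordinates, making enrichment
invariant to interpolation frequency — and the first containing polygon in
id order wins with a warning if the layer overlaps. Bathymetry loads from
ESRI ASCII rasters or lon,lat,z text; a local file replaces any online
elevation service so the step is testable offline with the same numerical
contract.

## Métier discovery and classification

Catch profiles (kg per FAO 3-alpha code, optionally divided by trip length
in days) are clustered with k-medoids under Euclidean, Manhattan or
Bray–Curtis dissimilarity; Bray–Curtis is the default because métiers
differ both in which species they take and in relative abundances, and
because catch matrices are sparse and non-normal, which also argues
against any PCA pre-reduction (none is used).

- `pam` solves instances with C(n, k) ≤ 2000 candidate medoid sets exactly
  by enumeration — on such tiny instances enumeration is cheaper than the
  classic heuristic and guarantees the global optimum, which BUILD+SWAP
  does not: there exist 4-point instances where the swap neighbourhood
  traps the standard algorithm in a suboptimal medoid set. Larger
  instances use greedy BUILD seeding plus best-improvement SWAP to a
  swap-local optimum; all ties break to the lowest index, so the result is
  deterministic.
- `clara` draws `n_samples` subsamples of `sample_size` (defaults 100 and
  1000), augments each with the best medoids found so far, runs PAM on the
  subsample, assigns the full dataset and keeps the medoid set with the
  lowest full-data mean dissimilarity. Deterministic per seed.
- `asw` is the mean silhouette s(i) = (b−a)/max(a, b) with the usual
  conventions: singletons score 0, and a = b = 0 (co-located points)
  scores 0. `discover_metiers` picks the k in the searched range with
  maximal full-data ASW and returns the whole (k, ASW) profile for
  inspection.
- Optional outlier removal drops records whose nearest-neighbour
  dissimilarity exceeds the 99th percentile of nearest-neighbour
  dissimilarities (the removal rule is ours; only the option is standard).
- Classification is fuzzy: u_c ∝ d_c^(−2/(m−1)) over the medoids, computed
  in log space so the m → 1⁺ limit degrades gracefully to the crisp
  nearest-medoid rule; zero distance gives full membership (ties split
  equally); m defaults to 2, the customary exponent where none is
  prescribed. All-zero records are unclassifiable and flagged.
- Discovered medoids carry provisional labels M1..Mk until identified:
  `label_medoids` greedily matches medoids to user-supplied reference
  catch profiles by Bray–Curtis on compositions (the automated analogue of
  the manual métier-editing step). No reference profile values are
  bundled; the synthetic module writes its own.

## Linkage, prediction, fishing points

Matching requires the same vessel and positive interval overlap between
the track's [first ping, last ping] and the record's
[departure, arrival]. Many tracks may absorb the same record; a track
overlapping several records takes the largest overlap, exact ties going to
the earliest record start and then the lowest record index. Métier and
gear copy from record to track.

The behaviour-based métier predictor uses a documented 29-dimensional
feature vector — 11 speed quantiles (0–100% by 10), 15 speed-bin fractions
([0,1)..[14,15) kn), trip duration (h), mean |depth| (m), night-ping
fraction (22:00–06:00 UTC) — standardised and fed to a single hidden layer
of 32 units (seeded scikit-learn MLP). A stratified 80/20 split reports
held-out accuracy before refitting on all labelled tracks; unlabelled
tracks receive the argmax label and its probability as confidence. The
architecture and feature set are this package's interpretation of the
neural-network approach; they are deliberately small and deterministic.

A ping is a fishing set position iff its speed lies in the métier's
inclusive [v_min, v_max] window AND (no depth range is set OR |depth| lies
inside it — a missing depth fails a set range) AND (no harbour-distance
rule is set OR the nearest harbour is at least the minimum away). Marking
applies to interpolated pings and uses the ping's reported/derived
instantaneous speed, not implied speed. Shipped defaults cover common
towed gears (OTB/TBB/PTM 2.5–4.5 kn); user threshold files override.

## Effort and indicators

Fishing pings are counted per cell; effort hours = count × interpolation
interval — the explicit formalisation of mapping position counts to hours.
Boundary pings go to the lowest-id cell. Indicator 5 sums the areas of
cells with any effort; indicator 6 accumulates cells by descending effort
(ties by id) until reaching q (default 90%) of the total, *including* the
crossing cell so the covered share is guaranteed ≥ q. Trawled area sums
segment length × OWG over consecutive fishing-ping pairs, with OWG a
per-vessel constant or a function of depth; it telescopes under refinement
on straight segments.

## Synthetic fleet generator

The generator emulates the conditions the chain is designed for: a
rectangular landmass east of a 2°×2° sea box, three harbours ~1 km off the
coast, depth increasing linearly seaward at 500 m per degree of longitude,
and a fleet (default 13 vessels over 30 days at a 120 min cadence,
emulating the scale of the original sample data) alternating harbour
dwells of 6–14 h with trips: steaming at N(10, 1) kn to a gear-specific
ground, fishing, and returning. Trawlers (OTB, trips 26–36 h, grounds
50–450 m) tow straight 1–2.5 h legs at U(2.5, 4.5) kn with gently drifting
heading — long straight tows are how towed gear actually operates, and the
2 h ping cadence makes corner-heavy walks unidentifiable anyway; purse
seiners (PS, trips 10–16 h, grounds 60–200 m) alternate near-zero drifts
with ~8 kn searches, the classic bimodal speed signature. Catches are
Dirichlet draws around métier-specific compositions (trawl: hake, mullet,
shrimp, Norway lobster; seine: anchovy, sardine, mackerel) scaled by
~400 kg/day and a lognormal factor; pairwise Bray–Curtis between mean
compositions exceeds 0.95, comfortably separable. Logbook intervals equal
the true trip limits jittered by ±1 h (less than half the minimum
inter-trip gap, so interval matching remains identifiable). Positions get
N(0, 2×10⁻⁴ °) noise and reported speeds N(0, 0.15 kn) noise; duplicates,
on-land relocations and negative speeds are injected at configurable rates
(defaults 3%/3%/2%, the order of magnitude reported for real national
feeds). Everything is deterministic per seed, and truth tables record each
ping's trip and fishing state, each trip's métier and fishing intervals,
and each injected error.

What the generator does *not* emulate: tide/current drift, vessel
interaction, multi-bout trips with port calls, seasonal métier switching
by vessel, heterogeneous gear widths, reporting lags or species
misreporting in logbooks. Consequently, passing the truth-comparison
scores shows the chain is internally consistent and recovers planted
structure under realistic noise — not that its thresholds or the ANN
transfer unchanged to any particular real fleet.

The end-to-end check runs 20 vessels over 60 days (≈14 000 native pings,
≈950 trips, ≈135 000 interpolated pings) and scores track recovery, métier
agreement (adjusted Rand), fishing precision/recall and match recovery,
all ≥ 0.9 under default noise and error rates; the residual ~6% fishing
error is concentrated at activity transitions, where Hermite smoothing of
the 2 h cadence blends steaming and fishing speeds. Métier-recovery
experiments use 5 000 planted trips with CLARA at 5 subsamples of 500
records (smaller than the 100×1000 defaults; the search is insensitive to
this on well-separated profiles and it keeps the whole suite fast).

## Known limitations

- The store serialises timestamps as ISO text; sub-second precision is
  preserved but not exercised (VMS feeds report whole seconds).
- Timestamps without timezone are interpreted as UTC, the VMS convention.
- Polygon-cell gridding is O(cells × pings); use the regular-grid spec for
  fine partitions.
- The fuzzy classifier's membership depends on the distance's scale for
  m ≠ 2 only through ratios, but mixing distances between discovery and
  classification is not supported.
- `dcf_indicator6` is undefined (raises) on a zero-effort grid.
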