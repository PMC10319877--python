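# Methods

## Scope and data model

`pedtraj` processes one-way pedestrian commute traces: per-trip CSV
files of GPS fixes (course, horizontal accuracy, latitude, longitude,
device speed, timestamp, nickname) sampled nominally at 1 Hz. A trip's
metadata — school code, participant number, transport mode,
companionship — is encoded in the participant nickname
(`ZAF_0001_WALK_ALONE`) and, with the trip date, in the filename
(`2018-11-05_sgv_2603.csv`). Mode tokens are matched against a shipped
bilingual (Catalan/English) synonym table (`data/mode_synonyms.yaml`);
parsing is total — unknown tokens become `unknown` placeholders and an
unrecognised school code flags the trip for manual review rather than
raising.

Timestamps are naive local wall-clock at 1 s resolution; no timezone
arithmetic is done (trips never span a DST change). Coordinates are
written at 6 decimal places (~0.11 m), which bounds the meaningful
precision of all distances.

All step quantities use the time-advanced convention: Δt, d, v at row
*i* describe the interval from fix *i* to fix *i*+1, and the last row of
a processed file carries empty step fields. Distances are haversine
great-circle with mean Earth radius 6 371 008.8 m; at commute scale
(< 10 km) the difference from an ellipsoidal geodesic is orders of
magnitude below the coordinate rounding. The instantaneous velocity
v = d/Δt is authoritative; the device-reported speed column is carried
through files but never used in computation.

## Cleaning stages and their thresholds

The original study applied these steps by inspecting routes on maps, so
an automated re-implementation must make every threshold explicit. All
defaults live in `CleaningPolicy` and are config-overridable:

| parameter | default | role |
|---|---|---|
| `v_nonped` | 2.5 m/s | v_eff cap for unknown-mode trips; kept pedestrian v_eff tops out near 2 m/s, vehicles sit well above |
| `v_outlier_max` | 10 m/s | instantaneous cap; above any running teenager, far below 90 m/s activation spikes |
| `haccuracy_max` | 100 m | reported GPS uncertainty cap |
| `school_radius` | 150 m | endpoint-at-school radius (the protocol has recording start/stop 5–150 m from home) |
| `min_records` | 30 | minimum fixes for a meaningful trip |
| `max_outlier_fraction` | 0.3 | spike fraction above which the whole trip is discarded |
| `endpoint_dwell_radius` / `endpoint_dwell_min` | 20 m / 60 s | terminal indoor-dwell detection |

Outlier removal iterates flag-and-delete passes to a fixed point (at
most 10): a single pass would mislabel the record following a spike,
because its incoming step velocity is only inflated by the spike record
itself. A record is velocity-implicated when **both** its adjacent step
velocities exceed the cap (terminal records: their single adjacent
step), which spares the good neighbours of an isolated teleport. The
terminal dwell cluster — fixes accumulating inside the school where GPS
degrades — is collapsed to its first fix when it spans more than
`endpoint_dwell_min`; we keep one representative record so the trip
still ends at the destination. The whole-trip discard fraction counts
only spike/accuracy removals, not the dwell trim: a long indoor dwell
does not corrupt the walked path, and counting it would discard
otherwise-clean trips that merely idled at the school.

Origin–destination validation requires exactly one endpoint within
`school_radius`, at least `min_records` fixes, and a net displacement of
at least `2 × school_radius`. The displacement clause is what rejects
"scatter" recordings — a cloud of fixes around the school with no
journey in them.

## Geomasking and the disclosure-risk model

The home end of a trace is the sensitive part. The mask strips the
first (home→school) or last (school→home) *t* seconds **of movement**:
leading/trailing zero-velocity fixes do not start the clock but fall
inside the cut, so the removal is always a contiguous prefix xor suffix.
*t* is drawn once per trajectory, uniformly on the integers [20, 50]
(integers match the 1 s cadence; the draw is seeded and reproducible).
The window is measured in elapsed time, not record count, so it is
robust to sampling gaps. Trip direction comes from per-school
configuration when available, else from inference: the endpoint nearest
the school is taken as the destination.

Risk is quantified by spatial k-anonymity with a deliberately simple
model: constant walking speed `v_assumed` = 1.5 m/s for everyone, so a
masked endpoint is consistent with any housing unit within radius
d = v·t, i.e. k = ρ·π·(v·t)² units for district housing density ρ, and
the disclosure risk is 1/k. The shipped district table
(`data/districts.csv`: urban surface in km², housing units, school
mapping) reconstructs the published per-district risks at t = 50 s to
their printed three significant figures, and their unweighted mean
2.72 × 10⁻³. Two of the printed densities (L'Eixample, Viladecans)
differ from the quotient of the printed surface and unit counts in the
last printed digit — the published table appears to have used unrounded
surfaces — so density checks use a 10⁻⁴ relative tolerance; the risks
themselves reproduce exactly at 3 significant figures either way.

## Resampling and validation statistics

Interpolation inserts a fix at every missing integer second, linearly
in latitude/longitude against time (also for accuracy, course and
device speed). Interpolating in coordinate space rather than a
projection differs from the great-circle chord by far less than a
millimetre at city scale. Original fixes are preserved exactly;
afterwards Δt ≡ 1.0 and d ≡ v identically. Duration and endpoints are
invariant; path length is invariant for collinear inserts and can only
shrink toward the chord otherwise. Non-integer-second input timestamps
raise rather than being silently snapped.

MSD(τ) averages the squared displacement over **all** time origins
within a trip, then over trips with equal weight (an `origin="start"`
option uses only the trip start). The autocorrelation of
u = ln(v/v_m) normalises each trip's autocovariance by its own lag-0
variance before averaging, so C(0) = 1 by construction; zero-velocity
steps are excluded from u (ln 0) and counted, and zero-variance trips
are skipped with a log line. Confidence intervals are 95% percentile
bootstrap with 1,000 resamples over trajectories, seeded — the choice
of bootstrap unit (trips, not records) matches the equal-trip-weight
averaging. Velocity histograms use 0.1 m/s bins on [0, 9] and 0.1 bins
on [−5, 2] for u.

## The synthetic cohort generator

`CohortSpec` defaults encode the study conditions the pipeline assumes:

* 10 schools × 8 participants; per-trip base walking speed lognormal
  with mean 1.5 m/s and sd 0.25 across trips, per-second lognormal
  variation (cv 0.3) within trips; trip durations uniform on
  [300, 700] s.
* Routes follow an abstract street lattice, not real map data: the home
  point is drawn 400–1500 m from the school, a Manhattan staircase of
  40–120 m blocks is laid toward it, and leftover trip length is spent
  on side-street detours. This keeps the turn structure that drives
  velocity autocorrelation while removing any street-network
  dependency. The home annulus starts at 400 m so that genuine commutes
  sit clearly inside the OD-validation displacement rule
  (2 × 150 m) even after startup-burst offsets; home coordinates are
  never written to output (the first recorded fix is already away from
  "home", mirroring the privacy protocol).
* Gap model: each step is 1 s with probability 0.83, else 2/3/4/6 s
  with probabilities 0.10/0.05/0.018/0.002 — realising the observed
  structure of 17% of steps longer than 1 s and 99.8% at most 4 s.
* GPS noise is AR(1)-correlated per axis (stationary sd 3 m,
  ρ = 0.998 at 1 s). Receiver error at 1 Hz is strongly autocorrelated;
  white noise of realistic amplitude would add metre-scale jitter to
  every step and swamp walking velocities, which contradicts the
  velocity scale of real kept data.
* Artifacts: 30% of trips get a startup burst of 1–6 scattered fixes
  with 20–90 m/s jump speeds (GPS activation); 30% get a terminal dwell
  cluster of 90–180 s at the destination; contaminants are 10%
  declared-vehicle trips, 5% unlabelled vehicles (6–12 m/s), 5% scatter
  blobs around the school, and 5% trips with no school endpoint; 10% of
  pedestrians omit the mode token.

Every record (clean / outlier / dwell) and every trajectory
(pedestrian / contaminant class) carries a truth label, so
`truth_eval` scores each cleaning stage exactly. `CohortSpec.clean()`
switches off noise, gaps, artifacts, contaminants **and** missing mode
labels — the last because an unlabelled fast walker legitimately trips
the unknown-mode speed rule, and the clean configuration is defined as
one where every trip passes all stages untouched.

What the generator does **not** emulate: real street networks and route
choice, demographic heterogeneity, weather, multipath urban-canyon
error structure, or device-specific sampling quirks. Passing tests
therefore demonstrate that the pipeline recovers known structure under
the stated statistical conditions, not that it is optimal on any
particular real deployment.

## Numerical and design notes

* The ± values in cohort summary tables are standard errors of the
  mean.
* Cohort tables report per-school mean ± s.e., min/max of D and T,
  pooled instantaneous-velocity statistics, and quartiles; empty groups
  are omitted with a log line.
* Masked trips left with fewer than 30 fixes are discarded with a
  recorded reason, as are trips whose step series degenerates.
* Pipeline order is fixed: mode filter → OD validation → outliers →
  geomask → interpolation. Geomasking precedes interpolation so
  resampled files never contain masked-away time. File-level failures
  quarantine the file and continue (crowdsourced cohorts contain
  malformed inputs); a known school code without coordinates is an
  error, an unknown code goes to manual review.
* Test and acceptance problem sizes are chosen so sampling error is
  small relative to the checked tolerances — e.g. the duration-quartile
  recovery check uses an 800-trip clean cohort because at 160 trips the
  sample-quartile standard error (~14 s) is comparable to the 5%
  tolerance band itself.

## Known limitations

* The risk model's constant-speed circle is deliberately rough; it is
  an ambiguity count, not a differential-privacy guarantee, and uses
  district-level housing density rather than cadastral parcels.
* Reorientation angles and tortuosity statistics are out of scope.
* The OD displacement rule means commutes from homes closer than
  ~300 m to school are not validatable; such trips are rare in the
  emulated setting but would need a relaxed policy elsewhere.
* Linear interpolation slightly depresses the mean instantaneous
  velocity (short inserted steps populate the low-v region); D, T and
  v_eff are preserved. The pre/post comparison report quantifies this
  per cohort.
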