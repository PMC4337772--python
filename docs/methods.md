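# Methods

This note documents the models, conventions, and numerical choices behind
`envtrack`, and what the synthetic test battery does and does not
demonstrate about real data.

## Grid model

An environmental variable is an array over 1–4 axes drawn from
`{x, y, z, t}` in a declared CRS.  Coordinates are **cell centers**, the
convention of reanalysis and ocean-color products; a query point therefore
generally falls between four centers, and fractional offsets `(fx, fy)` are
measured between adjacent centers.  Axes must be strictly monotone;
decreasing axes (north-up latitude vectors) and `[0, 360)` longitudes are
normalized at load time (flipped, re-indexed to `[-180, 180)`).

Global regular longitude axes (span = 360°) are treated as circular: the
bracketing cell may straddle the antimeridian, with node columns
`(n−1, 0)`.  This is one of three situations where "more than four"
neighbours arise; the others are inverse-distance weighting with a widened
neighbour ring (`idw_k > 4`) and missing-node fall-through (below).

Temporal queries between the first and last scene bracket exactly; queries
up to one median scene interval beyond an edge clamp to the edge scene with
a warning; anything further is an out-of-domain error.  There is no spatial
extrapolation.  The vertical axis, when present, resolves to the nearest
level only — none of the supported products requires vertical
interpolation in practice.

**Scenes and tiles.**  The spatial plane is cut into `tile_shape` blocks;
one block at one timestamp is a *scene*, the unit of fetching and caching.
`scenes_required` maps a point batch to the de-duplicated scene-key list
sorted by (variable, timestamp index, tile index), which is also the order
in which the annotator processes points — matching the physical layout of
archive files so that reads are batched.

## Coordinate systems and geodesics

Supported projections: WGS84 lon/lat, plate carrée, sinusoidal, Lambert
conformal conic (2 standard parallels), and Albers equal area, implemented
from Snyder's standard formulas.  Lambert and Albers use the full WGS84
ellipsoidal forms (conformal latitude iteration to 1e-13 rad).  The
sinusoidal projection deliberately uses the MODIS authalic sphere radius
6 371 007.181 m rather than the WGS84 ellipsoid, matching the grid
definition of the MODIS products it exists to serve.

Distances are true ellipsoidal geodesics (Vincenty inverse, 1e-12 rad
convergence) on WGS84; this is also what nearest-neighbour and IDW
interpolation use for node weighting.  A spherical-haversine option
(R = 6371 km) is provided — the two differ by at most ~0.5 %, which is
irrelevant for interpolation weights but matters if distances are reported.
Vincenty can fail to converge for nearly antipodal pairs; the
implementation then falls back to a spherical estimate.  No annotation
geometry at realistic scales triggers this.  Note that the reverse bearing
of a segment differs from `forward + 180°` by the meridian convergence
`Δλ sin φ`, so bearing-reversal symmetry is only sub-0.2° for short
segments at low latitude; the test suite checks it there.

## Interpolation

Space first, then time.  For a fix `p(x, y, t)` the four bracketing nodes
are read at the two bracketing scenes; each scene's nodes are interpolated
spatially, and the two spatial values temporally:

- **nearest_neighbour** — the node at minimal geodesic distance.
- **bilinear** — `(1−fx)(1−fy)v1 + fx(1−fy)v2 + (1−fx)fy v3 + fx fy v4`.
  On irregular grids the fractional coordinates are per-cell, i.e. a
  per-cell linear rescaling; this extends the textbook regular-grid method
  without changing it where spacing is constant.
- **inverse_distance_weighted** — Shepard weights `d_k^{-p}` with `p = 2`
  by default, over the `k` nearest non-missing nodes (`k = 4` default;
  larger `k` widens the node ring).  A query within 1 m of a node returns
  that node's value exactly (the weight would otherwise overflow).

Temporal methods: nearest neighbour (midpoint ties resolve to the earlier
scene) and IDW with power 1, which for two samples reduces exactly to
linear interpolation — the natural reading of a two-scene bracket.  Exact
scene-time queries return the scene value with no arithmetic.

**Categorical variables** are forced to nearest-neighbour in both space
and time, so every annotated category is a code actually present in the
data.

**Missing values.**  The file sentinel (`_FillValue`) and NaN both count
as missing.  Missing nodes are dropped and the remaining weights
renormalized (bilinear renormalizes its corner weights; nearest neighbour
falls through to the next-nearest).  Only an all-missing neighborhood
yields a missing annotation, which is flagged and counted, never silently
zero.  All methods produce convex combinations, so annotated values can
never leave the range of the contributing nodes — the property the test
battery checks at scale.

## Derived covariates

Wind direction is reported as the azimuth **toward** which air moves
(`atan2(u, v)`, degrees from north), the convention the tailwind
decomposition requires; a ±180° converter to the meteorological "from"
convention is provided.  For travel heading θ,
`tailwind = u sin θ + v cos θ` and `crosswind = u cos θ − v sin θ`
(positive crosswind = wind from the animal's left; a flag flips the sign
convention).  The decomposition is a rotation, hence the energy identity
`tail² + cross² = u² + v²` and equivariance under joint rotation of wind
and heading.

Flight heading between fixes is the initial geodesic bearing from fix *i*
to fix *i+1*, assigned to fix *i* (forward difference); the last fix
inherits the previous heading and carries no speed.  Duplicate timestamps
within an individual are rejected.

Terrain: Horn's 3×3 kernel for slope and aspect (exact for planes — the
property test), aspect reported as the downslope azimuth and undefined on
flat cells; rugosity is the population standard deviation of the window's
elevations — vector-ruggedness alternatives exist, and the SD definition
is the implemented, documented choice.  Orographic uplift is
`|w| tan(slope) cos(φ_to − φ_upslope)`: positive on windward slopes, odd
under wind reversal, optionally clamped at zero for downslope flow
(default unclamped, both behaviours exposed).  Thermal uplift is the
convective velocity scale `w* = [(g z_i/T) · H/(ρ c_p)]^{1/3}` for
positive sensible heat flux and 0 otherwise, with ρ = 1.225 kg/m³ and
c_p = 1005 J/(kg·K) as overridable defaults; temperatures below 200 are
interpreted as °C and converted.

## Annotation pipeline

Track annotation is a pure function of (track, request, datasets): the
output preserves row order and every input column, adding one column per
requested (variable, method) named `<dataset>.<variable>.<spatial>-<temporal>`.
Area annotation evaluates pixel **centers** of the requested rectangle
(row 0 at the north edge; GeoTIFFs carry the equivalent edge-registered
affine), so requesting a variable's own grid at native resolution with
nearest-neighbour reproduces the stored scene bit-exactly.

Case-study segmentation: *transit* = ground speed strictly greater than
5 m/s **and** longitude in `[−90°, −82.5°)`; *coastal foraging* =
longitude in `[−82.5°, −75°)` at any speed; *other* = everything else.
Bands are half-open on the east so the shared boundary belongs to the
coastal band exclusively.  Travel direction (outbound vs return) is
labelled by the sign of the per-fix longitude change — an interpretation,
since the underlying segmentation protocol does not state one.

## Scene cache

Scenes are materialized by a provider (`key → payload`) at most once,
retried on transient failure, and retained under a capacity limit with
either least-frequently-used eviction (default) or least-recently-used —
production systems describe both, at different storage tiers, so both are
implemented as selectable alternatives rather than a composite score.
Ties break by oldest access then lexicographic key, making eviction fully
deterministic.  Recency uses a logical clock, not wall time, so runs are
reproducible.  The cache is transparent: any capacity, strategy, or
warm/cold state yields bit-identical annotations.

## Synthetic data

The generator provides fields with exact closed-form oracles — affine in
(x, y, t) (for which bilinear + linear-in-time is exact, giving a
machine-precision end-to-end check), sinusoidal (smooth curvature),
categorical mosaics (seeded block codes), uniform and banded winds, and
plane/Gaussian-hill DEMs — plus tracks generated along ellipsoidal
geodesics between waypoints at constant speed with a 90-minute fix
interval by default, a typical seabird GPS duty cycle.  The bundled
island–coast loop scenario places a clockwise loop inside an easterly wind
band so the eastbound outbound legs meet head winds and the westbound
return is assisted: the qualitative signature of the albatross case study,
used as a logic check, not a reproduction of measured values.

What these fixtures do **not** emulate: spatially correlated reanalysis
error structure, clouds/swath gaps of real remote-sensing products, GRIB
and HDF container quirks, or ocean biogeochemistry.  Passing tests
demonstrate the correctness of transformation, interpolation, caching and
derivation logic — not the fidelity of any particular archive.

## Problem sizes and tolerances

The verification battery uses 1,000 random points for the affine oracle
(tolerance 1e-9 relative), 10,000 neighborhoods × 6 method combinations
for convexity (1e-9 slack), 10,000 samples for the wind energy identity
(1e-9 absolute), 100 random planes for Horn exactness, 1,000 round-trip
points per projection (1e-6°), and 1,000 random operation sequences
against a brute-force eviction simulator.  These sizes exercise every
branch while keeping the whole battery in the seconds range on one core.

## Known limitations

- No live fetching from archive providers is included; providers are a
  one-function contract, and the bundled ones serve local data.
- Vertical (z) interpolation is nearest-level only.
- Area requests are accepted in WGS84 lon/lat only (outputs for projected
  native grids are still computed by transforming pixel centers).
- Vincenty's nearly-antipodal weakness is handled by a spherical fallback
  rather than a full Karney implementation.
- The two accession-based case-study counts require downloading the
  deposited tracking study and are not part of the offline battery.
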