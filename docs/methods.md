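# Methods

## Problem and data model

The package compares species occurrence data from two sources with very
different sampling processes: an opportunistic social-media harvest
(`facebook` in the code) and a formal aggregator export (`gbif`). Records
are Darwin-Core-style rows (species key, WGS84 decimal coordinates,
coordinate uncertainty in meters, optional date, source label); a national
checklist supplies each species' taxon group and Red List category
(CR/EN/VU = Threatened; NT, LC, DD nonthreatened, with DD also tabulated
separately); a country boundary polygon defines land. All geometry passes
through shapely; file I/O is plain CSV and GeoJSON.

## Cleaning cascade

Rules run in a fixed order — duplicate, uncertainty, zero-coordinate,
integer-coordinate, at-sea — and the removal report attributes each record
to the first rule that fires, so `input = output + Σ removed` always holds
and the cascade is idempotent.

* **Duplicates** are keyed on (species, source, lon, lat) with coordinates
  rounded to 4 decimals (≈ 11 m); the first record in input order survives.
  Deduplication is deliberately within-source: cross-source near-duplicates
  are subsumed by 1-km thinning, and collapsing them earlier would distort
  per-source record counts.
* **Uncertainty** over 10,000 m ("over" read strictly) removes a record;
  records with *missing* uncertainty are kept by default because dropping
  them is a judgement call, exposed as `drop_missing_uncertainty`.
* **Zero and integer coordinates** require BOTH coordinates to match the
  pattern. A lone integer longitude is common in legitimate data; the pair
  matching mirrors the default of the standard coordinate-cleaning tools.
* **At sea** means not intersecting any land polygon; boundary points count
  as land.

Free-text locality cross-validation (locality incompatible with
coordinates) is out of scope — there is no gazetteer here; the ingest-time
coordinate validity check plus the at-sea rule are the implemented portion.
This is a known limitation.

## Thinning

One record per species per 1-km² cell, on a half-open square grid in the
projected plane (grid arithmetic in meters, origin (0, 0)). This is
resolution-based thinning, not minimum-pairwise-distance thinning; two
records 100 m apart straddling a cell edge both survive. Ties break to the
smallest record id, making the operation deterministic and idempotent.
EOO estimation uses per-source thinning (each source's range is measured
from its own records); overall record counts use combined thinning, where
records of one species from both sources collapse within a cell.

## Projection and EOO

The equal-area projection is the cylindrical equal-area map with standard
parallel 30° on the authalic sphere (R = 6371.0088 km):
x = R·λ·cos φ₀, y = R·sin φ / cos φ₀. This is the spherical form of the
World-Behrmann convention; its area distortion relative to the ellipsoidal
form is far below the 1-km² raster granularity, and it gives a closed-form
map with an exact inverse. A lon/lat rectangle projects to area
R²·Δλ·Δ(sin φ) exactly, which the tests exploit.

Hulls are built in the projected plane (projecting first makes "area of the
hull" well-defined; hulls in degrees would not be area-true) using Andrew's
monotone chain with strict turns: duplicate points are collapsed, collinear
boundary points are not vertices, and fewer than three distinct or all
collinear points yield a status code (`insufficient_points`, `degenerate`)
instead of an area. Such species are excluded from range-size summaries but
always listed with their status.

Raw EOO is the shoelace area of the hull. Masked EOO rasterizes at the grid
resolution and counts cells whose center lies in both hull and land
(boundary-inclusive), restricted to the hull's bounding box. Cell-center
containment is unbiased to first order; its error is bounded by the
boundary band, ≤ 2·perimeter·cell_size, which the tests assert. (A
"one-cell" tolerance would be wrong: a 3,000-km² hull routinely overshoots
by a few km².) Grid-aligned rectangles are recovered exactly.

The criterion-B1 flag is `masked EOO < 20,000 km²`, strict at the
threshold, following the "less than" phrasing of the criterion; it is
advisory, since B1 listing also needs concurring threat conditions.

## Synthetic study conditions

The generator's defaults are the package's study conditions, fixed once:

* **Country**: a star-convex polygon ~2.4° across centered near (90° E,
  23.5° N) (radial jitter keeps it simple by construction), ~150,000 km² of
  land; five cities, two near the interior carrying 65% of the sampling
  weight — emulating recording effort concentrated in the central, urban
  part of a country.
* **Checklist**: largest-remainder apportionment makes group and category
  counts exactly match the requested proportions (default: 55% LC, 25%
  Threatened, 10% NT, 10% DD across eight taxon groups), with the pairing
  of category to group shuffled by seed. Deterministic counts make
  composition tests exact rather than statistical.
* **True ranges**: convex hulls of 12 points in a disc of radius 40–160 km
  around a center uniform in land; areas (intersected with land, computed
  with the same projection operators as the estimator) span roughly
  10³–10⁵ km², the magnitude at which the 20,000-km² threshold
  discriminates.
* **Source profiles**: the facebook-like profile includes Threatened
  species with probability 0.90–0.95 and LC with 0.60; the gbif-like
  profile includes Threatened at 0.02 and LC at 0.95. Record volumes
  default to 5,000 vs 15,000 (a 25%/75% split). These choices reproduce,
  qualitatively, the observed situation in which the social-media source
  holds the large majority of Threatened-species records while the
  aggregator's records are almost entirely LC.
* **Urban bias**: each clean point is, with probability s/(1+s) (strength
  s), drawn from a Gaussian kernel (σ = 15 km) truncated to range ∩ land
  and anchored at the point of that region nearest ONE anchor city drawn
  per species from the city weights; otherwise uniform in range ∩ land.
  The per-species anchor models site fidelity: recorders of a given species
  tend to operate from one urban base, which keeps a heavily urban-biased
  source spatially narrow per species even when it holds many records. A
  per-record independent city draw was tried first and rejected: with
  ~10² records per species, every city inside a range collects points and
  the convex hull spans them, so the "clustered" source paradoxically got
  the larger EOO. Defaults: strength 1.0 (facebook, mixture weight 0.5)
  and 100 (gbif, weight ≈ 0.99). No quantitative calibration of the bias
  magnitude is claimed — the knob is exposed.
* **Contamination**: per-clean-record Bernoulli rates (duplicate 5%,
  zero-coordinate 1%, integer-coordinate 1%, high-uncertainty 3%, at-sea
  2%), each appended record carrying exactly one mode. Clean uncertainties
  are uniform on [10, 5000] m and high-uncertainty ones uniform on
  (10000, 50000] m, bracketing the 10-km threshold from both sides. Flags
  live in a side table keyed by record id and are never written to the
  occurrence table, so the pipeline cannot peek at ground truth.

What the generator does **not** emulate: real geography and real city
locations; taxon-specific recording behaviour (e.g., birds being unusually
well covered in aggregators); temporal structure beyond a uniform random
date; spatially correlated uncertainty; misidentification. Passing tests
therefore demonstrate that the pipeline recovers known structure under
these idealized conditions, not that any particular real-world dataset
would show the same effect sizes.

## Numerical and design choices

* Deterministic everything: fixed seeds propagate through
  `numpy.random.SeedSequence`-derived child seeds; ties break
  lexicographically (smallest record id); apportionment breaks remainder
  ties by key order. Same inputs and seed give byte-identical outputs,
  which the summary writer's checksummed manifest makes checkable.
* Degenerate inputs: empty record sets clean to empty with zero counts;
  species with one estimable source are listed but excluded from paired
  percentages ("comparable" = ok in both sources; a one-sided EOO has no
  defined difference); exact EOO ties do not count as "larger" (strict
  inequality).
* Percentages are written to one decimal; internal values are unrounded.
* Problem sizes in tests and the acceptance script (200 species, 20,000
  records, 1,000-set hull oracle, 100-hull raster checks) were chosen so
  the whole suite completes in well under a minute while keeping binomial
  noise far from the qualitative thresholds being asserted.
* Run-to-run variability: with 200 species the facebook share of
  Threatened-species records is typically 0.85–1.0 but occasionally dips
  near 0.76 when a rare Threatened species enters the gbif-like source and
  draws a large abundance weight; the LC share within the gbif-like source
  stays above 0.95.

## Known limitations

* The projection is spherical; sub-0.1% area differences from the
  ellipsoidal Behrmann projection are absorbed by the raster tolerance but
  would matter for exact cross-tool comparisons.
* The cleaning report's per-rule attribution depends on cascade order
  (the surviving set does not, for the point-wise rules).
* No statistical inference is attached to the source comparisons; the
  summaries are descriptive, matching their intended use.
* Rasterization iterates the hull's bounding box; pathological hulls
  spanning an entire continent at 1-km resolution would be slow, though
  country-scale inputs are fast.
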