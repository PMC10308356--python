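"""Synthetic dual-source occurrence data with known ground truth.

Real occurrence datasets of this kind cannot be redistributed (one source is
manually georeferenced social-media posts, the other a live aggregator
snapshot), so every downstream stage is exercised against a generator that
emulates the structure of such data:

* an irregular country polygon with city-center sampling hotspots,
  concentrated toward the interior so that opportunistic recording is
  biased toward the "central part" of the country;
* a national checklist with taxon groups and Red List categories in exact,
  deterministically apportioned proportions;
* per-species true ranges (convex polygons intersecting land) whose areas
  are ground truth for range-size recovery tests;
* two sampling profiles with different species composition (a social-media
  source skewed toward Threatened species, an aggregator source dominated
  by Least Concern species) and different spatial clustering toward cities;
* contamination with duplicates, zero coordinates, integer coordinates,
  over-threshold coordinate uncertainty, and at-sea points — the failure
  modes the cleaning cascade removes.

Contamination flags and true-range membership travel in a side table keyed
by record_id; they are never written into the standard occurrence table, so
the pipeline under test cannot peek at the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from . import eoo
from .ingest import (CATEGORIES, TAXON_GROUPS, ChecklistEntry, CountryMask,
                     OccurrenceRecord, write_checklist, write_country,
                     write_occurrences)

CONTAMINATION_MODES = ("duplicate", "zero_coord", "integer_coord",
                       "high_uncertainty", "at_sea")

# Study-condition defaults: checklist composition loosely follows a national
# vertebrate+invertebrate Red List (a large LC majority, a substantial
# Threatened minority, some NT and DD).
DEFAULT_GROUP_PROPS = {
    "bird": 0.35, "butterfly": 0.18, "fish": 0.15, "reptile": 0.10,
    "mammal": 0.08, "amphibian": 0.05, "crustacean": 0.05, "other": 0.04,
}
DEFAULT_STATUS_PROPS = {"CR": 0.05, "EN": 0.10, "VU": 0.10,
                        "NT": 0.10, "LC": 0.55, "DD": 0.10}


@dataclass(frozen=True)
class SyntheticCountry:
    land_polygon: Polygon            # simple polygon, WGS84 degrees
    sea_region: shapely.Geometry     # complement of land within a bounding box
    city_centers: tuple[tuple[float, float], ...]
    city_weights: tuple[float, ...]  # sum to 1

    def as_mask(self) -> CountryMask:
        return CountryMask((self.land_polygon,))


@dataclass(frozen=True)
class TrueRange:
    species_id: str
    polygon: Polygon        # convex, WGS84 degrees
    true_area_km2: float    # area of polygon ∩ land in the equal-area plane


@dataclass(frozen=True)
class SamplingProfile:
    """How one data source samples the fauna.

    species_inclusion_prob maps Red List category to the probability that a
    species of that category appears in the source at all;
    urban_bias_strength s mixes city-kernel sampling (weight s/(1+s)) with
    sampling uniform over range ∩ land; contamination_rates are per-clean-
    record Bernoulli rates for each contamination mode.

    The city kernel models site fidelity: for each species, one anchor city
    is drawn from the country's city weights, and kernel points are a
    bivariate Gaussian (sd ``city_kernel_sigma_km``) truncated to
    range ∩ land, centered on the point of that region nearest the anchor
    city. Opportunistic recorders of one species tend to operate from one
    urban base, which is what keeps heavily urban-biased sources spatially
    narrow per species even when they hold many records.
    """

    source_label: str
    species_inclusion_prob: dict[str, float]
    urban_bias_strength: float = 0.0
    contamination_rates: dict[str, float] = field(default_factory=dict)
    city_kernel_sigma_km: float = 15.0

    def __post_init__(self):
        for cat, p in self.species_inclusion_prob.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("inclusion probabilities must be in [0, 1]")
        for mode, r in self.contamination_rates.items():
            if mode not in CONTAMINATION_MODES:
                raise ValueError(f"unknown contamination mode {mode!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError("contamination rates must be in [0, 1]")
        if self.urban_bias_strength < 0:
            raise ValueError("urban_bias_strength must be nonnegative")

    @property
    def urban_weight(self) -> float:
        s = self.urban_bias_strength
        return s / (1.0 + s)


DEFAULT_CONTAMINATION = {"duplicate": 0.05, "zero_coord": 0.01,
                         "integer_coord": 0.01, "high_uncertainty": 0.03,
                         "at_sea": 0.02}

#: Social-media-like source: strongly includes Threatened species, spreads
#: spatially across ranges (weak urban clustering).
FACEBOOK_PROFILE = SamplingProfile(
    source_label="facebook",
    species_inclusion_prob={"CR": 0.95, "EN": 0.95, "VU": 0.90,
                            "NT": 0.70, "LC": 0.60, "DD": 0.60},
    urban_bias_strength=1.0,
    contamination_rates=dict(DEFAULT_CONTAMINATION),
)

#: Aggregator-like source: almost exclusively Least Concern species, records
#: strongly clustered around cities.
GBIF_PROFILE = SamplingProfile(
    source_label="gbif",
    species_inclusion_prob={"CR": 0.02, "EN": 0.02, "VU": 0.02,
                            "NT": 0.05, "LC": 0.95, "DD": 0.05},
    urban_bias_strength=100.0,
    contamination_rates=dict(DEFAULT_CONTAMINATION),
)

_CENTER_LON, _CENTER_LAT = 90.0, 23.5  # tropical study region
_BASE_RADIUS_DEG = 1.2


def make_country(seed: int) -> SyntheticCountry:
    """Deterministic irregular country polygon with city hotspots.

    A star-convex polygon (radially jittered, hence simple by construction)
    a few degrees across, with 5 cities: two high-weight cities near the
    interior and three low-weight peripheral ones.
    """
    rng = np.random.default_rng(seed)
    n_vert = 16
    angles = np.linspace(0.0, 2.0 * math.pi, n_vert, endpoint=False)
    angles = angles + rng.uniform(-0.08, 0.08, n_vert)
    radii = _BASE_RADIUS_DEG * rng.uniform(0.75, 1.25, n_vert)
    lon = _CENTER_LON + radii * np.cos(angles)
    lat = _CENTER_LAT + radii * np.sin(angles)
    land = Polygon(np.column_stack([lon, lat]))
    assert land.is_valid

    cities: list[tuple[float, float]] = []
    # two central cities: small offsets from the centroid
    cx, cy = land.centroid.x, land.centroid.y
    for _ in range(2):
        while True:
            p = (cx + rng.uniform(-0.25, 0.25), cy + rng.uniform(-0.25, 0.25))
            if land.contains(Point(p)):
                break
        cities.append(p)
    # three peripheral cities at ~60% of the local radius
    for _ in range(3):
        while True:
            a = rng.uniform(0, 2 * math.pi)
            r = 0.6 * _BASE_RADIUS_DEG * rng.uniform(0.8, 1.0)
            p = (cx + r * math.cos(a), cy + r * math.sin(a))
            if land.contains(Point(p)):
                break
        cities.append(p)
    weights = np.array([0.35, 0.30, 0.15, 0.10, 0.10])
    sea = box(*shapely.buffer(land, 1.0, quad_segs=2).bounds).difference(land)
    return SyntheticCountry(land, sea, tuple(cities), tuple(weights / weights.sum()))


def _apportion(n: int, props: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among keys with given proportions."""
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, expected 1")
    keys = sorted(props)  # deterministic tie-breaking by key
    quotas = {k: n * props[k] for k in keys}
    counts = {k: int(math.floor(quotas[k])) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def generate_checklist(
    n_species: int,
    group_props: dict[str, float] | None = None,
    status_props: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ChecklistEntry]:
    """Checklist with exact (largest-remainder) group and status composition.

    Group and status marginals are both exact; the pairing of statuses to
    groups is shuffled deterministically from the seed.
    """
    group_props = group_props if group_props is not None else DEFAULT_GROUP_PROPS
    status_props = status_props if status_props is not None else DEFAULT_STATUS_PROPS
    unknown = set(group_props) - set(TAXON_GROUPS)
    if unknown:
        raise ValueError(f"unknown taxon groups: {sorted(unknown)}")
    unknown = set(status_props) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    group_counts = _apportion(n_species, group_props)
    status_counts = _apportion(n_species, status_props)
    groups = [g for g in sorted(group_counts) for _ in range(group_counts[g])]
    statuses = [s for s in sorted(status_counts) for _ in range(status_counts[s])]
    rng = np.random.default_rng(seed)
    statuses = [statuses[i] for i in rng.permutation(n_species)]
    width = max(4, len(str(n_species)))
    return [
        ChecklistEntry(
            species_id=f"sp{i + 1:0{width}d}",
            scientific_name=f"Taxonomus species{i + 1}",
            taxon_group=groups[i],
            category=statuses[i],
        )
        for i in range(n_species)
    ]


def _sample_in_region(rng, region, n: int, max_batches: int = 200) -> np.ndarray:
    """Uniform points (projected km) inside a shapely region, by rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        m = max(4 * (n - got), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(region, xs, ys)
        pts = np.column_stack([xs[ok], ys[ok]])
        out.append(pts)
        got += len(pts)
        if got >= n:
            break
    if got < n:
        raise RuntimeError("rejection sampling failed; region too thin")
    return np.concatenate(out)[:n]


def generate_true_ranges(
    checklist: list[ChecklistEntry],
    country: SyntheticCountry,
    seed: int,
    radius_km_bounds: tuple[float, float] = (40.0, 160.0),
) -> list[TrueRange]:
    """One convex true range per species, intersecting land.

    Each range is the convex hull of 12 points in a disc of random radius
    around a center drawn inside land. Areas span roughly 10^3..10^5 km^2
    after land masking, the magnitude at which the criterion-B1 threshold
    (20,000 km^2) discriminates. true_area_km2 uses the same projection and
    the exact vector intersection with land.
    """
    if not checklist:
        raise ValueError("checklist is empty")
    rng = np.random.default_rng(seed)
    proj = eoo.ProjectionSpec()
    land_proj = eoo.project_geometry(country.land_polygon, proj)
    centers = _sample_in_region(rng, land_proj, len(checklist))
    ranges: list[TrueRange] = []
    for entry, (cx, cy) in zip(checklist, centers):
        radius = rng.uniform(*radius_km_bounds)
        ang = rng.uniform(0, 2 * math.pi, 12)
        rad = radius * np.sqrt(rng.uniform(0, 1, 12))
        pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        hull = eoo.convex_hull(pts)
        poly_proj = Polygon(hull)
        area = poly_proj.intersection(land_proj).area
        lons, lats = eoo.unproject(hull[:, 0], hull[:, 1], proj)
        ranges.append(TrueRange(entry.species_id,
                                Polygon(np.column_stack([lons, lats])), float(area)))
    return ranges


def _random_dates(rng, n: int) -> list[str | None]:
    days = rng.integers(0, 6500, n)  # ~18 years of observation history
    base = np.datetime64("2005-01-01")
    dates = base + days.astype("timedelta64[D]")
    missing = rng.random(n) < 0.1
    return [None if m else str(d) for d, m in zip(dates, missing)]


def sample_occurrences(
    ranges: list[TrueRange],
    checklist: list[ChecklistEntry],
    country: SyntheticCountry,
    profile: SamplingProfile,
    n_target: int,
    seed: int,
) -> tuple[list[OccurrenceRecord], pd.DataFrame]:
    """Draw one source's occurrence records plus the ground-truth side table.

    Species enter the source by a Bernoulli draw on their category's
    inclusion probability; n_target clean records are then allocated across
    included species by a multinomial with lognormal abundance weights.
    Each clean point comes either from a truncated Gaussian kernel around a
    weighted random city (probability s/(1+s)) or uniformly from
    range ∩ land. Contaminated records are appended afterwards at Bernoulli
    rates per clean record, one mode each, and flagged only in the returned
    side table (columns: record_id, contamination_type, inside_true_range).
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    range_by_sp = {r.species_id: r for r in ranges}
    missing = [e.species_id for e in checklist if e.species_id not in range_by_sp]
    if missing:
        raise ValueError(f"species without true ranges: {missing[:5]}")

    rng = np.random.default_rng(seed)
    proj = eoo.ProjectionSpec()
    land_proj = eoo.project_geometry(country.land_polygon, proj)
    cities_proj = np.array([eoo.project(c[0], c[1], proj) for c in country.city_centers])
    city_w = np.asarray(country.city_weights)

    incl = np.array([rng.random() < profile.species_inclusion_prob.get(e.category, 0.0)
                     for e in checklist])
    included = [e for e, ok in zip(checklist, incl) if ok]
    records: list[OccurrenceRecord] = []
    truth_rows: list[tuple[str, str, bool]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{profile.source_label}-{counter:07d}"

    clean_pts_proj: list[np.ndarray] = []
    clean_species: list[str] = []
    if included:
        weights = rng.lognormal(0.0, 0.75, len(included))
        alloc = rng.multinomial(n_target, weights / weights.sum())
        sigma = profile.city_kernel_sigma_km
        w_urban = profile.urban_weight
        for entry, k in zip(included, alloc):
            if k == 0:
                continue
            region = eoo.project_geometry(
                range_by_sp[entry.species_id].polygon, proj).intersection(land_proj)
            if region.is_empty or region.area <= 0:
                region = land_proj
            n_urban = int(rng.binomial(k, w_urban))
            pts = []
            if n_urban:
                anchor_city = cities_proj[rng.choice(len(cities_proj), p=city_w)]
                pts.append(_kernel_points(rng, region, anchor_city, sigma, n_urban))
            if k - n_urban:
                pts.append(_sample_in_region(rng, region, k - n_urban))
            pts = np.concatenate(pts) if pts else np.empty((0, 2))
            clean_pts_proj.append(pts)
            clean_species.extend([entry.species_id] * k)

    if clean_pts_proj:
        all_pts = np.concatenate(clean_pts_proj)
        lons, lats = eoo.unproject(all_pts[:, 0], all_pts[:, 1], proj)
        uncs = rng.uniform(10.0, 5000.0, len(all_pts))
        dates = _random_dates(rng, len(all_pts))
        for sp, lo, la, un, dt in zip(clean_species, lons, lats, uncs, dates):
            rid = next_id()
            records.append(OccurrenceRecord(rid, sp, profile.source_label,
                                            float(lo), float(la), float(un), dt))
            truth_rows.append((rid, "none", True))

    n_clean = len(records)
    rates = profile.contamination_rates
    clean_snapshot = list(records)

    # duplicates: exact copies of clean records under a fresh record_id
    if rates.get("duplicate", 0.0) > 0 and n_clean:
        dup_mask = rng.random(n_clean) < rates["duplicate"]
        for r, is_dup in zip(clean_snapshot, dup_mask):
            if is_dup:
                rid = next_id()
                records.append(OccurrenceRecord(rid, r.species_id, r.source,
                                                r.lon, r.lat, r.uncertainty_m,
                                                r.event_date))
                truth_rows.append((rid, "duplicate", True))

    land_geo = country.land_polygon
    minx, miny, maxx, maxy = land_geo.bounds
    sp_pool = [e.species_id for e in included] or [checklist[0].species_id]

    def random_species() -> str:
        return sp_pool[rng.integers(0, len(sp_pool))]

    def in_range(sp: str, lon: float, lat: float) -> bool:
        return bool(shapely.intersects_xy(range_by_sp[sp].polygon, lon, lat))

    for _ in range(int(rng.binomial(n_clean, rates.get("zero_coord", 0.0)))):
        sp, rid = random_species(), next_id()
        records.append(OccurrenceRecord(rid, sp, profile.source_label, 0.0, 0.0,
                                        float(rng.uniform(10, 5000)), None))
        truth_rows.append((rid, "zero_coord", in_range(sp, 0.0, 0.0)))

    for _ in range(int(rng.binomial(n_clean, rates.get("integer_coord", 0.0)))):
        lon = float(rng.integers(int(minx), int(maxx) + 1))
        lat = float(rng.integers(int(miny), int(maxy) + 1))
        if lon == 0.0 and lat == 0.0:
            lon = float(int(maxx))
        sp, rid = random_species(), next_id()
        records.append(OccurrenceRecord(rid, sp, profile.source_label, lon, lat,
                                        float(rng.uniform(10, 5000)), None))
        truth_rows.append((rid, "integer_coord", in_range(sp, lon, lat)))

    n_high = int(rng.binomial(n_clean, rates.get("high_uncertainty", 0.0)))
    if n_high:
        pts = _sample_in_region(rng, land_proj, n_high)
        lons, lats = eoo.unproject(pts[:, 0], pts[:, 1], proj)
        for lo, la in zip(np.atleast_1d(lons), np.atleast_1d(lats)):
            sp, rid = random_species(), next_id()
            unc = float(rng.uniform(10_000.0, 50_000.0))
            unc = max(unc, math.nextafter(10_000.0, math.inf))  # strictly over 10 km
            records.append(OccurrenceRecord(rid, sp, profile.source_label,
                                            float(lo), float(la), unc, None))
            truth_rows.append((rid, "high_uncertainty", in_range(sp, float(lo), float(la))))

    n_sea = int(rng.binomial(n_clean, rates.get("at_sea", 0.0)))
    if n_sea:
        sea = country.sea_region
        got = 0
        sminx, sminy, smaxx, smaxy = sea.bounds
        while got < n_sea:
            xs = rng.uniform(sminx, smaxx, 4 * (n_sea - got) + 16)
            ys = rng.uniform(sminy, smaxy, len(xs))
            ok = shapely.contains_xy(sea, xs, ys)
            for lo, la in zip(xs[ok], ys[ok]):
                if got >= n_sea:
                    break
                if float(lo).is_integer() and float(la).is_integer():
                    continue
                sp, rid = random_species(), next_id()
                records.append(OccurrenceRecord(rid, sp, profile.source_label,
                                                float(lo), float(la),
                                                float(rng.uniform(10, 5000)), None))
                truth_rows.append((rid, "at_sea", in_range(sp, float(lo), float(la))))
                got += 1

    truth = pd.DataFrame(truth_rows,
                         columns=["record_id", "contamination_type", "inside_true_range"])
    return records, truth


def _kernel_points(rng, region, anchor_city, sigma_km, n,
                   max_rounds: int = 80) -> np.ndarray:
    """Truncated Gaussian kernel samples inside region, anchored at the point
    of the region nearest the anchor city (site fidelity). Falls back to
    uniform sampling only if the truncated kernel cannot fill the request."""
    from shapely.ops import nearest_points

    anchor = np.asarray(nearest_points(region, Point(anchor_city))[0].coords[0])
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_rounds):
        m = max(4 * (n - got), 64)
        pts = anchor + rng.normal(0.0, sigma_km, (m, 2))
        ok = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
        pts = pts[ok]
        out.append(pts)
        got += len(pts)
        if got >= n:
            break
    if got >= n:
        return np.concatenate(out)[:n]
    out.append(_sample_in_region(rng, region, n - got))
    return np.concatenate(out)[:n]


def write_dataset(
    out_dir,
    country: SyntheticCountry,
    checklist: list[ChecklistEntry],
    records: list[OccurrenceRecord],
    truth: pd.DataFrame,
) -> None:
    """Write the standard tables plus the ground-truth side table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_occurrences(records, out / "occurrences.csv")
    write_checklist(checklist, out / "checklist.csv")
    write_country(country.as_mask(), out / "country.geojson")
    truth.to_csv(out / "ground_truth.csv", index=False)
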