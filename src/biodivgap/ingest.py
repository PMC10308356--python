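"""Readers and writers for occurrence tables, checklists and country geometry.

Column names follow Darwin Core where a term exists (decimalLatitude,
decimalLongitude, coordinateUncertaintyInMeters, eventDate) so that real
GBIF exports map onto the occurrence format with a column rename at most.
Ingest is lossless for accepted rows: writers reproduce accepted rows
field-for-field, and rows that cannot become records are returned in a
rejection log with a reason rather than silently dropped.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Iterable

import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.polygon import orient

SOURCES = ("facebook", "gbif")
TAXON_GROUPS = ("amphibian", "bird", "butterfly", "crustacean", "fish",
                "mammal", "reptile", "other")
CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD")
THREATENED_CATEGORIES = frozenset({"CR", "EN", "VU"})

OCCURRENCE_COLUMNS = ("record_id", "species_id", "source", "decimalLongitude",
                      "decimalLatitude", "coordinateUncertaintyInMeters", "eventDate")
CHECKLIST_COLUMNS = ("species_id", "scientificName", "taxonGroup", "category")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced observation of one species from one source."""

    record_id: str
    species_id: str
    source: str
    lon: float
    lat: float
    uncertainty_m: float | None = None
    event_date: str | None = None


@dataclass(frozen=True)
class ChecklistEntry:
    """A checklist species with its taxon group and national Red List category."""

    species_id: str
    scientific_name: str
    taxon_group: str
    category: str

    @property
    def threatened(self) -> bool:
        return self.category in THREATENED_CATEGORIES


@dataclass(frozen=True)
class CountryMask:
    """Terrestrial polygons (WGS84 degrees) used for at-sea tests and masking."""

    land_polygons: tuple[Polygon, ...]


@dataclass(frozen=True)
class Rejection:
    row_index: int  # 0-based data-row position in the input file
    record_id: str
    reason: str  # bad_coordinate | missing_species | duplicate_record_id


def _parse_float(text: str) -> float | None:
    try:
        v = float(text)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def read_occurrences(
    path, source_override: str | None = None
) -> tuple[list[OccurrenceRecord], list[Rejection]]:
    """Read an occurrence CSV; every row becomes a record or a logged rejection.

    Row order is preserved. A missing required column is a hard error; bad
    coordinates, missing species and duplicate record ids are soft rejections.
    """
    records: list[OccurrenceRecord] = []
    rejections: list[Rejection] = []
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in OCCURRENCE_COLUMNS:
            if col == "source" and source_override is not None:
                continue
            if col not in header:
                raise ValueError(f"missing required column: {col}")
        for i, row in enumerate(reader):
            rid = (row.get("record_id") or "").strip()
            species = (row.get("species_id") or "").strip()
            lon = _parse_float(row.get("decimalLongitude", ""))
            lat = _parse_float(row.get("decimalLatitude", ""))
            if not species:
                rejections.append(Rejection(i, rid, "missing_species"))
                continue
            if (lon is None or lat is None or not (-180.0 <= lon <= 180.0)
                    or not (-90.0 <= lat <= 90.0)):
                rejections.append(Rejection(i, rid, "bad_coordinate"))
                continue
            if rid in seen_ids:
                rejections.append(Rejection(i, rid, "duplicate_record_id"))
                continue
            seen_ids.add(rid)
            unc = _parse_float(row.get("coordinateUncertaintyInMeters", ""))
            date = (row.get("eventDate") or "").strip() or None
            source = source_override or (row.get("source") or "").strip()
            records.append(OccurrenceRecord(rid, species, source, lon, lat, unc, date))
    return records, rejections


def write_occurrences(records: Iterable[OccurrenceRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(OCCURRENCE_COLUMNS)
        for r in records:
            w.writerow([
                r.record_id, r.species_id, r.source, repr(r.lon), repr(r.lat),
                "" if r.uncertainty_m is None else repr(r.uncertainty_m),
                r.event_date or "",
            ])


def read_checklist(path) -> list[ChecklistEntry]:
    """Read a checklist CSV; duplicate species ids or unknown categories are errors."""
    entries: list[ChecklistEntry] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in CHECKLIST_COLUMNS:
            if col not in header:
                raise ValueError(f"missing required column: {col}")
        for row in reader:
            sid = row["species_id"].strip()
            if sid in seen:
                raise ValueError(f"duplicate species_id: {sid}")
            seen.add(sid)
            cat = row["category"].strip()
            if cat not in CATEGORIES:
                raise ValueError(f"unknown Red List category: {cat!r}")
            group = row["taxonGroup"].strip()
            if group not in TAXON_GROUPS:
                raise ValueError(f"unknown taxon group: {group!r}")
            entries.append(ChecklistEntry(sid, row["scientificName"].strip(), group, cat))
    return entries


def write_checklist(entries: Iterable[ChecklistEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CHECKLIST_COLUMNS)
        for e in entries:
            w.writerow([e.species_id, e.scientific_name, e.taxon_group, e.category])


def _normalize_polygon(poly: Polygon) -> Polygon:
    if not poly.is_valid:
        raise ValueError("self-intersecting or otherwise invalid polygon ring")
    return orient(poly, sign=1.0)  # outer ring counter-clockwise


def read_country(path) -> CountryMask:
    """Read a GeoJSON country boundary into a :class:`CountryMask`.

    Accepts Feature/FeatureCollection/raw geometry with Polygon or
    MultiPolygon members; rings are validated simple and re-oriented
    outer-counter-clockwise.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    polys: list[Polygon] = []
    for g in geoms:
        if isinstance(g, Polygon):
            polys.append(_normalize_polygon(g))
        elif isinstance(g, MultiPolygon):
            polys.extend(_normalize_polygon(p) for p in g.geoms)
        else:
            raise ValueError(f"unsupported geometry type: {g.geom_type}")
    if not polys:
        raise ValueError("no polygon features in country file")
    if sum(p.area for p in polys) <= 0:
        raise ValueError("country mask has zero area")
    return CountryMask(tuple(polys))


def write_country(country: CountryMask, path) -> None:
    geom = (country.land_polygons[0] if len(country.land_polygons) == 1
            else MultiPolygon(country.land_polygons))
    gj = {"type": "Feature", "properties": {"name": "land"}, "geometry": mapping(geom)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": [gj]}, fh)


def land_union(country: CountryMask):
    """Union of the land polygons as one shapely geometry (degrees)."""
    return shapely.union_all([*country.land_polygons])
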