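"""Record-cleaning cascade for occurrence data.

Rules, applied in a fixed order with each removal attributed to the first
rule that fires:

1. duplicate     — same (species, source) and coordinates equal after
                   rounding to ``duplicate_coord_decimals`` (default 4,
                   about 11 m); first record in input order survives
2. uncertainty   — coordinate uncertainty strictly greater than
                   ``max_uncertainty_m`` (default 10 km); missing
                   uncertainty is kept unless ``drop_missing_uncertainty``
3. zero_coord    — lon == 0 and lat == 0 exactly
4. integer_coord — both lon and lat exact integers
5. at_sea        — point not on any land polygon (boundary counts as land)

A lone zero or lone integer coordinate is legitimate in real data, so the
zero/integer rules require both coordinates to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .ingest import CountryMask, OccurrenceRecord, land_union

RULES = ("duplicate", "uncertainty", "zero_coord", "integer_coord", "at_sea")


@dataclass(frozen=True)
class CleanConfig:
    max_uncertainty_m: float = 10_000.0
    duplicate_coord_decimals: int = 4
    drop_missing_uncertainty: bool = False
    filters_enabled: tuple[str, ...] = RULES

    def __post_init__(self):
        if self.max_uncertainty_m <= 0:
            raise ValueError("max_uncertainty_m must be positive")
        unknown = set(self.filters_enabled) - set(RULES)
        if unknown:
            raise ValueError(f"unknown cleaning rules: {sorted(unknown)}")


@dataclass
class CleanReport:
    input_count: int
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})
    output_count: int = 0

    def check(self) -> None:
        assert self.input_count - sum(self.removed.values()) == self.output_count


def drop_duplicates(
    records: Sequence[OccurrenceRecord], decimals: int = 4
) -> tuple[list[OccurrenceRecord], int]:
    """Keep the first record per (species, source, rounded lon, rounded lat)."""
    seen: set[tuple] = set()
    kept: list[OccurrenceRecord] = []
    removed = 0
    for r in records:
        key = (r.species_id, r.source, round(r.lon, decimals), round(r.lat, decimals))
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(r)
    return kept, removed


def filter_uncertainty(
    records: Sequence[OccurrenceRecord],
    max_uncertainty_m: float = 10_000.0,
    drop_missing: bool = False,
) -> tuple[list[OccurrenceRecord], int]:
    """Drop records whose uncertainty exceeds the threshold ("over" is strict)."""
    kept = []
    for r in records:
        if r.uncertainty_m is None:
            if not drop_missing:
                kept.append(r)
        elif r.uncertainty_m <= max_uncertainty_m:
            kept.append(r)
    return kept, len(records) - len(kept)


def filter_zero_coords(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], int]:
    kept = [r for r in records if not (r.lon == 0.0 and r.lat == 0.0)]
    return kept, len(records) - len(kept)


def filter_integer_coords(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], int]:
    kept = [r for r in records
            if not (float(r.lon).is_integer() and float(r.lat).is_integer())]
    return kept, len(records) - len(kept)


def filter_at_sea(
    records: Sequence[OccurrenceRecord], country: CountryMask
) -> tuple[list[OccurrenceRecord], int]:
    """Drop records not on land; points on a land boundary are retained."""
    if not records:
        return [], 0
    land = land_union(country)
    xs = np.array([r.lon for r in records])
    ys = np.array([r.lat for r in records])
    on_land = shapely.intersects_xy(land, xs, ys)  # boundary-inclusive
    kept = [r for r, ok in zip(records, on_land) if ok]
    return kept, len(records) - len(kept)


def clean(
    records: Sequence[OccurrenceRecord],
    country: CountryMask,
    config: CleanConfig = CleanConfig(),
) -> tuple[list[OccurrenceRecord], CleanReport]:
    """Run the full cascade; each removal is attributed to the first rule firing."""
    report = CleanReport(input_count=len(records))
    current = list(records)
    for rule in config.filters_enabled:
        if rule == "duplicate":
            current, n = drop_duplicates(current, config.duplicate_coord_decimals)
        elif rule == "uncertainty":
            current, n = filter_uncertainty(
                current, config.max_uncertainty_m, config.drop_missing_uncertainty)
        elif rule == "zero_coord":
            current, n = filter_zero_coords(current)
        elif rule == "integer_coord":
            current, n = filter_integer_coords(current)
        elif rule == "at_sea":
            current, n = filter_at_sea(current, country)
        report.removed[rule] = n
    report.output_count = len(current)
    report.check()
    return current, report
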