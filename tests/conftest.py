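import numpy as np
import pytest
from shapely.geometry import Polygon

from biodivgap.ingest import CountryMask, OccurrenceRecord


@pytest.fixture(scope="session")
def square_country() -> CountryMask:
    """A 2x2-degree all-land square: (90..92 E, 23..25 N)."""
    return CountryMask((Polygon([(90, 23), (92, 23), (92, 25), (90, 25)]),))


def rec(rid, sp="sp1", source="facebook", lon=90.5, lat=23.5, unc=100.0, date=None):
    return OccurrenceRecord(rid, sp, source, lon, lat, unc, date)


@pytest.fixture
def cascade_records() -> list[OccurrenceRecord]:
    """Twelve records engineered so the cleaning cascade removes exactly one
    batch per rule: 6 clean, 2 duplicates of kept records, 1 over-threshold
    uncertainty, 1 zero-coordinate, 1 integer-coordinate, 1 at sea."""
    return [
        rec("r01", sp="spA", lon=90.40001, lat=23.70001),
        rec("r02", sp="spB", lon=91.123456, lat=24.654321),
        rec("r03", sp="spC", lon=90.8, lat=23.2, unc=None),
        rec("r04", sp="spA", source="gbif", lon=90.40001, lat=23.70001),
        rec("r05", sp="spD", lon=91.9, lat=24.9),
        rec("r06", sp="spE", lon=90.1, lat=24.1),
        # duplicates of r01 (4-decimal rounding collision) and r02 (exact)
        rec("r07", sp="spA", lon=90.40004, lat=23.70004),
        rec("r08", sp="spB", lon=91.123456, lat=24.654321),
        rec("r09", sp="spF", lon=90.6, lat=23.6, unc=20000.0),
        rec("r10", sp="spG", lon=0.0, lat=0.0),
        rec("r11", sp="spH", lon=91.0, lat=24.0),
        rec("r12", sp="spI", lon=89.3, lat=22.2),
    ]


@pytest.fixture(scope="session")
def tiny_world():
    """Small synthetic world shared by generator-driven tests."""
    from biodivgap import synthetic_data as sd

    country = sd.make_country(424242)
    checklist = sd.generate_checklist(8, group_props={"bird": 1.0},
                                      status_props={"LC": 0.5, "EN": 0.5}, seed=7)
    ranges = sd.generate_true_ranges(checklist, country, 11)
    return country, checklist, ranges


def random_contaminated_batch(tiny_world, seed, n_target=60):
    from biodivgap import synthetic_data as sd

    country, checklist, ranges = tiny_world
    profile = sd.SamplingProfile(
        source_label="facebook",
        species_inclusion_prob={c: 1.0 for c in ("CR", "EN", "VU", "NT", "LC", "DD")},
        urban_bias_strength=0.5,
        contamination_rates={"duplicate": 0.10, "zero_coord": 0.05,
                             "integer_coord": 0.05, "high_uncertainty": 0.08,
                             "at_sea": 0.05},
    )
    return sd.sample_occurrences(ranges, checklist, country, profile, n_target, seed)
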