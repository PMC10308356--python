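import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point

from biodivgap import eoo
from biodivgap import synthetic_data as sd


class TestMakeCountry:
    def test_deterministic_given_seed(self):
        a, b = sd.make_country(1), sd.make_country(1)
        assert list(a.land_polygon.exterior.coords) == list(b.land_polygon.exterior.coords)
        assert a.city_centers == b.city_centers
        assert a.city_weights == b.city_weights

    def test_seed_sensitivity(self):
        a, b = sd.make_country(1), sd.make_country(2)
        assert list(a.land_polygon.exterior.coords) != list(b.land_polygon.exterior.coords)

    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_invariants(self, seed):
        c = sd.make_country(seed)
        assert c.land_polygon.is_valid and c.land_polygon.is_simple
        assert len(c.city_centers) >= 3
        assert all(c.land_polygon.contains(Point(p)) for p in c.city_centers)
        assert math.isclose(sum(c.city_weights), 1.0, rel_tol=1e-12)
        assert c.sea_region.disjoint(c.land_polygon.buffer(-1e-9))


class TestGenerateChecklist:
    def test_exact_apportionment(self):
        status_props = {"CR": .1, "EN": .1, "VU": .1, "NT": .1, "LC": .5, "DD": .1}
        entries = sd.generate_checklist(100, {"bird": 1.0}, status_props, seed=0)
        counts = {c: sum(e.category == c for e in entries) for c in status_props}
        assert counts == {"CR": 10, "EN": 10, "VU": 10, "NT": 10, "LC": 50, "DD": 10}

    def test_full_checklist_size(self):
        entries = sd.generate_checklist(1619, seed=0)
        assert len(entries) == 1619
        assert len({e.species_id for e in entries}) == 1619

    def test_single_group(self):
        entries = sd.generate_checklist(3, {"bird": 1.0}, {"LC": 1.0}, seed=0)
        assert all(e.taxon_group == "bird" for e in entries)

    def test_group_marginal_exact_with_defaults(self):
        entries = sd.generate_checklist(200, seed=3)
        counts = {g: sum(e.taxon_group == g for e in entries)
                  for g in sd.DEFAULT_GROUP_PROPS}
        # largest-remainder apportionment: every count within 1 of n*p
        for g, p in sd.DEFAULT_GROUP_PROPS.items():
            assert abs(counts[g] - 200 * p) < 1.0

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sd.generate_checklist(10, {"bird": 0.5}, {"LC": 1.0}, seed=0)

    def test_deterministic(self):
        assert sd.generate_checklist(50, seed=5) == sd.generate_checklist(50, seed=5)


class TestGenerateTrueRanges:
    def test_invariants_and_determinism(self, tiny_world):
        country, checklist, ranges = tiny_world
        assert len(ranges) == len(checklist)
        for tr in ranges:
            assert tr.polygon.intersects(country.land_polygon)
            assert tr.true_area_km2 > 0
        again = sd.generate_true_ranges(checklist, country, 11)
        assert [list(r.polygon.exterior.coords) for r in again] == \
               [list(r.polygon.exterior.coords) for r in ranges]

    def test_true_area_consistent_with_eoo_operators(self, tiny_world):
        country, _, ranges = tiny_world
        proj = eoo.ProjectionSpec()
        land = eoo.project_geometry(country.land_polygon, proj)
        for tr in ranges[:3]:
            recomputed = eoo.project_geometry(tr.polygon, proj).intersection(land).area
            assert tr.true_area_km2 == pytest.approx(recomputed, rel=1e-9)

    def test_whole_land_range_recovers_land_area(self, tiny_world):
        country, _, _ = tiny_world
        proj = eoo.ProjectionSpec()
        land = eoo.project_geometry(country.land_polygon, proj)
        # a range equal to the land polygon has true area == land area
        assert eoo.project_geometry(country.land_polygon, proj).intersection(
            land).area == pytest.approx(land.area, rel=1e-12)

    def test_empty_checklist_rejected(self, tiny_world):
        with pytest.raises(ValueError):
            sd.generate_true_ranges([], tiny_world[0], 0)


def make_profile(**kw):
    base = dict(source_label="facebook",
                species_inclusion_prob={c: 1.0 for c in
                                        ("CR", "EN", "VU", "NT", "LC", "DD")},
                urban_bias_strength=0.0, contamination_rates={})
    base.update(kw)
    return sd.SamplingProfile(**base)


class TestSampleOccurrences:
    def test_clean_records_inside_range_and_land(self, tiny_world):
        country, checklist, ranges = tiny_world
        records, truth = sd.sample_occurrences(
            ranges, checklist, country, make_profile(), 120, seed=0)
        assert len(records) == 120
        assert (truth.contamination_type == "none").all()
        rng_by_sp = {r.species_id: r.polygon for r in ranges}
        for r in records:
            assert shapely.intersects_xy(country.land_polygon, r.lon, r.lat)
            assert shapely.intersects_xy(rng_by_sp[r.species_id].buffer(1e-9),
                                         r.lon, r.lat)

    def test_duplicate_rate_binomial(self, tiny_world):
        country, checklist, ranges = tiny_world
        n = 1000
        records, truth = sd.sample_occurrences(
            ranges, checklist, country,
            make_profile(contamination_rates={"duplicate": 0.5}), n, seed=1)
        n_dup = int((truth.contamination_type == "duplicate").sum())
        sigma = math.sqrt(n * 0.25)
        assert abs(n_dup - 500) <= 3 * sigma

    def test_inclusion_prob_filters_categories(self, tiny_world):
        country, checklist, ranges = tiny_world
        profile = make_profile(species_inclusion_prob={
            "LC": 1.0, "CR": 0.0, "EN": 0.0, "VU": 0.0, "NT": 0.0, "DD": 0.0})
        records, _ = sd.sample_occurrences(ranges, checklist, country, profile,
                                           200, seed=2)
        lc = {e.species_id for e in checklist if e.category == "LC"}
        assert {r.species_id for r in records} <= lc

    def test_conservation_and_side_channel(self, tiny_world):
        country, checklist, ranges = tiny_world
        profile = make_profile(contamination_rates={"duplicate": 0.1,
                                                    "zero_coord": 0.05,
                                                    "at_sea": 0.05})
        records, truth = sd.sample_occurrences(ranges, checklist, country,
                                               profile, 150, seed=3)
        n_clean = int((truth.contamination_type == "none").sum())
        assert n_clean <= 150
        assert len(truth) == len(records)
        assert set(truth.record_id) == {r.record_id for r in records}
        assert len({r.record_id for r in records}) == len(records)

    def test_determinism(self, tiny_world):
        country, checklist, ranges = tiny_world
        p = make_profile(urban_bias_strength=2.0,
                         contamination_rates={"duplicate": 0.1, "at_sea": 0.05})
        a, ta = sd.sample_occurrences(ranges, checklist, country, p, 100, seed=4)
        b, tb = sd.sample_occurrences(ranges, checklist, country, p, 100, seed=4)
        assert a == b
        assert ta.equals(tb)

    def test_invalid_n_target(self, tiny_world):
        country, checklist, ranges = tiny_world
        with pytest.raises(ValueError):
            sd.sample_occurrences(ranges, checklist, country, make_profile(), 0, 0)

    def test_urban_bias_pulls_records_toward_cities(self, tiny_world):
        """Mean distance to the nearest city must be significantly smaller
        under strong urban bias than under uniform sampling (3 sigma over
        20 paired replicate seeds)."""
        country, checklist, ranges = tiny_world
        cities = np.array([eoo.project(*c) for c in country.city_centers])

        def mean_city_dist(strength, seed):
            records, _ = sd.sample_occurrences(
                ranges, checklist, country,
                make_profile(urban_bias_strength=strength), 150, seed=seed)
            pts = np.array([eoo.project(r.lon, r.lat) for r in records])
            d = np.linalg.norm(pts[:, None, :] - cities[None, :, :], axis=2)
            return d.min(axis=1).mean()

        diffs = np.array([mean_city_dist(0.0, s) - mean_city_dist(25.0, s)
                          for s in range(20)])
        assert diffs.mean() > 3 * diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert diffs.mean() > 0


class TestSamplingProfileValidation:
    @pytest.mark.parametrize("kw", [
        {"species_inclusion_prob": {"LC": 1.5}},
        {"species_inclusion_prob": {"XX": 0.5}},
        {"contamination_rates": {"duplicate": -0.1}},
        {"contamination_rates": {"weird": 0.1}},
        {"urban_bias_strength": -1.0},
    ])
    def test_invalid_profiles_rejected(self, kw):
        base = dict(source_label="gbif", species_inclusion_prob={"LC": 1.0})
        base.update(kw)
        with pytest.raises(ValueError):
            sd.SamplingProfile(**base)

    def test_urban_weight_mapping(self):
        assert make_profile(urban_bias_strength=0.0).urban_weight == 0.0
        assert make_profile(urban_bias_strength=1.0).urban_weight == 0.5
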