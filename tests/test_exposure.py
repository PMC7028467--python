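"""Exposure engine: geometry primitives, resolution, densities, series."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from ambientpest.config import SQ_M_PER_ACRE, RunConfig
from ambientpest.exposure import (
    STATUS_MISSING,
    STATUS_OBSERVED,
    STATUS_OOS,
    ApplicationIndex,
    annual_density,
    buffer_area_acres,
    compute_series,
    intersection_fraction,
    make_buffer,
    person_year_location,
    resolve_applications,
)

from conftest import make_app, make_field, make_spell


class TestBuffer:
    def test_area_close_to_disc(self):
        buf = make_buffer(0, 0, 500)
        assert abs(buf.area - math.pi * 500**2) / (math.pi * 500**2) < 1e-3
        assert abs(buffer_area_acres(buf) - 194.077) < 0.2

    def test_contains_interior_excludes_exterior(self):
        buf = make_buffer(0, 0, 500)
        from shapely.geometry import Point

        assert buf.contains(Point(0, 499))
        assert not buf.contains(Point(0, 501))

    def test_translation_invariance(self):
        a = make_buffer(0, 0, 500)
        b = make_buffer(12345.6, -789.0, 500)
        assert abs(a.area - b.area) < 1e-6

    def test_nonfinite_centre_rejected(self):
        with pytest.raises(ValueError):
            make_buffer(float("nan"), 0, 500)
        with pytest.raises(ValueError):
            make_buffer(0, 0, -1)


class TestIntersectionFraction:
    def test_disjoint_and_contained(self):
        buf = make_buffer(0, 0, 500)
        assert intersection_fraction(box(5000, 5000, 5400, 5400), buf) == 0.0
        assert intersection_fraction(box(-50, -50, 50, 50), buf) == pytest.approx(1.0)

    def test_zero_area_field_rejected(self):
        buf = make_buffer(0, 0, 500)
        with pytest.raises(ValueError):
            intersection_fraction(box(0, 0, 0, 0), buf)

    def test_offset_square_matches_monte_carlo(self, rng):
        # 400x400 m square centred 500 m from the buffer centre
        field = box(300, -200, 700, 200)
        buf = make_buffer(0, 0, 500)
        frac = intersection_fraction(field, buf)
        pts = rng.uniform((300, -200), (700, 200), size=(1_000_000, 2))
        inside = (pts**2).sum(axis=1) <= 500**2
        assert abs(frac - inside.mean()) < 0.002

    def test_rotation_invariance_about_buffer_centre(self):
        from shapely.affinity import rotate

        field = box(100, 100, 500, 300)
        buf = make_buffer(0, 0, 500)
        f0 = intersection_fraction(field, buf)
        for angle in (30, 90, 200):
            f1 = intersection_fraction(
                rotate(field, angle, origin=(0, 0)), buf
            )
            assert abs(f0 - f1) < 1e-6


class TestResolve:
    def test_field_id_match(self):
        fields = [make_field("F1")]
        resolved, unresolved = resolve_applications([make_app()], fields)
        assert len(resolved) == 1 and not unresolved
        assert resolved[0].geometry.equals(fields[0].geometry)

    def test_section_split_proportional_to_area(self):
        # areas 10 and 30 acres -> 25/75 split of 100 lb
        a10 = math.sqrt(10 * SQ_M_PER_ACRE)
        a30 = math.sqrt(30 * SQ_M_PER_ACRE)
        fields = [
            make_field("F1", (0, 0, a10, a10), crop="cotton", section="S1"),
            make_field("F2", (5000, 0, 5000 + a30, a30), crop="cotton", section="S1"),
        ]
        app = make_app(field_id=None, section_id="S1", crop_code="cotton")
        resolved, unresolved = resolve_applications([app], fields)
        assert not unresolved
        pounds = sorted(r.pounds for r in resolved)
        assert pounds == pytest.approx([25.0, 75.0])

    def test_no_match_goes_to_unresolved(self):
        fields = [make_field("F1", crop="cotton", section="S1")]
        apps = [
            make_app("A1"),
            make_app("A2", field_id="F9", section_id="S1", crop_code="vineyard"),
            make_app("A3", field_id="F9", section_id="S9"),
        ]
        resolved, unresolved = resolve_applications(apps, fields)
        assert len(resolved) + len(unresolved) == 3
        assert {a.record_id for a in unresolved} == {"A2", "A3"}

    def test_survey_period_must_cover_year(self):
        fields = [make_field("F1", years=(1970, 1980))]
        resolved, unresolved = resolve_applications(
            [make_app(year=1990)], fields
        )
        assert not resolved and len(unresolved) == 1


class TestAnnualDensity:
    def test_no_applications_zero(self, config):
        fields = [make_field("F1", (0, 0, 200, 200))]
        resolved, _ = resolve_applications([make_app(year=1990)], fields)
        assert annual_density((0, 0), 1991, "chlorpyrifos", resolved, config) == 0.0
        assert annual_density((0, 0), 1990, "diazinon", resolved, config) == 0.0

    def test_fully_contained_field_closed_form(self, config):
        fields = [make_field("F1", (-100, -100, 100, 100))]
        resolved, _ = resolve_applications([make_app(pounds=100.0, year=1990)], fields)
        d = annual_density((0, 0), 1990, "chlorpyrifos", resolved, config)
        expected = 100.0 / (math.pi * 500**2 / SQ_M_PER_ACRE)
        assert d == pytest.approx(expected, rel=2e-3)  # 100/194.077 ~ 0.5153
        assert d == pytest.approx(0.5153, rel=5e-3)

    def test_additivity_over_applications(self, config):
        fields = [
            make_field("F1", (-100, -100, 100, 100)),
            make_field("F2", (400, -200, 800, 200)),
        ]
        apps = [
            make_app("A1", pounds=100.0, year=1990, field_id="F1"),
            make_app("A2", pounds=60.0, year=1990, field_id="F2"),
        ]
        resolved, _ = resolve_applications(apps, fields)
        d_both = annual_density((0, 0), 1990, "chlorpyrifos", resolved, config)
        d1 = annual_density((0, 0), 1990, "chlorpyrifos", resolved[:1], config)
        d2 = annual_density((0, 0), 1990, "chlorpyrifos", resolved[1:], config)
        assert d_both == pytest.approx(d1 + d2, rel=1e-12)

    def test_mass_conservation_with_enclosing_buffer(self, rng):
        # buffer big enough to contain every field: captured pounds exact
        cfg = RunConfig(buffer_radius_m=20_000)
        fields, apps = [], []
        for i in range(30):
            x0, y0 = rng.uniform(-5000, 5000, 2)
            w, h = rng.uniform(100, 600, 2)
            fields.append(make_field(f"F{i}", (x0, y0, x0 + w, y0 + h)))
            apps.append(make_app(f"A{i}", pounds=float(rng.uniform(1, 300)),
                                 year=1990, field_id=f"F{i}"))
        resolved, _ = resolve_applications(apps, fields)
        index = ApplicationIndex(resolved, cfg)
        d = index.density(0, 0, 1990, "chlorpyrifos")
        buf_acres = buffer_area_acres(make_buffer(0, 0, 20_000))
        assert d * buf_acres == pytest.approx(sum(a.pounds for a in apps), rel=1e-9)

    def test_captured_pounds_monotone_in_radius(self, rng):
        fields = [make_field("F1", (600, -200, 1000, 200))]
        resolved, _ = resolve_applications([make_app(pounds=50.0, year=1990)], fields)
        captured = []
        for r in (300, 500, 800, 1500, 5000):
            cfg = RunConfig(buffer_radius_m=r)
            idx = ApplicationIndex(resolved, cfg)
            captured.append(idx.density(0, 0, 1990, "chlorpyrifos")
                            * buffer_area_acres(make_buffer(0, 0, r)))
        assert all(b >= a - 1e-12 for a, b in zip(captured, captured[1:]))


class TestPersonYearLocation:
    def test_known_high_certainty(self, config):
        s = make_spell(x=10.0, y=20.0)
        assert person_year_location([s], 1990, config) == ("known", (10.0, 20.0))

    def test_gap_is_missing(self, config):
        s = make_spell(start=1974, end=1985)
        assert person_year_location([s], 1990, config)[0] == STATUS_MISSING

    def test_low_certainty_is_missing(self, config):
        s = make_spell(tier="zip")
        assert person_year_location([s], 1990, config)[0] == STATUS_MISSING
        relaxed = config.replace(low_certainty_is_missing=False)
        assert person_year_location([s], 1990, relaxed)[0] == "known"

    def test_out_of_state(self, config):
        s = make_spell(x=None, y=None, tier="none", in_state=False)
        assert person_year_location([s], 1990, config)[0] == "out_of_state"


class TestComputeSeries:
    def test_far_person_all_zero(self, config):
        fields = [make_field("F1", (50_000, 50_000, 50_400, 50_400))]
        resolved, _ = resolve_applications(
            [make_app(year=1990, pounds=10.0)], fields
        )
        index = ApplicationIndex(resolved, config)
        series = compute_series("P1", 2008, [make_spell()], index, config)
        s = series[("R", "chlorpyrifos")]
        assert all(s.values[y] == 0.0 for y in s.status)

    def test_positive_only_during_near_residence(self, config):
        fields = [make_field("F1", (100, -100, 400, 100))]
        apps = [make_app(f"A{y}", year=y, pounds=10.0) for y in range(1975, 2005)]
        resolved, _ = resolve_applications(apps, fields)
        index = ApplicationIndex(resolved, config)
        spells = [
            make_spell(start=1974, end=1979, x=90_000.0, y=0.0),
            make_spell(start=1980, end=1985, x=0.0, y=0.0),
            make_spell(start=1986, end=2008, x=90_000.0, y=0.0),
        ]
        series = compute_series("P1", 2008, spells, index, config)
        s = series[("R", "chlorpyrifos")]
        for y in s.status:
            if 1980 <= y <= 1985:
                assert s.values[y] > 0
            else:
                assert s.values[y] == 0.0

    def test_translation_invariance_of_series(self, config, rng):
        from shapely.affinity import translate

        fields = [make_field("F1", (100, -100, 400, 100))]
        apps = [make_app(year=1990, pounds=25.0)]
        resolved, _ = resolve_applications(apps, fields)
        spells = [make_spell()]
        s0 = compute_series("P1", 2008, spells, ApplicationIndex(resolved, config),
                            config)[("R", "chlorpyrifos")]
        dx = dy = 10_000.0
        fields2 = [make_field("F1", (100 + dx, -100 + dy, 400 + dx, 100 + dy))]
        resolved2, _ = resolve_applications(apps, fields2)
        spells2 = [make_spell(x=dx, y=dy)]
        s1 = compute_series("P1", 2008, spells2, ApplicationIndex(resolved2, config),
                            config)[("R", "chlorpyrifos")]
        for y in s0.status:
            assert s1.values[y] == pytest.approx(s0.values[y], rel=1e-9, abs=1e-15)

    def test_workplace_years_without_spell_missing(self, config):
        index = ApplicationIndex([], config)
        series = compute_series("P1", 2008, [make_spell()], index, config)
        w = series[("W", "chlorpyrifos")]
        assert all(st == STATUS_MISSING for st in w.status.values())

    def test_index_before_window_rejected(self, config):
        index = ApplicationIndex([], config)
        with pytest.raises(ValueError):
            compute_series("P1", 1960, [make_spell()], index, config)

    def test_out_of_state_years_marked(self, config):
        spells = [
            make_spell(start=1974, end=1989),
            make_spell(start=1990, end=2008, x=None, y=None, tier="none",
                       in_state=False),
        ]
        index = ApplicationIndex([], config)
        s = compute_series("P1", 2008, spells, index, config)[("R", "chlorpyrifos")]
        assert s.status[1990] == STATUS_OOS and s.status[1980] == STATUS_OBSERVED
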