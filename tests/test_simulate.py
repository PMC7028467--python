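"""Synthetic-study generator: determinism, geometry, copula, masking, outcomes."""

import math

import numpy as np
import pandas as pd
import pytest

from ambientpest.classify import classify_person
from ambientpest.exposure import ApplicationIndex, compute_series, resolve_applications
from ambientpest.imputation import impute_person
from ambientpest.simulate import (
    CalibrationError,
    ChemicalParams,
    ScenarioParams,
    build_pool,
    calibrate_alpha,
    draw_study,
    generate_applications,
    generate_landscape,
    generate_population,
    generate_study,
    latent_corr_for_binary,
    mask_histories,
)


def small_params(**kw):
    defaults = dict(seed=7, n_fields=30, n_cases=40, n_controls=40,
                    region=(0.0, 0.0, 12000.0, 12000.0))
    defaults.update(kw)
    return ScenarioParams(**defaults)


class TestLandscape:
    def test_deterministic_given_seed(self):
        a = generate_landscape(small_params())
        b = generate_landscape(small_params())
        assert all(x.geometry.equals(y.geometry) for x, y in zip(a, b))
        assert [x.crop_code for x in a] == [y.crop_code for y in b]

    def test_fields_disjoint_pairwise(self):
        fields = generate_landscape(small_params(n_fields=50))
        for i, f in enumerate(fields):
            for g in fields[i + 1:]:
                assert f.geometry.intersection(g.geometry).area == 0.0

    def test_total_area_bounded_by_region(self):
        p = small_params()
        fields = generate_landscape(p)
        region_area = (p.region[2] - p.region[0]) * (p.region[3] - p.region[1])
        assert sum(f.geometry.area for f in fields) <= region_area

    def test_capacity_error_when_region_too_small(self):
        with pytest.raises(Exception, match="disjoint fields"):
            generate_landscape(
                small_params(region=(0.0, 0.0, 1500.0, 1500.0), n_fields=50)
            )


def equal_prob_chems(p, rho_unused=None, n=2):
    return tuple(
        ChemicalParams(f"chem{i}", p, 1.0, 0.3, crops=None) for i in range(n)
    )


class TestApplications:
    def test_zero_probability_no_records(self):
        params = small_params(chemicals=(
            ChemicalParams("a", 0.0, 1.0, 0.3),
            ChemicalParams("b", 0.3, 1.0, 0.3),
        ))
        fields = generate_landscape(params)
        recs = generate_applications(fields, params)
        assert not any(r.chemical == "a" for r in recs)
        assert any(r.chemical == "b" for r in recs)

    def test_perfect_correlation_identical_indicators(self):
        params = small_params(chemicals=equal_prob_chems(0.4),
                              co_application_rho=1.0)
        fields = generate_landscape(params)
        recs = generate_applications(fields, params)
        sets = {
            c: {(r.field_id, r.year) for r in recs if r.chemical == c}
            for c in ("chem0", "chem1")
        }
        assert sets["chem0"] == sets["chem1"]

    def test_copula_hits_target_indicator_correlation(self):
        params = ScenarioParams(
            seed=3, n_fields=300, region=(0.0, 0.0, 40000.0, 40000.0),
            chemicals=equal_prob_chems(0.3), co_application_rho=0.6,
        )
        fields = generate_landscape(params)
        recs = generate_applications(fields, params)
        years = range(1974, 2013)
        n_fy = len(fields) * len(years)
        assert n_fy >= 10_000
        ind = {c: np.zeros(n_fy) for c in ("chem0", "chem1")}
        pos = {(f.field_id, y): i
               for i, (f, y) in enumerate((f, y) for f in fields for y in years)}
        for r in recs:
            ind[r.chemical][pos[(r.field_id, r.year)]] = 1.0
        corr = np.corrcoef(ind["chem0"], ind["chem1"])[0, 1]
        assert abs(corr - 0.6) < 0.05

    def test_pounds_are_rate_times_field_acres(self):
        params = small_params()
        fields = generate_landscape(params)
        recs = generate_applications(fields, params)
        acres = {f.field_id: f.area_acres for f in fields}
        for r in recs[:50]:
            assert r.treated_acres == pytest.approx(acres[r.field_id])
            assert r.pounds > 0


class TestPopulation:
    def test_no_moves_single_residential_spell(self):
        params = small_params(move_rate=0.0, out_of_state_prob=0.0)
        fields = generate_landscape(params)
        hist, persons = generate_population(fields, params, 50)
        for pid, spells in hist.items():
            assert sum(1 for s in spells if s.setting == "R") == 1

    def test_residence_covers_window_before_masking(self):
        params = small_params()
        fields = generate_landscape(params)
        hist, persons = generate_population(fields, params, 50)
        idx = persons.set_index("person_id")["index_year"]
        for pid, spells in hist.items():
            res = sorted((s for s in spells if s.setting == "R"),
                         key=lambda s: s.start_year)
            years = set()
            for s in res:
                years.update(s.years)
            assert years >= set(range(1974, int(idx[pid]) + 1))

    def test_near_field_fraction_tracks_target(self):
        # the spell-level near-field probability controls how many persons
        # ever live within drift range; checked against a binomial band
        params = ScenarioParams(seed=17, n_fields=60, near_field_prob=0.45,
                                move_rate=0.0, out_of_state_prob=0.0)
        fields = generate_landscape(params)
        hist, _ = generate_population(fields, params, 2000)
        near = 0
        from shapely.geometry import Point
        from shapely.strtree import STRtree

        tree = STRtree([f.geometry for f in fields])
        for pid, spells in hist.items():
            s = [sp for sp in spells if sp.setting == "R"][0]
            if tree.query(Point(s.x, s.y).buffer(500)).size:
                near += 1
        # single-spell persons: expected fraction = near_field_prob exactly
        assert abs(near / 2000 - 0.45) < 0.03


class TestMasking:
    def test_zero_probability_no_gaps(self, rng):
        params = small_params(missing_year_prob=0.0)
        fields = generate_landscape(params)
        hist, _ = generate_population(fields, params, 20)
        masked = mask_histories(hist, 0.0, rng)
        assert {p: [(s.start_year, s.end_year) for s in sp]
                for p, sp in masked.items()} == {
            p: [(s.start_year, s.end_year) for s in sp] for p, sp in hist.items()
        }

    def test_masked_fraction_near_probability(self, rng):
        params = small_params(out_of_state_prob=0.0)
        fields = generate_landscape(params)
        hist, _ = generate_population(fields, params, 300)
        p = 0.15
        masked = mask_histories(hist, p, rng)
        total = dropped = 0
        for pid in hist:
            before = sum(len(list(s.years)) for s in hist[pid])
            after = sum(len(list(s.years)) for s in masked[pid])
            total += before
            dropped += before - after
        assert abs(dropped / total - p) < 0.01


class TestOutcomes:
    def test_alpha_calibration_null_model(self, rng):
        lp = np.zeros(5000)
        alpha = calibrate_alpha(lp, 0.3)
        assert 1 / (1 + math.exp(-alpha)) == pytest.approx(0.3, abs=1e-9)

    def test_unattainable_fraction_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_alpha(np.full(10, 1e9), 0.3)

    def test_null_scenario_case_fraction_in_binomial_bounds(self):
        params = small_params(planted_log_or={}, covariate_effects={})
        pool = build_pool(params, n_persons=2000)
        alpha = calibrate_alpha(pool.linear_predictor, 0.5)
        rng = np.random.default_rng(5)
        p = 1 / (1 + np.exp(-(alpha + pool.linear_predictor)))
        status = rng.uniform(size=2000) < p
        # 99% binomial bounds around 1000
        assert abs(status.sum() - 1000) < 2.58 * math.sqrt(2000 * 0.25)

    def test_truth_flags_match_recomputation_from_unmasked_data(self):
        params = small_params()
        study = generate_study(params)
        pool = study.pool
        resolved, _ = resolve_applications(pool.applications, pool.fields)
        index = ApplicationIndex(resolved, pool.config)
        for pid in study.persons["person_id"].head(20):
            row = pool.persons[pool.persons["person_id"] == pid].iloc[0]
            series = compute_series(pid, int(row["index_year"]),
                                    pool.histories[pid], index, pool.config)
            flags = classify_person(impute_person(series), int(row["index_year"]),
                                    pool.config)
            for chem in pool.config.chemicals:
                expected = int(flags[chem].combined == "both")
                assert pool.truth_flags.at[pid, chem] == expected

    def test_study_fills_quotas_deterministically(self):
        a = generate_study(small_params())
        b = generate_study(small_params())
        assert (a.persons["case_status"] == 1).sum() == 40
        assert (a.persons["case_status"] == 0).sum() == 40
        pd.testing.assert_frame_equal(a.persons, b.persons)

    def test_large_sample_crude_or_recovers_planted_effect(self):
        # planted log OR on the outcome-model exposure indicator; crude OR
        # from the truth flags converges to the planted value
        target = 3.22
        params = ScenarioParams(
            seed=23, n_cases=2500, n_controls=2500,
            planted_log_or={"chlorpyrifos": math.log(target)},
            covariate_effects={}, missing_year_prob=0.0,
        )
        pool = build_pool(params, n_persons=11000)
        rng = np.random.default_rng(23)
        persons = draw_study(pool, params, rng)
        flags = pool.truth_flags.loc[persons["person_id"], "chlorpyrifos"]
        y = persons.set_index("person_id")["case_status"]
        a = int(((flags == 1) & (y == 1)).sum())
        b = int(((flags == 0) & (y == 1)).sum())
        c = int(((flags == 1) & (y == 0)).sum())
        d = int(((flags == 0) & (y == 0)).sum())
        crude = (a * d) / (b * c)
        assert abs(crude - target) / target < 0.10


def test_latent_corr_solver_endpoints():
    assert latent_corr_for_binary(0.0, 0.3, 0.3) == 0.0
    assert latent_corr_for_binary(1.0, 0.3, 0.3) == 1.0
    r = latent_corr_for_binary(0.6, 0.3, 0.3)
    assert 0.6 < r < 1.0  # latent corr exceeds indicator corr
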