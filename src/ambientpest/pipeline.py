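"""End-to-end study orchestration.

Stages: resolve applications to field geometry, compute raw exposure
series, summarise missingness, impute, classify under the configured
window/latency, fit the mutually adjusted models with the >10%
change-in-estimate screen, and build co-exposure tables.  Intermediates
persist as the per-module CSV formats so any stage can be audited or
restarted; a provenance record carries the seed, config hash and
stage-by-stage counts.  Outputs are deterministic given seed and config.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio
from .classify import (
    EmptyWindowError,
    classify_person,
    exposure_window,
    flags_to_frame,
    residency_filter,
)
from .config import RunConfig
from .exposure import (
    STATUS_MISSING,
    STATUS_OOS,
    VALUED_STATUSES,
    ApplicationIndex,
    ExposureSeries,
    compute_series,
    resolve_applications,
)
from .imputation import impute_person, summarize_missingness
from .io import AddressSpell
from .model import (
    DEFAULT_COVARIATES,
    DesignError,
    ExposureOddsModel,
    change_in_estimate_screen,
    coexposure_table,
)

log = logging.getLogger("ambientpest")

#: covariates evaluated by the change-in-estimate screen (the person
#: schema's optional risk factors, mirroring farm residence/work history)
CANDIDATE_COVARIATES = ("ever_farm_live", "ever_farm_work")


@dataclass
class StudyData:
    """The four validated inputs of a run."""

    fields: list
    applications: list
    histories: dict[str, list[AddressSpell]]
    persons: pd.DataFrame

    @classmethod
    def load(cls, fields_path, applications_path, histories_path, persons_path):
        return cls(
            apio.read_fields(fields_path),
            apio.read_applications(applications_path),
            apio.read_histories(histories_path),
            apio.read_persons(persons_path),
        )

    @classmethod
    def from_synthetic(cls, study) -> "StudyData":
        return cls(study.fields, study.applications, study.histories, study.persons)


@dataclass
class ResultsBundle:
    """Everything a primary run produces."""

    config: RunConfig
    series_raw: pd.DataFrame
    series_imputed: pd.DataFrame
    missingness: pd.DataFrame
    flags: pd.DataFrame
    or_tables: dict[str, pd.DataFrame]
    screen_reports: dict[str, dict]
    coexposure: list
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        apio.write_series_csv(self.series_raw, out / "series_raw.csv")
        apio.write_series_csv(self.series_imputed, out / "series_imputed.csv")
        self.missingness.to_csv(out / "missingness.csv", index=False)
        self.flags.to_csv(out / "flags.csv", index=False)
        for chem, tbl in self.or_tables.items():
            safe = chem.replace(",", "_").replace("/", "_")
            tbl.to_csv(out / f"model_{safe}.csv", index=False, float_format="%.17g")
        coex = pd.DataFrame(
            [
                {
                    "chemical_a": t.chemical_a,
                    "chemical_b": t.chemical_b,
                    "stratum": t.stratum,
                    "n_both": t.n_both,
                    "n_neither": t.n_neither,
                    "n_exactly_one": t.n_exactly_one,
                    "pct_both": 100 * t.proportions[0],
                    "pct_neither": 100 * t.proportions[1],
                    "pct_exactly_one": 100 * t.proportions[2],
                }
                for t in self.coexposure
            ]
        )
        coex.to_csv(out / "coexposure.csv", index=False, float_format="%.17g")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )


def _series_to_frame(all_series: dict, imputed: bool) -> pd.DataFrame:
    rows = []
    oos_label = "unassessed"
    for pid in all_series:
        for (setting, chem), s in all_series[pid].items():
            for y in sorted(s.status):
                st = s.status[y]
                rows.append(
                    {
                        "person_id": pid,
                        "setting": setting,
                        "chemical": chem,
                        "year": y,
                        "density": s.values[y] if st in VALUED_STATUSES else np.nan,
                        "status": st,
                        "provenance": oos_label if st == STATUS_OOS else st,
                    }
                )
    df = pd.DataFrame(
        rows, columns=apio.SERIES_COLUMNS + ["provenance"]
    )
    if not imputed:
        df = df.drop(columns=["provenance"])
    return df


def compute_exposures(data: StudyData, config: RunConfig):
    """Stages 1-3: resolve, compute raw series, impute.

    Returns (raw series dict, imputed series dict, missingness frame,
    counts dict)."""
    resolved, unresolved = resolve_applications(data.applications, data.fields)
    index = ApplicationIndex(resolved, config)
    raw: dict[str, dict] = {}
    imputed: dict[str, dict] = {}
    miss_rows = []
    for row in data.persons.itertuples(index=False):
        pid = row.person_id
        series = compute_series(
            pid, row.index_year, data.histories.get(pid, []), index, config
        )
        raw[pid] = series
        imputed[pid] = impute_person(series)
        for setting in ("R", "W"):
            s = series[(setting, config.chemicals[0])]
            m = summarize_missingness(s)
            miss_rows.append(
                {
                    "person_id": pid,
                    "setting": setting,
                    "years_total": m.years_total,
                    "years_missing": m.years_missing,
                    "years_out_of_state": m.years_out_of_state,
                    "fraction_missing": m.fraction_missing,
                }
            )
    counts = {
        "applications_in": len(data.applications),
        "applications_resolved": len(resolved),
        "applications_unresolved": len(unresolved),
        "persons": len(data.persons),
    }
    return raw, imputed, pd.DataFrame(miss_rows), counts


def classify_all(imputed: dict, persons: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    flags = {}
    for row in persons.itertuples(index=False):
        flags[row.person_id] = classify_person(
            imputed[row.person_id], row.index_year, config
        )
    return flags_to_frame(flags)


def analysis_targets(config: RunConfig) -> list[str]:
    """Group plus each non-organochlorine chemical, the paper-structured set."""
    targets = ["organochlorines"] if config.organochlorine_group else []
    targets += [c for c in config.chemicals if c not in config.organochlorine_group]
    return targets


def fit_models(
    persons: pd.DataFrame,
    flags: pd.DataFrame,
    config: RunConfig,
    screen: bool = True,
    contrast: str = "both_vs_neither",
):
    """Mutually adjusted model per analysis target, with optional
    change-in-estimate covariate screening."""
    targets = analysis_targets(config)
    or_tables: dict[str, pd.DataFrame] = {}
    screens: dict[str, dict] = {}
    for target in targets:
        co = tuple(t for t in targets if t != target)
        covs = DEFAULT_COVARIATES
        try:
            if screen:
                report = change_in_estimate_screen(
                    persons, flags, target, DEFAULT_COVARIATES,
                    CANDIDATE_COVARIATES, co, contrast=contrast,
                )
                screens[target] = report
                covs = DEFAULT_COVARIATES + tuple(report["selected"])
            res = ExposureOddsModel.from_study(
                persons, flags, target, co, covs, contrast
            ).fit()
            or_tables[target] = res.or_table()
        except (DesignError, EmptyWindowError) as e:
            or_tables[target] = pd.DataFrame(
                [{"term": target, "error": str(e)}]
            )
            log.warning("model for %s not estimable: %s", target, e)
    return or_tables, screens


def run_primary(
    config: RunConfig, data: StudyData, out_dir: str | Path | None = None
) -> ResultsBundle:
    """The full primary analysis; writes the bundle when out_dir given."""
    raw, imputed, missingness, counts = compute_exposures(data, config)
    flags = classify_all(imputed, data.persons, config)
    or_tables, screens = fit_models(data.persons, flags, config)

    controls = data.persons.loc[data.persons["case_status"] == 0, "person_id"]
    coex = []
    targets = analysis_targets(config)
    if "organochlorines" in targets and len(controls):
        for other in targets:
            if other != "organochlorines":
                coex.append(
                    coexposure_table(flags, "organochlorines", other,
                                     controls, "controls")
                )
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": counts,
        "n_cases": int((data.persons["case_status"] == 1).sum()),
        "n_controls": int((data.persons["case_status"] == 0).sum()),
    }
    bundle = ResultsBundle(
        config, _series_to_frame(raw, False), _series_to_frame(imputed, True),
        missingness, flags, or_tables, screens, coex, provenance,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------


def _single_address_histories(
    data: StudyData, config: RunConfig
) -> dict[str, list[AddressSpell]]:
    """Pretend each person spent the whole window at the residence they
    occupied in their index year (the single-address comparison design)."""
    from dataclasses import replace

    out: dict[str, list[AddressSpell]] = {}
    idx = data.persons.set_index("person_id")["index_year"]
    for pid, spells in data.histories.items():
        if pid not in idx.index:
            continue
        index_year = int(idx[pid])
        at_index = [
            s for s in spells if s.setting == "R" and s.covers_year(index_year)
        ]
        if not at_index:
            out[pid] = []  # unknown index address: all years missing
            continue
        s = at_index[0]
        whole = replace(
            s, start_year=config.window_start_year, end_year=index_year
        )
        # workplace shares the address so classification reduces to the
        # residential signal
        out[pid] = [whole, replace(whole, setting="W")]
    return out


def run_sensitivity(
    config: RunConfig, data: StudyData, bundle: ResultsBundle
) -> dict[str, dict]:
    """Sensitivity variants around an already-computed primary bundle.

    latency 10/20, >=30-year in-state and in-county residency
    restrictions, exclusion of persons with >1/3 residential window years
    missing, and the single-address-at-index comparison.  A variant whose
    contrast is empty reports ``not_estimable`` and the run continues.
    """
    raw, imputed, _, _ = compute_exposures(data, config)
    variants: dict[str, dict] = {}

    def try_fit(name, persons, flags):
        try:
            tables, _ = fit_models(persons, flags, config, screen=False)
            variants[name] = {"or_tables": tables}
        except (DesignError, EmptyWindowError, ValueError) as e:
            variants[name] = {"not_estimable": str(e)}

    for lat in (10, 20):
        cfg = config.replace(latency_years=lat)
        ok = data.persons["index_year"] - lat >= cfg.window_start_year
        persons = data.persons.loc[ok]
        flags = classify_all(imputed, persons, cfg)
        try_fit(f"latency_{lat}", persons, flags)

    windows = {
        row.person_id: exposure_window(row.index_year, config)
        for row in data.persons.itertuples(index=False)
    }
    flags0 = classify_all(imputed, data.persons, config)
    for tag, name in (("in_state", "state_30y"), ("in_counties", "county_30y")):
        eligible = residency_filter(data.histories, tag, 30, windows)
        persons = data.persons[data.persons["person_id"].isin(eligible)]
        if persons.empty:
            variants[name] = {"not_estimable": "no eligible persons"}
            continue
        try_fit(name, persons, flags0)

    miss = bundle.missingness
    res_miss = miss[miss["setting"] == "R"].set_index("person_id")["fraction_missing"]
    keep = res_miss[res_miss <= 1 / 3].index
    persons = data.persons[data.persons["person_id"].isin(keep)]
    try_fit("exclude_gt_third_missing", persons, flags0)

    single = StudyData(
        data.fields, data.applications,
        _single_address_histories(data, config), data.persons,
    )
    _, single_imputed, _, _ = compute_exposures(single, config)
    single_flags = classify_all(single_imputed, data.persons, config)
    try_fit("single_address_at_index", data.persons, single_flags)
    return variants
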