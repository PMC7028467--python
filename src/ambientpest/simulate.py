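"""Synthetic agricultural case-control studies with known ground truth.

Everything downstream of data collection is testable against this module:
it lays out a rectangular-field agricultural landscape, simulates yearly
pesticide applications with copula-correlated co-application of multiple
chemicals, builds residential and workplace address histories with moves,
recall gaps and out-of-state spells, and assigns case status from a
logistic outcome model with *planted* log odds ratios, returning the true
exposure flags and coefficients alongside the masked study data.

Default scenario parameters emulate the study structure this pipeline
targets: 155 cases and 150 controls of postmenopausal age drawn from an
intensively farmed region, exposure prevalences in the 40-70% range,
heavy co-application of organochlorines with chlorpyrifos, and a planted
chlorpyrifos odds ratio of 3.22.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .classify import COMBINED_BOTH, classify_person
from .config import ORGANOCHLORINES, SQ_M_PER_ACRE, RunConfig
from .exposure import ApplicationIndex, compute_series, resolve_applications
from .imputation import impute_person
from .io import AddressSpell, ApplicationRecord, FieldPolygon, PERSON_CATEGORIES
from shapely.geometry import Point, box


class CapacityError(RuntimeError):
    """The region cannot hold the requested number of disjoint fields."""


class CalibrationError(RuntimeError):
    """No intercept attains the requested case fraction."""


@dataclass(frozen=True)
class ChemicalParams:
    """Application regime of one chemical.

    ``crops`` restricts applications to fields of those crop codes
    (None = applied to any crop); the restriction is what makes
    person-level exposures to different chemicals partially discordant
    even though applications on a shared field are highly correlated.
    """

    name: str
    annual_probability: float  # P(applied) per field-year while active
    rate_median: float  # lb/acre, median of the lognormal rate
    rate_sigma: float  # lognormal sigma of the rate
    active_start: int = 1950
    active_end: int = 2050
    crops: tuple[str, ...] | None = None


def _default_chemicals() -> tuple[ChemicalParams, ...]:
    return (
        ChemicalParams("dicofol", 0.25, 1.5, 0.6, crops=("cotton", "vineyard")),
        ChemicalParams("endosulfan", 0.20, 1.0, 0.6, crops=("cotton", "row_crop")),
        ChemicalParams(
            "chlorpyrifos", 0.30, 2.0, 0.6, crops=("orchard", "cotton", "row_crop")
        ),
        ChemicalParams("diazinon", 0.25, 1.2, 0.6, crops=("orchard", "vineyard")),
        ChemicalParams(
            "1,3-dichloropropene", 0.15, 50.0, 0.8, crops=("row_crop", "vineyard")
        ),
    )


@dataclass
class ScenarioParams:
    """Knobs of the synthetic study; defaults are the reference scenario."""

    region: tuple[float, float, float, float] = (0.0, 0.0, 20000.0, 20000.0)
    n_fields: int = 80
    field_size_m: tuple[float, float] = (200.0, 600.0)
    chemicals: tuple[ChemicalParams, ...] = field(default_factory=_default_chemicals)
    co_application_rho: float = 0.6  # pairwise correlation of app indicators
    n_cases: int = 155
    n_controls: int = 150
    index_year_range: tuple[int, int] = (2009, 2012)
    move_rate: float = 2.0  # expected residence changes over the window
    missing_year_prob: float = 0.05
    out_of_state_prob: float = 0.05
    near_field_prob: float = 0.45  # P(a residence spell is within drift range)
    workplace_prob: float = 0.7  # P(person has any workplace history)
    planted_log_or: dict[str, float] = field(
        default_factory=lambda: {"chlorpyrifos": math.log(3.22)}
    )
    covariate_effects: dict[str, float] = field(default_factory=dict)
    truth_exposure: str = "both"  # indicator driving the outcome model
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.co_application_rho,
            self.missing_year_prob,
            self.out_of_state_prob,
            self.near_field_prob,
            self.workplace_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/correlation {p} outside [0, 1]")
        if min(self.n_fields, self.n_cases, self.n_controls) <= 0:
            raise ValueError("n_fields, n_cases, n_controls must be positive")
        for c in self.chemicals:
            if not 0.0 <= c.annual_probability <= 1.0:
                raise ValueError(f"{c.name}: annual_probability outside [0, 1]")
            if c.rate_median < 0:
                raise ValueError(f"{c.name}: negative rate")

    def run_config(self, **overrides) -> RunConfig:
        names = tuple(c.name for c in self.chemicals)
        group = tuple(n for n in names if n in ORGANOCHLORINES)
        kw = dict(chemicals=names, organochlorine_group=group, seed=self.seed)
        kw.update(overrides)
        return RunConfig(**kw)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

_CROPS = ("orchard", "vineyard", "cotton", "row_crop")
_SECTION_M = 1600.0  # one-square-mile PLSS-style section grid


def generate_landscape(params: ScenarioParams, rng=None) -> list[FieldPolygon]:
    """Place ``n_fields`` disjoint axis-aligned rectangular fields.

    Fields carry a crop code, a survey period spanning the study years and
    a section id from a one-mile grid, enabling both linkage paths.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    x0, y0, x1, y1 = params.region
    lo, hi = params.field_size_m
    placed: list[tuple[float, float, float, float]] = []
    fields: list[FieldPolygon] = []
    attempts = 0
    max_attempts = 400 * params.n_fields
    while len(fields) < params.n_fields:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {params.n_fields} disjoint fields in region "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        fx = rng.uniform(x0, x1 - w)
        fy = rng.uniform(y0, y1 - h)
        rect = (fx, fy, fx + w, fy + h)
        if any(
            not (rect[2] <= r[0] or r[2] <= rect[0] or rect[3] <= r[1] or r[3] <= rect[1])
            for r in placed
        ):
            continue
        placed.append(rect)
        i = len(fields)
        cx, cy = fx + w / 2, fy + h / 2
        section = f"S{int((cx - x0) // _SECTION_M)}_{int((cy - y0) // _SECTION_M)}"
        fields.append(
            FieldPolygon(
                field_id=f"F{i:04d}",
                crop_code=_CROPS[int(rng.integers(len(_CROPS)))],
                survey_start_year=1970,
                survey_end_year=2020,
                geometry=box(*rect),
                section_id=section,
            )
        )
    return fields


# ---------------------------------------------------------------------------
# applications with copula-correlated co-application
# ---------------------------------------------------------------------------


def latent_corr_for_binary(rho: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation reproducing a target correlation of
    the thresholded binary indicators with marginals p1, p2."""
    if rho <= 0.0:
        return 0.0
    if rho >= 0.999:
        return 1.0
    z1, z2 = norm.ppf(p1), norm.ppf(p2)
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def binary_corr(r: float) -> float:
        joint = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([z1, z2])
        return (joint - p1 * p2) / denom

    target = min(rho, binary_corr(0.9999) - 1e-9)
    return brentq(lambda r: binary_corr(r) - target, 0.0, 0.9999, xtol=1e-6)


def generate_applications(
    fields: list[FieldPolygon], params: ScenarioParams, rng=None
) -> list[ApplicationRecord]:
    """Simulate yearly application records per field.

    Co-application between chemicals follows a one-factor Gaussian copula:
    each field-year draws a shared latent factor, and a chemical is
    applied when its loading-weighted latent score falls below the
    quantile of its annual probability.  The loading is calibrated so the
    *indicator* correlation between chemical pairs equals
    ``co_application_rho``.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    chems = params.chemicals
    p_mean = float(np.mean([c.annual_probability for c in chems])) if chems else 0.5
    p_mean = min(max(p_mean, 1e-6), 1 - 1e-6)
    r_latent = latent_corr_for_binary(params.co_application_rho, p_mean, p_mean)
    lam = math.sqrt(r_latent)
    y0 = min(c.active_start for c in chems) if chems else 1974
    y1 = max(c.active_end for c in chems) if chems else 2012
    y0 = max(y0, 1974)
    y1 = min(y1, params.index_year_range[1])
    years = np.arange(y0, y1 + 1)

    records: list[ApplicationRecord] = []
    rid = 0
    for f in fields:
        acres = f.area_acres
        # latent shared factor per year, chemical-specific noise
        z = rng.standard_normal(len(years))
        for c in chems:
            if c.annual_probability <= 0:
                continue
            if c.crops is not None and f.crop_code not in c.crops:
                continue
            eps = rng.standard_normal(len(years))
            score = lam * z + math.sqrt(max(1 - lam * lam, 0.0)) * eps
            cut = norm.ppf(c.annual_probability)
            applied = score < cut
            active = (years >= c.active_start) & (years <= c.active_end)
            rates = c.rate_median * np.exp(
                c.rate_sigma * rng.standard_normal(len(years))
                - 0.5 * c.rate_sigma**2
            )
            for yi in np.nonzero(applied & active)[0]:
                records.append(
                    ApplicationRecord(
                        record_id=f"A{rid:07d}",
                        chemical=c.name,
                        pounds=float(rates[yi] * acres),
                        year=int(years[yi]),
                        field_id=f.field_id,
                        section_id=f.section_id,
                        crop_code=f.crop_code,
                        treated_acres=acres,
                    )
                )
                rid += 1
    return records


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

_COV_FREQS = {
    "bmi_cat": [0.35, 0.35, 0.30],
    "menarche_cat": [0.2, 0.25, 0.55],
    "menopause_cat": [0.15, 0.7, 0.15],
    "births_cat": [0.15, 0.15, 0.3, 0.4],
    "oc_cat": [0.45, 0.25, 0.3],
    "ht_cat": [0.45, 0.2, 0.05, 0.2, 0.1],
}


def _far_point(rng, params, field_tree, radius):
    x0, y0, x1, y1 = params.region
    for _ in range(200):
        x = rng.uniform(x0, x1)
        y = rng.uniform(y0, y1)
        if not field_tree.query(Point(x, y).buffer(radius + 100, quad_segs=4)).size:
            return x, y
    return x, y  # dense landscape: accept a possibly-near point


def _near_point(rng, params, fields):
    f = fields[int(rng.integers(len(fields)))]
    minx, miny, maxx, maxy = f.geometry.bounds
    # within drift range of the field edge
    side = int(rng.integers(4))
    off = rng.uniform(30.0, 400.0)
    if side == 0:
        return rng.uniform(minx, maxx), maxy + off
    if side == 1:
        return rng.uniform(minx, maxx), miny - off
    if side == 2:
        return maxx + off, rng.uniform(miny, maxy)
    return minx - off, rng.uniform(miny, maxy)


def _make_spells(pid, setting, segments, rng, params, fields, field_tree, radius):
    """Turn a list of (start, end) year segments into located spells."""
    spells = []
    for start, end in segments:
        if rng.uniform() < params.out_of_state_prob:
            spells.append(
                AddressSpell(pid, setting, start, end, None, None, "none",
                             in_state=False, on_farm=bool(rng.uniform() < 0.05),
                             in_counties=False)
            )
            continue
        if rng.uniform() < params.near_field_prob:
            x, y = _near_point(rng, params, fields)
        else:
            x, y = _far_point(rng, params, field_tree, radius)
        tier = "parcel" if rng.uniform() < 0.92 else "zip"
        spells.append(
            AddressSpell(pid, setting, start, end, float(x), float(y), tier,
                         in_state=True, on_farm=bool(rng.uniform() < 0.1),
                         in_counties=bool(rng.uniform() < 0.9))
        )
    return spells


def _segment_years(start, end, n_breaks, rng):
    if n_breaks <= 0 or end <= start:
        return [(start, end)]
    breaks = sorted(rng.choice(np.arange(start + 1, end + 1),
                               size=min(n_breaks, end - start), replace=False))
    segs, s = [], start
    for b in breaks:
        segs.append((s, int(b) - 1))
        s = int(b)
    segs.append((s, end))
    return segs


def generate_population(
    fields: list[FieldPolygon],
    params: ScenarioParams,
    n_persons: int,
    rng=None,
    config: RunConfig | None = None,
    id_offset: int = 0,
) -> tuple[dict[str, list[AddressSpell]], pd.DataFrame]:
    """Histories plus a covariate table (case_status left at 0).

    Residential spells cover the full window (before masking); workplace
    spells cover a subset of years, with gaps standing for years out of
    the workforce.  ``years_in_counties`` is derived from the history so
    the covariate is internally consistent.
    """
    from shapely.strtree import STRtree

    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    config = config or params.run_config()
    tree = STRtree([f.geometry for f in fields])
    radius = config.buffer_radius_m
    histories: dict[str, list[AddressSpell]] = {}
    rows = []
    for i in range(n_persons):
        pid = f"P{id_offset + i:06d}"
        index_year = int(rng.integers(params.index_year_range[0],
                                      params.index_year_range[1] + 1))
        start = config.window_start_year
        span = index_year - start
        n_moves = int(rng.poisson(params.move_rate))
        res_segments = _segment_years(start, index_year, n_moves, rng)
        spells = _make_spells(pid, "R", res_segments, rng, params, fields, tree, radius)
        if rng.uniform() < params.workplace_prob:
            w_start = start + int(rng.integers(0, max(span // 2, 1)))
            w_end = min(index_year, w_start + int(rng.integers(5, max(span, 6))))
            w_segs = _segment_years(w_start, w_end, int(rng.poisson(1.0)), rng)
            spells += _make_spells(pid, "W", w_segs, rng, params, fields, tree, radius)
        histories[pid] = spells

        yic = 0
        for y in range(start, index_year + 1):
            if any(s.setting == "R" and s.covers_year(y) and s.in_counties
                   for s in spells):
                yic += 1
        row = {
            "person_id": pid,
            "case_status": 0,
            "index_year": index_year,
            "age": float(np.clip(rng.normal(61, 7), 50, 80).round(1)),
            "ses_quintile": int(rng.integers(1, 6)),
            "alcohol_weekly": int(rng.uniform() < 0.35),
            "years_in_counties": float(yic),
            "ever_farm_live": int(any(s.on_farm and s.setting == "R" for s in spells)),
            "ever_farm_work": int(any(s.on_farm and s.setting == "W" for s in spells)),
        }
        for cov, freqs in _COV_FREQS.items():
            levels = PERSON_CATEGORIES[cov]
            row[cov] = levels[int(rng.choice(len(levels), p=freqs))]
        rows.append(row)
    persons = pd.DataFrame(rows)
    for cov, levels in PERSON_CATEGORIES.items():
        persons[cov] = pd.Categorical(persons[cov], categories=levels, ordered=True)
    return histories, persons


def mask_histories(
    histories: dict[str, list[AddressSpell]], prob: float, rng
) -> dict[str, list[AddressSpell]]:
    """Independently drop each in-state spell-year with probability
    ``prob``, splitting spells around the dropped years (recall gaps)."""
    if prob <= 0:
        return {pid: list(sp) for pid, sp in histories.items()}
    out: dict[str, list[AddressSpell]] = {}
    for pid, spells in histories.items():
        new: list[AddressSpell] = []
        for s in spells:
            if not s.in_state:
                new.append(s)
                continue
            keep = [y for y in s.years if rng.uniform() >= prob]
            seg_start = None
            prev = None
            for y in keep + [None]:
                if seg_start is None:
                    seg_start = y
                elif y is None or y != prev + 1:
                    new.append(replace(s, start_year=seg_start, end_year=prev))
                    seg_start = y
                prev = y
        out[pid] = new
    return out


# ---------------------------------------------------------------------------
# outcome model and the full study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPool:
    """Source population with everything needed to (re)draw outcomes."""

    fields: list[FieldPolygon]
    applications: list[ApplicationRecord]
    histories: dict[str, list[AddressSpell]]  # unmasked
    persons: pd.DataFrame
    truth_flags: pd.DataFrame  # person x chemical binary, outcome-model scale
    linear_predictor: np.ndarray  # planted effects + covariate effects, no intercept
    config: RunConfig


@dataclass
class SyntheticStudy:
    """A drawn case-control study plus its ground truth."""

    fields: list[FieldPolygon]
    applications: list[ApplicationRecord]
    histories: dict[str, list[AddressSpell]]  # masked
    persons: pd.DataFrame  # with case_status
    truth: dict
    config: RunConfig
    pool: SimulatedPool


def _covariate_lp(persons: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(persons))
    for key, beta in effects.items():
        if ":" in key:
            cov, level = key.split(":", 1)
            lp += beta * (persons[cov].astype(str) == level).to_numpy(float)
        else:
            lp += beta * persons[key].to_numpy(float)
    return lp


def _truth_indicator(flags: dict, chem: str, mode: str) -> int:
    f = flags[chem]
    if mode == "both":
        return int(f.combined == COMBINED_BOTH)
    if mode == "any":
        return int(f.residential_exposed or f.workplace_exposed)
    if mode == "residential":
        return int(f.residential_exposed)
    raise ValueError(f"unknown truth_exposure mode '{mode}'")


def build_pool(
    params: ScenarioParams, n_persons: int | None = None, rng=None
) -> SimulatedPool:
    """Generate the landscape, applications, population and true exposure
    flags (computed on un-masked histories through the exposure engine)."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    config = params.run_config()
    n_persons = n_persons or int(math.ceil(1.3 * (params.n_cases + params.n_controls)))
    fields = generate_landscape(params, rng)
    apps = generate_applications(fields, params, rng)
    histories, persons = generate_population(fields, params, n_persons, rng, config)
    resolved, _ = resolve_applications(apps, fields)
    index = ApplicationIndex(resolved, config)
    truth_rows = []
    for row in persons.itertuples(index=False):
        series = compute_series(row.person_id, row.index_year,
                                histories[row.person_id], index, config)
        imputed = impute_person(series)
        flags = classify_person(imputed, row.index_year, config)
        chems = list(config.chemicals) + (
            ["organochlorines"] if config.organochlorine_group else []
        )
        truth_rows.append(
            {"person_id": row.person_id}
            | {c: _truth_indicator(flags, c, params.truth_exposure)
               for c in chems}
        )
    truth_flags = pd.DataFrame(truth_rows).set_index("person_id")
    lp = _covariate_lp(persons, params.covariate_effects)
    for chem, beta in params.planted_log_or.items():
        lp = lp + beta * truth_flags.loc[persons["person_id"], chem].to_numpy(float)
    return SimulatedPool(fields, apps, histories, persons, truth_flags, lp, config)


def calibrate_alpha(linear_predictor: np.ndarray, target_fraction: float) -> float:
    """Intercept making the expected case fraction hit the target."""

    def expected(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + linear_predictor)))))

    lo, hi = -30.0, 30.0
    if expected(lo) > target_fraction or expected(hi) < target_fraction:
        raise CalibrationError(
            f"case fraction {target_fraction} unattainable with planted effects"
        )
    return brentq(lambda a: expected(a) - target_fraction, lo, hi, xtol=1e-10)


def draw_study(pool: SimulatedPool, params: ScenarioParams, rng) -> pd.DataFrame:
    """Draw case status from the outcome model and sample the quotas.

    The intercept is calibrated by root-finding so the pool's expected
    case count matches the quota fraction; persons are then Bernoulli-
    assigned and the first ``n_cases`` cases and ``n_controls`` controls
    (in pool order) form the study.  Raises if a quota cannot be filled.
    """
    n_total = params.n_cases + params.n_controls
    alpha = calibrate_alpha(pool.linear_predictor, params.n_cases / n_total)
    p = 1.0 / (1.0 + np.exp(-(alpha + pool.linear_predictor)))
    for _ in range(50):
        status = (rng.uniform(size=len(p)) < p).astype(int)
        if status.sum() >= params.n_cases and (1 - status).sum() >= params.n_controls:
            break
    else:
        raise CalibrationError("could not fill case/control quotas from pool")
    persons = pool.persons.copy()
    persons["case_status"] = status
    cases = persons[persons["case_status"] == 1].head(params.n_cases)
    controls = persons[persons["case_status"] == 0].head(params.n_controls)
    return (
        pd.concat([cases, controls])
        .sort_values("person_id")
        .reset_index(drop=True)
    )


def generate_study(params: ScenarioParams) -> SyntheticStudy:
    """End-to-end synthetic study: pool, outcome draw, masking, truth."""
    rng = np.random.default_rng(params.seed)
    pool = build_pool(params, rng=rng)
    persons = draw_study(pool, params, rng)
    selected = set(persons["person_id"])
    masked = mask_histories(
        {pid: sp for pid, sp in pool.histories.items() if pid in selected},
        params.missing_year_prob,
        rng,
    )
    truth = {
        "flags": pool.truth_flags.loc[persons["person_id"]],
        "planted_log_or": dict(params.planted_log_or),
        "covariate_effects": dict(params.covariate_effects),
        "truth_exposure": params.truth_exposure,
    }
    return SyntheticStudy(
        pool.fields, pool.applications, masked, persons, truth, pool.config, pool
    )
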