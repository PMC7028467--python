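"""Missing-year imputation for exposure series.

Two rules are applied, in order:

1. Residential gaps (years with no usable address) take the person's mean
   observed residential density for that chemical, computed over the
   analysis window.  Years spent out of state are *not* imputed — the
   location is known but unassessable — and count as unexposed downstream.
2. Workplace gaps (unemployment, home-making, retirement) take the same
   year's residential value, after step 1, on the assumption that the
   person was at home during working hours.

A series with no observed years at all cannot be mean-imputed; it is
returned unchanged with ``all_missing=True`` so exclusion rules can act.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exposure import (
    STATUS_IMPUTED_MEAN,
    STATUS_IMPUTED_RES,
    STATUS_MISSING,
    STATUS_OBSERVED,
    STATUS_OOS,
    VALUED_STATUSES,
    ExposureSeries,
)


@dataclass(frozen=True)
class MissingnessSummary:
    person_id: str
    setting: str
    years_total: int
    years_missing: int
    years_out_of_state: int

    @property
    def fraction_missing(self) -> float:
        return self.years_missing / self.years_total if self.years_total else 0.0


def impute_residential(series: ExposureSeries) -> ExposureSeries:
    """Fill residential missing years with the person-chemical mean of
    observed years.  Observed and out-of-state years are untouched.
    Idempotent: already-imputed years are left as they are."""
    out = series.copy()
    observed = [
        out.values[y] for y in out.status if out.status[y] == STATUS_OBSERVED
    ]
    missing_years = [y for y in out.status if out.status[y] == STATUS_MISSING]
    if not observed:
        if missing_years:
            out.all_missing = all(
                out.status[y] in (STATUS_MISSING, STATUS_OOS) for y in out.status
            )
        return out
    mean = sum(observed) / len(observed)
    for y in missing_years:
        out.values[y] = mean
        out.status[y] = STATUS_IMPUTED_MEAN
    return out


def impute_workplace(
    work_series: ExposureSeries, residential_imputed: ExposureSeries
) -> ExposureSeries:
    """Fill workplace missing years with the same year's (post-imputation)
    residential value.  If the residential year itself has no value (an
    all-missing residence), the workplace year stays missing."""
    out = work_series.copy()
    still_missing = False
    for y in out.status:
        if out.status[y] != STATUS_MISSING:
            continue
        res_status = residential_imputed.status.get(y)
        if res_status in VALUED_STATUSES:
            out.values[y] = residential_imputed.values[y]
            out.status[y] = STATUS_IMPUTED_RES
        else:
            still_missing = True
    if still_missing and not any(
        out.status[y] in VALUED_STATUSES for y in out.status
    ):
        out.all_missing = True
    return out


def summarize_missingness(series: ExposureSeries) -> MissingnessSummary:
    """Missing/out-of-state year counts over the window.

    Must be computed *before* imputation; a series containing imputed
    years is rejected because the counts would be meaningless.
    """
    statuses = list(series.status.values())
    if any(s in (STATUS_IMPUTED_MEAN, STATUS_IMPUTED_RES) for s in statuses):
        raise ValueError("missingness must be summarised on pre-imputation series")
    return MissingnessSummary(
        person_id=series.person_id,
        setting=series.setting,
        years_total=len(statuses),
        years_missing=sum(1 for s in statuses if s == STATUS_MISSING),
        years_out_of_state=sum(1 for s in statuses if s == STATUS_OOS),
    )


def impute_person(
    series_by_key: dict[tuple[str, str], ExposureSeries]
) -> dict[tuple[str, str], ExposureSeries]:
    """Apply both rules to one person's full set of series.

    Residential series are mean-imputed first; workplace series then copy
    from the imputed residential series of the same chemical.
    """
    out: dict[tuple[str, str], ExposureSeries] = {}
    for (setting, chem), s in series_by_key.items():
        if setting == "R":
            out[(setting, chem)] = impute_residential(s)
    for (setting, chem), s in series_by_key.items():
        if setting == "W":
            res = out.get(("R", chem))
            if res is None:
                raise ValueError(
                    f"workplace series for '{chem}' has no residential counterpart"
                )
            out[(setting, chem)] = impute_workplace(s, res)
    return out
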