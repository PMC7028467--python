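"""Binary exposure classification under window, latency and grouping rules.

A person is exposed to a chemical in a setting when any year of their
exposure-assessment window carries a density strictly above the threshold
(default: greater than zero).  The window runs from the configured start
year (1974) to the index year minus the latency; "excluding L years
before diagnosis" drops years ``index-L+1 .. index`` and retains through
``index - L``.  Years that could not be assessed (out of state, or
residual missing after imputation) count as unexposed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DENSITY_FLOOR, RunConfig
from .exposure import VALUED_STATUSES, ExposureSeries
from .io import AddressSpell

COMBINED_BOTH = "both"
COMBINED_NEITHER = "neither"
COMBINED_DISCORDANT = "discordant"


@dataclass(frozen=True)
class ExposureFlags:
    person_id: str
    chemical: str
    residential_exposed: bool
    workplace_exposed: bool
    combined: str
    window_used: tuple[int, int]
    latency_years: int


class EmptyWindowError(ValueError):
    """The latency lag consumed the entire assessment window."""


def exposure_window(index_year: int, config: RunConfig) -> tuple[int, int]:
    """Closed year interval [window_start_year, index_year - latency]."""
    last = index_year - config.latency_years
    if last < config.window_start_year:
        raise EmptyWindowError(
            f"latency {config.latency_years} empties the window for index "
            f"year {index_year} (start {config.window_start_year})"
        )
    return (config.window_start_year, last)


def classify_chemical(
    series: ExposureSeries, window: tuple[int, int], config: RunConfig
) -> bool:
    """Exposed iff some window year has density above the threshold.

    Unassessed (out-of-state or residual-missing) years count as zero.
    """
    first, last = window
    if last < first:
        raise EmptyWindowError("empty classification window")
    threshold = max(config.density_threshold, DENSITY_FLOOR)
    for y in series.status:
        if first <= y <= last and series.status[y] in VALUED_STATUSES:
            if series.values[y] > threshold:
                return True
    return False


def combine_settings(residential_exposed: bool, workplace_exposed: bool) -> str:
    if residential_exposed and workplace_exposed:
        return COMBINED_BOTH
    if not residential_exposed and not workplace_exposed:
        return COMBINED_NEITHER
    return COMBINED_DISCORDANT


def classify_person(
    series_by_key: dict[tuple[str, str], ExposureSeries],
    index_year: int,
    config: RunConfig,
) -> dict[str, ExposureFlags]:
    """Per-chemical flags plus the pooled organochlorine-group flag."""
    window = exposure_window(index_year, config)
    person_id = next(iter(series_by_key.values())).person_id
    flags: dict[str, ExposureFlags] = {}
    for chem in config.chemicals:
        res = classify_chemical(series_by_key[("R", chem)], window, config)
        work = classify_chemical(series_by_key[("W", chem)], window, config)
        flags[chem] = ExposureFlags(
            person_id, chem, res, work, combine_settings(res, work),
            window, config.latency_years,
        )
    if config.organochlorine_group:
        flags["organochlorines"] = group_flags(
            flags, config.organochlorine_group, "organochlorines"
        )
    return flags


def group_flags(
    per_chemical: dict[str, ExposureFlags],
    members: tuple[str, ...] | list[str],
    group_name: str,
) -> ExposureFlags:
    """Pooled group exposure: exposed in a setting iff any member is.

    Supports subsetting (e.g. restricting the organochlorine group to
    dicofol and endosulfan only).
    """
    missing = [m for m in members if m not in per_chemical]
    if missing:
        raise KeyError(f"group '{group_name}' references unknown chemicals: {missing}")
    if not members:
        raise ValueError(f"group '{group_name}' has no members")
    res = any(per_chemical[m].residential_exposed for m in members)
    work = any(per_chemical[m].workplace_exposed for m in members)
    ref = per_chemical[members[0]]
    return ExposureFlags(
        ref.person_id, group_name, res, work, combine_settings(res, work),
        ref.window_used, ref.latency_years,
    )


def residency_filter(
    histories: dict[str, list[AddressSpell]],
    region_tag: str,
    min_years: int,
    windows: dict[str, tuple[int, int]],
) -> set[str]:
    """Persons with at least ``min_years`` window years covered by a
    residential spell carrying the given tag ('in_state' or 'in_counties')."""
    if region_tag not in ("in_state", "in_counties"):
        raise ValueError(f"unknown region tag '{region_tag}'")
    eligible: set[str] = set()
    for pid, spells in histories.items():
        if pid not in windows:
            continue
        first, last = windows[pid]
        count = 0
        for y in range(first, last + 1):
            for s in spells:
                if s.setting == "R" and s.covers_year(y) and getattr(s, region_tag):
                    count += 1
                    break
        if count >= min_years:
            eligible.add(pid)
    return eligible


def flags_to_frame(all_flags: dict[str, dict[str, ExposureFlags]]):
    """Long-format flags table: one row per person x chemical/group."""
    import pandas as pd

    rows = []
    for pid in all_flags:
        for chem, f in all_flags[pid].items():
            rows.append(
                {
                    "person_id": pid,
                    "chemical": chem,
                    "residential_exposed": int(f.residential_exposed),
                    "workplace_exposed": int(f.workplace_exposed),
                    "combined": f.combined,
                    "latency_years": f.latency_years,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "chemical", "residential_exposed",
            "workplace_exposed", "combined", "latency_years",
        ],
    )
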