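"""Readers and writers for the pipeline's file formats.

Field polygons travel as GeoJSON FeatureCollections; applications, address
histories and person tables travel as comma-separated UTF-8 CSV with a
header row.  Every reader validates its schema and either returns fully
validated objects or raises with the identifier of the offending row —
rows are never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .config import HIGH_CERTAINTY_TIERS, LOW_CERTAINTY_TIERS, SQ_M_PER_ACRE


class SchemaError(ValueError):
    """A required column or attribute is absent."""


class ValidationError(ValueError):
    """A row violates its contract; the message carries its identifier."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldPolygon:
    """A crop field: the spatial unit receiving pesticide applications."""

    field_id: str
    crop_code: str
    survey_start_year: int
    survey_end_year: int
    geometry: BaseGeometry
    section_id: str | None = None

    @property
    def area_acres(self) -> float:
        return self.geometry.area / SQ_M_PER_ACRE

    def covers_year(self, year: int) -> bool:
        return self.survey_start_year <= year <= self.survey_end_year


@dataclass(frozen=True)
class ApplicationRecord:
    """One reported pesticide application."""

    record_id: str
    chemical: str
    pounds: float
    year: int
    field_id: str | None
    section_id: str | None
    crop_code: str | None
    treated_acres: float


@dataclass(frozen=True)
class AddressSpell:
    """A geocoded residential ('R') or workplace ('W') occupancy interval.

    Years are a closed interval [start_year, end_year].  ``x``/``y`` are
    planar metre coordinates and may be None when the location is unknown.
    """

    person_id: str
    setting: str
    start_year: int
    end_year: int
    x: float | None
    y: float | None
    certainty_tier: str
    in_state: bool
    on_farm: bool
    in_counties: bool = False

    @property
    def location_known(self) -> bool:
        return self.x is not None and self.y is not None

    @property
    def high_certainty(self) -> bool:
        return self.certainty_tier in HIGH_CERTAINTY_TIERS

    def covers_year(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


PERSON_CATEGORIES = {
    "bmi_cat": ["<25", "25-29", ">=30"],
    "menarche_cat": ["<12", "12", ">12"],
    "menopause_cat": ["<45", "45-54", ">=55"],
    "births_cat": ["0", "1", "2", ">=3"],
    "oc_cat": ["none", "1-4y", ">=5y"],
    "ht_cat": ["none", "E", "P", "E+P", "mixed"],
}

PERSON_COLUMNS = [
    "person_id",
    "case_status",
    "index_year",
    "age",
    "ses_quintile",
    "bmi_cat",
    "menarche_cat",
    "menopause_cat",
    "births_cat",
    "oc_cat",
    "ht_cat",
    "alcohol_weekly",
    "years_in_counties",
    "ever_farm_live",
    "ever_farm_work",
]


# ---------------------------------------------------------------------------
# field polygons (GeoJSON)
# ---------------------------------------------------------------------------

_FIELD_PROPS = ("field_id", "crop_code", "survey_start_year", "survey_end_year")


def _looks_geographic(geoms: list[BaseGeometry]) -> bool:
    """Heuristic: degree coordinates have a tiny bbox and implausibly
    small areas for a crop field (1 deg^2 would be ~1e10 m^2; a real field
    in degrees has area ~1e-5)."""
    if not geoms:
        return False
    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    in_degree_range = -180 <= minx <= maxx <= 180 and -90 <= miny <= maxy <= 90
    tiny_areas = all(g.area < 1.0 for g in geoms)
    return in_degree_range and tiny_areas


def read_fields(path: str | Path) -> list[FieldPolygon]:
    """Read a GeoJSON FeatureCollection of crop-field polygons.

    Coordinates must be in a planar projected system in metres; layers that
    look like geographic (degree) coordinates are refused with a request to
    reproject upstream.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    fields: list[FieldPolygon] = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        for col in _FIELD_PROPS:
            if col not in props:
                raise SchemaError(f"feature {i}: missing required property '{col}'")
        geom = shape(feat["geometry"])
        fid = str(props["field_id"])
        if geom.is_empty or not geom.is_valid:
            raise ValidationError(f"field '{fid}': invalid or empty polygon")
        if geom.area <= 0:
            raise ValidationError(f"field '{fid}': non-positive area")
        fields.append(
            FieldPolygon(
                field_id=fid,
                crop_code=str(props["crop_code"]),
                survey_start_year=int(props["survey_start_year"]),
                survey_end_year=int(props["survey_end_year"]),
                geometry=geom,
                section_id=(
                    str(props["section_id"]) if props.get("section_id") is not None else None
                ),
            )
        )
    if _looks_geographic([f.geometry for f in fields]):
        raise ValidationError(
            "coordinates look geographic (degrees); reproject to a planar "
            "metre CRS before use"
        )
    seen: dict[tuple, str] = {}
    for f in fields:
        key = (f.field_id, f.survey_start_year, f.survey_end_year)
        if key in seen:
            raise ValidationError(
                f"duplicate field_id '{f.field_id}' within survey period "
                f"{f.survey_start_year}-{f.survey_end_year}"
            )
        seen[key] = f.field_id
    return fields


def write_fields(fields: list[FieldPolygon], path: str | Path) -> None:
    feats = []
    for f in fields:
        props = {
            "field_id": f.field_id,
            "crop_code": f.crop_code,
            "survey_start_year": f.survey_start_year,
            "survey_end_year": f.survey_end_year,
        }
        if f.section_id is not None:
            props["section_id"] = f.section_id
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(f.geometry)}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# application records (CSV)
# ---------------------------------------------------------------------------

_APP_COLUMNS = [
    "record_id",
    "chemical",
    "pounds",
    "year",
    "field_id",
    "section_id",
    "crop_code",
    "treated_acres",
]


def read_applications(path: str | Path) -> list[ApplicationRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _APP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"applications file missing columns: {missing}")
    records: list[ApplicationRecord] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        rid = row.record_id
        try:
            year = int(row.year)
        except ValueError:
            raise ValidationError(f"line {line_no}: unparseable year '{row.year}'")
        if not 1000 <= year <= 9999:
            raise ValidationError(f"line {line_no}: year {year} is not 4-digit")
        pounds = float(row.pounds)
        if pounds < 0:
            raise ValidationError(f"record '{rid}': negative pounds ({pounds})")
        acres = float(row.treated_acres)
        if acres <= 0:
            raise ValidationError(f"record '{rid}': non-positive treated_acres")
        records.append(
            ApplicationRecord(
                record_id=rid,
                chemical=row.chemical,
                pounds=pounds,
                year=year,
                field_id=row.field_id or None,
                section_id=row.section_id or None,
                crop_code=row.crop_code or None,
                treated_acres=acres,
            )
        )
    return records


def write_applications(records: list[ApplicationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "chemical": r.chemical,
                "pounds": repr(r.pounds),
                "year": r.year,
                "field_id": r.field_id or "",
                "section_id": r.section_id or "",
                "crop_code": r.crop_code or "",
                "treated_acres": repr(r.treated_acres),
            }
            for r in records
        ],
        columns=_APP_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# address histories (CSV)
# ---------------------------------------------------------------------------

_HIST_COLUMNS = [
    "person_id",
    "setting",
    "start_year",
    "end_year",
    "x",
    "y",
    "certainty_tier",
    "in_state",
    "on_farm",
]


def read_histories(path: str | Path) -> dict[str, list[AddressSpell]]:
    """Read address spells grouped by person.

    Gaps between a person's spells are legal (missing years); overlapping
    spells within the same person+setting are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _HIST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"histories file missing columns: {missing}")
    has_counties = "in_counties" in df.columns
    spells: dict[str, list[AddressSpell]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.person_id
        if row.setting not in ("R", "W"):
            raise ValidationError(
                f"line {line_no}: setting must be 'R' or 'W', got '{row.setting}'"
            )
        start, end = int(row.start_year), int(row.end_year)
        if end < start:
            raise ValidationError(
                f"person '{pid}': end_year {end} < start_year {start}"
            )
        tier = row.certainty_tier
        if tier not in HIGH_CERTAINTY_TIERS | LOW_CERTAINTY_TIERS:
            raise ValidationError(
                f"person '{pid}': unknown certainty_tier '{tier}'"
            )
        spells.setdefault(pid, []).append(
            AddressSpell(
                person_id=pid,
                setting=row.setting,
                start_year=start,
                end_year=end,
                x=float(row.x) if row.x != "" else None,
                y=float(row.y) if row.y != "" else None,
                certainty_tier=tier,
                in_state=bool(int(row.in_state)),
                on_farm=bool(int(row.on_farm)),
                in_counties=bool(int(row.in_counties)) if has_counties else False,
            )
        )
    for pid, sp in spells.items():
        for setting in ("R", "W"):
            sub = sorted(
                (s for s in sp if s.setting == setting), key=lambda s: s.start_year
            )
            for a, b in zip(sub, sub[1:]):
                if b.start_year <= a.end_year:
                    raise ValidationError(
                        f"person '{pid}' setting {setting}: overlapping spells "
                        f"[{a.start_year},{a.end_year}] and [{b.start_year},{b.end_year}]"
                    )
    return spells


def write_histories(spells: dict[str, list[AddressSpell]], path: str | Path) -> None:
    rows = []
    for pid in spells:
        for s in spells[pid]:
            rows.append(
                {
                    "person_id": s.person_id,
                    "setting": s.setting,
                    "start_year": s.start_year,
                    "end_year": s.end_year,
                    "x": repr(s.x) if s.x is not None else "",
                    "y": repr(s.y) if s.y is not None else "",
                    "certainty_tier": s.certainty_tier,
                    "in_state": int(s.in_state),
                    "on_farm": int(s.on_farm),
                    "in_counties": int(s.in_counties),
                }
            )
    pd.DataFrame(rows, columns=_HIST_COLUMNS + ["in_counties"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# person covariate/outcome table (CSV)
# ---------------------------------------------------------------------------


def read_persons(path: str | Path) -> pd.DataFrame:
    """Read the person covariate/outcome table, validating categorical codes."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PERSON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"persons file missing columns: {missing}")
    if df["person_id"].duplicated().any():
        dups = df.loc[df["person_id"].duplicated(), "person_id"].tolist()
        raise ValidationError(f"duplicate person_id: {dups}")
    out = pd.DataFrame({"person_id": df["person_id"]})
    for col in ("case_status", "alcohol_weekly", "ever_farm_live", "ever_farm_work"):
        vals = df[col].astype(int)
        if not vals.isin([0, 1]).all():
            raise ValidationError(f"{col} must be 0/1")
        out[col] = vals
    out["index_year"] = df["index_year"].astype(int)
    out["age"] = df["age"].astype(float)
    out["years_in_counties"] = df["years_in_counties"].astype(float)
    ses = df["ses_quintile"].astype(int)
    bad = ~ses.isin([1, 2, 3, 4, 5])
    if bad.any():
        pid = df.loc[bad, "person_id"].iloc[0]
        raise ValidationError(f"person '{pid}': ses_quintile out of range 1-5")
    out["ses_quintile"] = ses
    for col, levels in PERSON_CATEGORIES.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            pid = df.loc[bad, "person_id"].iloc[0]
            raise ValidationError(
                f"person '{pid}': invalid {col} '{df.loc[bad, col].iloc[0]}' "
                f"(allowed: {levels})"
            )
        out[col] = pd.Categorical(df[col], categories=levels, ordered=True)
    return out[PERSON_COLUMNS]


def write_persons(df: pd.DataFrame, path: str | Path) -> None:
    df[PERSON_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long-format exposure series CSV (shared by exposure + imputation stages)
# ---------------------------------------------------------------------------

SERIES_COLUMNS = ["person_id", "setting", "chemical", "year", "density", "status"]


def write_series_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = SERIES_COLUMNS + (["provenance"] if "provenance" in df.columns else [])
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_series_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"series file missing columns: {missing}")
    return df
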