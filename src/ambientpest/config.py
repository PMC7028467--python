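"""Run configuration for the exposure-reconstruction pipeline.

All geometry is assumed to live in a single planar projected coordinate
system with metre units; the package validates this assumption but never
reprojects.  Time resolution is the calendar year throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: 1 international acre in square metres.
SQ_M_PER_ACRE = 4046.8564224

#: Organochlorine pesticides pooled as a single exposure group.
ORGANOCHLORINES = (
    "aldrin",
    "chlordane",
    "dicofol",
    "dieldrin",
    "endosulfan",
    "lindane",
    "methoxychlor",
    "toxaphene",
)

#: Geocode certainty tiers treated as reliable point locations.
HIGH_CERTAINTY_TIERS = frozenset(
    {"building", "parcel", "nearest_parcel", "street", "intersection"}
)
#: Coarse tiers (zip/city/county/state centroids or failed geocodes).
LOW_CERTAINTY_TIERS = frozenset({"zip", "city", "county", "state", "none"})


class ConfigError(ValueError):
    """Raised when a RunConfig violates its invariants."""


@dataclass
class RunConfig:
    """Parameters controlling exposure assessment and classification.

    Parameters
    ----------
    buffer_radius_m
        Radius of the circular buffer drawn around each address, in metres.
        The default 500 m reflects the distance at which drift from
        commercial applications is detectable in household dust.
    window_start_year
        First calendar year of the exposure-assessment window (default 1974,
        the first year with complete state pesticide-use reporting).
    latency_years
        Number of years immediately before the index year excluded from the
        window (0 for the primary analysis; 10 and 20 in sensitivity runs).
    density_threshold
        Annual buffer density (lb/acre) strictly above which a year counts
        as exposed.  The default 0 implements the "greater than zero" rule;
        a numerical floor absorbs floating-point dust (see
        :data:`DENSITY_FLOOR`).
    crs_note
        Free-text identifier of the planar projected CRS of all geometry.
    chemicals
        Chemical names analysed.  Application records for other chemicals
        are retained on read but ignored by classification.
    organochlorine_group
        Chemical names pooled into the organochlorine group exposure.
    low_certainty_is_missing
        If True (default), person-years located only by a low-certainty
        geocode are treated as missing locations and later imputed.
    seed
        Seed for any stochastic step run under this configuration.
    """

    buffer_radius_m: float = 500.0
    window_start_year: int = 1974
    latency_years: int = 0
    density_threshold: float = 0.0
    crs_note: str = "planar-metres"
    chemicals: tuple[str, ...] = (
        "dicofol",
        "endosulfan",
        "chlorpyrifos",
        "diazinon",
        "1,3-dichloropropene",
    )
    organochlorine_group: tuple[str, ...] = ("dicofol", "endosulfan")
    low_certainty_is_missing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.chemicals = tuple(self.chemicals)
        self.organochlorine_group = tuple(self.organochlorine_group)
        if self.buffer_radius_m <= 0:
            raise ConfigError("buffer_radius_m must be positive")
        if self.latency_years < 0:
            raise ConfigError("latency_years must be non-negative")
        if self.density_threshold < 0:
            raise ConfigError("density_threshold must be non-negative")
        unknown = set(self.organochlorine_group) - set(self.chemicals)
        if unknown:
            raise ConfigError(
                f"organochlorine_group contains unknown chemicals: {sorted(unknown)}"
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chemicals"] = list(self.chemicals)
        d["organochlorine_group"] = list(self.organochlorine_group)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """SHA-256 of the canonical YAML rendering, for provenance logs."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


#: Densities at or below this floor are treated as zero when classifying.
DENSITY_FLOOR = 1e-12
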