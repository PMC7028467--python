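import numpy as np
import pytest
from shapely.geometry import box

from ambientpest.config import RunConfig
from ambientpest.io import AddressSpell, ApplicationRecord, FieldPolygon


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_field(field_id="F1", rect=(0, 0, 400, 400), crop="cotton",
               years=(1970, 2020), section=None):
    return FieldPolygon(
        field_id=field_id,
        crop_code=crop,
        survey_start_year=years[0],
        survey_end_year=years[1],
        geometry=box(*rect),
        section_id=section,
    )


def make_app(record_id="A1", chemical="chlorpyrifos", pounds=100.0, year=1990,
             field_id="F1", section_id=None, crop_code=None, treated_acres=10.0):
    return ApplicationRecord(
        record_id=record_id, chemical=chemical, pounds=pounds, year=year,
        field_id=field_id, section_id=section_id, crop_code=crop_code,
        treated_acres=treated_acres,
    )


def make_spell(pid="P1", setting="R", start=1974, end=2008, x=0.0, y=0.0,
               tier="parcel", in_state=True, on_farm=False, in_counties=True):
    return AddressSpell(
        person_id=pid, setting=setting, start_year=start, end_year=end,
        x=x, y=y, certainty_tier=tier, in_state=in_state, on_farm=on_farm,
        in_counties=in_counties,
    )
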