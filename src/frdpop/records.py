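"""Field-record schema for street-survey dog sightings.

One :class:`DogRecord` corresponds to a single sighting of a free-roaming
dog during a two-round photographic sight-resight survey.  Collections of
records are carried as :class:`pandas.DataFrame` objects with the columns in
:data:`DOG_RECORD_COLUMNS`; the dataclass exists for single-record
construction and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import pandas as pd

DOMAINS = ("city", "suburb")
SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("pup_young", "adult", "unknown")
FEMALE_STATUSES = ("pregnant", "lactating", "non_pregnant", "not_applicable", "unknown")
BODY_CONDITIONS = ("thin_emaciated", "ideal_overweight", "unknown")
SOCIAL_ORGS = ("single", "pair", "pack", "unknown")
LOCATION_CATEGORIES = (
    "vacant_lot",
    "street_sidewalk",
    "alley",
    "public_park",
    "restaurant_garbage",
)
LOCATION_CATEGORIES_ALL = LOCATION_CATEGORIES + ("other", "unknown")

DOG_RECORD_COLUMNS = [
    "stratum_id",
    "domain",
    "survey_round",
    "sex",
    "age_class",
    "female_status",
    "body_condition",
    "social_org",
    "location_category",
    "lat",
    "lon",
    "resighted",
]

_ENUM_DOMAINS = {
    "domain": DOMAINS,
    "sex": SEXES,
    "age_class": AGE_CLASSES,
    "female_status": FEMALE_STATUSES,
    "body_condition": BODY_CONDITIONS,
    "social_org": SOCIAL_ORGS,
    "location_category": LOCATION_CATEGORIES_ALL,
}


def body_condition_from_score(score: int) -> str:
    """Collapse a 1-5 visual body-condition score to the two-level class.

    Scores 1-2 are thin/emaciated, 3-5 ideal/overweight (ICAM scale).
    """
    if not 1 <= int(score) <= 5:
        raise ValueError(f"body condition score must be 1-5, got {score}")
    return "thin_emaciated" if score <= 2 else "ideal_overweight"


@dataclass
class DogRecord:
    stratum_id: str
    domain: str
    survey_round: int
    sex: str = "unknown"
    age_class: str = "unknown"
    female_status: str = "not_applicable"
    body_condition: str = "unknown"
    social_org: str = "unknown"
    location_category: str = "unknown"
    lat: Optional[float] = None
    lon: Optional[float] = None
    resighted: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.survey_round not in (1, 2):
            raise ValueError(f"survey_round must be 1 or 2, got {self.survey_round!r}")
        if isinstance(self.body_condition, int):
            self.body_condition = body_condition_from_score(self.body_condition)
        for name, allowed in _ENUM_DOMAINS.items():
            if name == "domain":
                continue
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")
        if self.sex != "female" and self.female_status not in ("not_applicable", "unknown"):
            raise ValueError("female_status other than not_applicable requires sex=female")
        if self.resighted and self.survey_round != 2:
            raise ValueError("resighted flag is only meaningful on round-2 records")


def records_to_frame(records: list[DogRecord]) -> pd.DataFrame:
    """Convert a list of records to the canonical DataFrame layout."""
    data = {f.name: [getattr(r, f.name) for r in records] for f in fields(DogRecord)}
    return pd.DataFrame(data, columns=DOG_RECORD_COLUMNS)


def as_frame(records) -> pd.DataFrame:
    """Accept either a DataFrame or a list of DogRecord and return a frame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in DOG_RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"record frame is missing columns: {missing}")
        return records
    return records_to_frame(list(records))
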