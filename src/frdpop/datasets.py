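"""Packaged inputs from the Kerman free-roaming dog street survey.

The survey covered 25 of 100 city blocks (one randomly chosen colour of a
four-colour blocking) plus all 15 suburbs of greater Kerman; these are the
pooled sight-resight counts, the published city-vs-suburb attribute
contingency tables, and the reference model configuration.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .demographics import ContingencyTable2x2
from .estimation import CaptureRecaptureCount

#: Human population of Kerman city and suburbs (census).
HUMAN_POPULATION = 547_558
#: Surface area of the study region, km2.
AREA_KM2 = 220.0
#: City blocks surveyed out of the 100-block grid.
SAMPLED_FRACTION_CITY = 25 / 100
#: Total dogs recorded across both rounds and domains, and the sex tallies.
SEX_COUNTS = {"male": 986, "female": 303, "unknown": 220}
TOTAL_RECORDED = 1509
#: Within-city location proportions as published (percent).
LOCATION_PCT = {
    "vacant_lot": 46.2,
    "street_sidewalk": 24.4,
    "alley": 24.4,
    "public_park": 4.2,
    "restaurant_garbage": 0.8,
}
#: Initial model stocks from the field estimate (dogs).
INITIAL_PUPPY_YOUNG = 1547
INITIAL_ADULT = 5234
BASELINE_POPULATION = INITIAL_PUPPY_YOUNG + INITIAL_ADULT


def _data_path(name: str):
    return resources.files("frdpop.data").joinpath(name)


def sight_resight_counts() -> list[CaptureRecaptureCount]:
    """Pooled city and suburb two-round counts."""
    frame = pd.read_csv(_data_path("kerman_counts.csv"))
    return [
        CaptureRecaptureCount(
            str(row.stratum_id), str(row.domain), int(row.n1), int(row.n2), int(row.r)
        )
        for row in frame.itertuples()
    ]


def city_counts() -> CaptureRecaptureCount:
    return next(c for c in sight_resight_counts() if c.domain == "city")


def suburb_counts() -> CaptureRecaptureCount:
    return next(c for c in sight_resight_counts() if c.domain == "suburb")


def attribute_tables() -> dict[str, ContingencyTable2x2]:
    """Published city-vs-suburb 2x2 tables keyed by ``variable:interest``."""
    frame = pd.read_csv(_data_path("kerman_table1.csv"))
    out = {}
    for row in frame.itertuples():
        key = f"{row.variable}:{row.interest}"
        out[key] = ContingencyTable2x2(
            a=int(row.city_interest),
            b=int(row.city_reference),
            c=int(row.suburb_interest),
            d=int(row.suburb_reference),
        )
    return out


def model_config() -> dict:
    """Reference model configuration (vital rates, stocks, scenario grid)."""
    with _data_path("model.yaml").open("r") as fh:
        return yaml.safe_load(fh)
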