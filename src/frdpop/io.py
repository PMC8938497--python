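"""File readers/writers and configuration parsing.

CSV dialect: comma-separated, UTF-8, header row required, ``.`` decimal
separator.  Config files are YAML (JSON being a subset); unknown keys are
rejected to fail fast on typos.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import CaptureRecaptureCount
from .records import DOG_RECORD_COLUMNS, _ENUM_DOMAINS

log = logging.getLogger("frdpop")

_REQUIRED_RECORD_COLUMNS = [
    c for c in DOG_RECORD_COLUMNS if c not in ("lat", "lon", "resighted")
]


@dataclass
class ParseReport:
    """Per-column tallies of values that could not be parsed as valid enum
    levels and were loaded as 'unknown' instead."""

    coerced: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.coerced.values())


def read_dog_records(path) -> tuple[pd.DataFrame, ParseReport]:
    """Read a sighting-record CSV, coercing bad enum values to unknown.

    Rows are never silently dropped: unparseable categorical values are
    replaced by ``unknown`` (or ``not_applicable`` where that is the
    neutral level), counted in the returned :class:`ParseReport`, and
    logged once per column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path} contains no records")
    missing = [c for c in _REQUIRED_RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    for optional in ("lat", "lon"):
        if optional not in frame.columns:
            frame[optional] = np.nan
    if "resighted" not in frame.columns:
        frame["resighted"] = False

    report = ParseReport()
    frame["survey_round"] = pd.to_numeric(frame["survey_round"], errors="coerce")
    bad_round = ~frame["survey_round"].isin([1, 2])
    if bad_round.any():
        raise ValueError(f"{path}: survey_round must be 1 or 2 ({int(bad_round.sum())} bad rows)")
    frame["survey_round"] = frame["survey_round"].astype(int)

    # body condition may arrive as a 1-5 score; collapse to the two classes
    bc = frame["body_condition"].astype(str).str.strip()
    numeric = pd.to_numeric(bc, errors="coerce")
    score = numeric.between(1, 5)
    bc = bc.mask(score & (numeric <= 2), "thin_emaciated")
    bc = bc.mask(score & (numeric > 2), "ideal_overweight")
    frame["body_condition"] = bc

    for column, allowed in _ENUM_DOMAINS.items():
        if column == "domain":
            bad = ~frame[column].isin(allowed)
            if bad.any():
                raise ValueError(
                    f"{path}: domain must be one of {allowed} "
                    f"({int(bad.sum())} bad rows)"
                )
            continue
        values = frame[column].astype(str).str.strip().str.lower()
        fallback = "not_applicable" if column == "female_status" else "unknown"
        bad = ~values.isin(allowed)
        if bad.any():
            report.coerced[column] = int(bad.sum())
            log.warning(
                "%s: %d unparseable %s value(s) coerced to %r",
                path, int(bad.sum()), column, fallback,
            )
        frame[column] = values.where(~bad, fallback)
    frame["resighted"] = frame["resighted"].fillna(False).astype(bool)
    return frame[DOG_RECORD_COLUMNS + [c for c in frame.columns if c not in DOG_RECORD_COLUMNS]], report


def read_counts_csv(path) -> list[CaptureRecaptureCount]:
    """Read per-stratum sight-resight counts (`stratum_id,domain,n1,n2,r`)."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = ["stratum_id", "domain", "n1", "n2", "r"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    if frame.empty:
        raise ValueError(f"{path} contains no counts")
    return [
        CaptureRecaptureCount(
            str(row.stratum_id), str(row.domain), int(row.n1), int(row.n2), int(row.r)
        )
        for row in frame.itertuples()
    ]


_CONFIG_KEYS = {
    "params", "distributions", "initial", "K", "spay_rates",
    "horizons", "dt", "schedule", "monte_carlo",
}
_PARAM_KEYS = {"Q", "Np", "M", "fm", "Du1"}


def load_config(path) -> dict:
    """Load and validate a model/scenario configuration (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "params" in cfg:
        bad = set(cfg["params"]) - _PARAM_KEYS
        if bad:
            raise ValueError(f"{path}: unknown parameter keys {sorted(bad)}")
    if "schedule" in cfg and cfg["schedule"] not in ("constant", "ramp"):
        raise ValueError(f"{path}: schedule must be 'constant' or 'ramp'")
    return cfg


def write_report(path, payload: dict, *, seed=None, config=None) -> None:
    """Write a JSON report with a reproducibility metadata block."""
    meta = {"package": "frdpop"}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config"] = str(config)
    out = {"metadata": meta, **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_frame(path, frame: pd.DataFrame, *, seed=None, config=None) -> None:
    """Write a CSV with a commented metadata header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        meta = {"package": "frdpop"}
        if seed is not None:
            meta["seed"] = seed
        if config is not None:
            meta["config"] = str(config)
        fh.write(f"# {json.dumps(meta)}\n")
        frame.to_csv(fh, index=False)


def read_frame(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_frame` (metadata line skipped)."""
    return pd.read_csv(path, comment="#")
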