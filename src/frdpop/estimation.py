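"""Sight-resight abundance estimation for closed dog populations.

Two photographic street surveys are run one week apart over the same
transects.  With ``n1`` dogs sighted in round one, ``n2`` in round two and
``r`` of the round-two dogs recognised from round one, the closed-population
abundance is estimated by the Lincoln-Petersen estimator with Chapman's
small-sample correction::

    N_hat = (n1 + 1) * (n2 + 1) / (r + 1) - 1

The estimator is (nearly) unbiased when detection is independent between
rounds and across dogs and the population is closed between rounds — the
design assumptions of a two-round sight-resight survey.

A city surveyed in a random subset of blocks is extrapolated by the inverse
sampled fraction; suburbs surveyed exhaustively are a census and enter
without extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .records import DOMAINS


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CaptureRecaptureCount:
    """Pooled two-round sighting counts for one survey stratum."""

    stratum_id: str
    domain: str
    n1: int
    n2: int
    r: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        for name in ("n1", "n2", "r"):
            value = getattr(self, name)
            if isinstance(value, bool) or not float(value).is_integer():
                raise ValueError(f"{name} must be an integer count, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
            object.__setattr__(self, name, int(value))
        if self.r > min(self.n1, self.n2):
            raise ValueError(
                f"r={self.r} exceeds min(n1, n2)={min(self.n1, self.n2)}: "
                "resights cannot outnumber either round"
            )


@dataclass(frozen=True)
class AbundanceEstimate:
    point: float
    by_domain: Mapping[str, float]
    sampled_fraction_city: float
    extrapolation_factor: float
    rounded_total: int


@dataclass(frozen=True)
class DensityIndices:
    dogs_per_100_people: float
    dogs_per_km2: float
    human_to_dog_ratio: float
    human_population: float
    area_km2: float
    dogs_per_km_route: Optional[float] = None


def chapman_estimate(counts: CaptureRecaptureCount) -> float:
    """Chapman-corrected Lincoln-Petersen point estimate, unrounded."""
    return (counts.n1 + 1) * (counts.n2 + 1) / (counts.r + 1) - 1


def chapman_variance(counts: CaptureRecaptureCount) -> float:
    """Approximate variance of the Chapman estimator (Seber).

    Extension beyond the core survey analysis: the two-round design on its
    own does not support a meaningful uncertainty statement about detection
    heterogeneity, so this is opt-in and reported separately.
    """
    n1, n2, r = counts.n1, counts.n2, counts.r
    return ((n1 + 1) * (n2 + 1) * (n1 - r) * (n2 - r)) / ((r + 1) ** 2 * (r + 2))


def chapman_ci(counts: CaptureRecaptureCount, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI around the Chapman estimate (extension)."""
    point = chapman_estimate(counts)
    half = z * math.sqrt(chapman_variance(counts))
    return (max(0.0, point - half), point + half)


def total_abundance(
    city_counts: CaptureRecaptureCount,
    suburb_counts: CaptureRecaptureCount,
    sampled_fraction_city: float,
) -> AbundanceEstimate:
    """City-plus-suburb abundance with city-only extrapolation.

    The city estimate comes from a random subset of blocks and is scaled by
    ``1 / sampled_fraction_city``; the suburb estimate covers every suburb
    and is used as-is.  Full precision is kept throughout; only
    ``rounded_total`` is rounded (half-up).
    """
    if not 0 < sampled_fraction_city <= 1:
        raise ValueError(
            f"sampled_fraction_city must be in (0, 1], got {sampled_fraction_city!r}"
        )
    factor = 1.0 / sampled_fraction_city
    city = chapman_estimate(city_counts) * factor
    suburb = chapman_estimate(suburb_counts)
    point = city + suburb
    return AbundanceEstimate(
        point=point,
        by_domain={"city": city, "suburb": suburb},
        sampled_fraction_city=sampled_fraction_city,
        extrapolation_factor=factor,
        rounded_total=round_half_up(point),
    )


def density_indices(
    estimate: AbundanceEstimate | float,
    human_population: float,
    area_km2: float,
    route_km: Optional[float] = None,
) -> DensityIndices:
    """Per-capita and per-area density indices from the unrounded estimate.

    ``route_km`` (total surveyed street length) is optional and never
    defaulted; when given, a dogs-per-km-of-route index is added.
    """
    n = estimate.point if isinstance(estimate, AbundanceEstimate) else float(estimate)
    if human_population <= 0:
        raise ValueError(f"human_population must be positive, got {human_population!r}")
    if area_km2 <= 0:
        raise ValueError(f"area_km2 must be positive, got {area_km2!r}")
    per_route = None
    if route_km is not None:
        if route_km <= 0:
            raise ValueError(f"route_km must be positive, got {route_km!r}")
        per_route = n / route_km
    return DensityIndices(
        dogs_per_100_people=100.0 * n / human_population,
        dogs_per_km2=n / area_km2,
        human_to_dog_ratio=human_population / n,
        human_population=human_population,
        area_km2=area_km2,
        dogs_per_km_route=per_route,
    )


def counts_from_records(records) -> list[CaptureRecaptureCount]:
    """Aggregate per-stratum (n1, n2, r) counts from raw sighting records."""
    from .records import as_frame

    frame = as_frame(records)
    out = []
    for (stratum, domain), grp in frame.groupby(["stratum_id", "domain"], sort=True):
        n1 = int((grp["survey_round"] == 1).sum())
        round2 = grp[grp["survey_round"] == 2]
        n2 = int(len(round2))
        r = int(round2["resighted"].astype(bool).sum())
        out.append(CaptureRecaptureCount(str(stratum), str(domain), n1, n2, r))
    return out


def pool_counts(
    counts: Sequence[CaptureRecaptureCount], domain: str, stratum_id: Optional[str] = None
) -> CaptureRecaptureCount:
    """Pool per-block counts into a single per-domain stratum.

    The headline estimate is computed on domain pools (all surveyed city
    blocks together, all suburbs together); per-block estimation is possible
    but noisier because block-level resights are small.
    """
    sub = [c for c in counts if c.domain == domain]
    if not sub:
        raise ValueError(f"no counts with domain {domain!r}")
    return CaptureRecaptureCount(
        stratum_id=stratum_id or f"{domain}_pooled",
        domain=domain,
        n1=sum(c.n1 for c in sub),
        n2=sum(c.n2 for c in sub),
        r=sum(c.r for c in sub),
    )
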