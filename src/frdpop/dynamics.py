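"""Age-structured stock-and-flow model of a free-roaming dog population.

Two stocks — puppies/young dogs (< 12 months) and adults — change through
annual flows: births into the young stock, density-dependent deaths in both
stocks, and maturation of young dogs into adults.  Density dependence enters
through a logistic-style factor ``kt = 1 - Population / K`` that scales both
births and natural deaths, so the population saturates at the carrying
capacity ``K``.

Vital rates are specified as finite annual rates and converted to
instantaneous rates::

    B = fm * Q * Np                    finite birth rate
    A = (B / (B - M)) * ln(1 + B - M)  instantaneous birth rate
    D = (M / (B - M)) * ln(1 + B - M)  instantaneous mortality rate

where ``Q`` is litters per female per year, ``Np`` pups per litter, ``M``
the finite annual mortality and ``fm`` the female fraction parameter.  At
``B == M`` the transforms reduce to their analytic limits ``A = B, D = M``.

The sterilization intervention spays a fraction ``s`` of the female stock
each year.  Spaying attenuates the effective birth rate to ``A * (1 - s)``,
removes spayed females from the breeding pool, and adds a spay-linked loss
term ``QS * Birth.Rate`` to both death flows (``QS`` is the spayed-female
share of the female population).  Two modelling quirks of the source system
are retained deliberately because they define the model being reproduced:
the young-stock death flow cancels algebraically against the maturation
bracket (young dogs leave only by maturation), and births are attenuated by
``(1 - s)`` twice (once through the effective birth rate, once through the
breeding-pool restriction).  See docs/methods.md.

Integration is explicit Euler, one step per ``dt`` years (default annual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

#: Carrying capacities used in the reference scenario grid (dogs): derived
#: from a 33:1 human:dog ratio, 110 dogs/km2 and 250 dogs/km2 respectively.
K1, K2, K3 = 16592, 24200, 55000

_B_EQ_M_TOL = 1e-12


@dataclass(frozen=True)
class VitalRateParams:
    """Finite vital rates: Q litters/female/year, Np pups/litter, M annual
    mortality fraction, fm female proportion, du1 maturation time (years)."""

    Q: float
    Np: float
    M: float
    fm: float = 0.3125
    du1: float = 1.0

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError(f"Q must be > 0, got {self.Q!r}")
        if self.Np <= 0:
            raise ValueError(f"Np must be > 0, got {self.Np!r}")
        if not 0 < self.M < 1:
            raise ValueError(f"M must be in (0, 1), got {self.M!r}")
        if not 0 < self.fm < 1:
            raise ValueError(f"fm must be in (0, 1), got {self.fm!r}")
        if self.du1 <= 0:
            raise ValueError(f"du1 must be > 0, got {self.du1!r}")


@dataclass(frozen=True)
class DerivedRates:
    """Instantaneous rates plus the structural parameters the stepper needs."""

    B: float
    A: float
    D: float
    fm: float = 0.3125
    du1: float = 1.0


@dataclass(frozen=True)
class PopulationState:
    puppy_young: float
    adult: float

    def __post_init__(self) -> None:
        if self.puppy_young < 0 or self.adult < 0:
            raise ValueError("stocks must be non-negative")

    @property
    def population(self) -> float:
        return self.puppy_young + self.adult

    def female(self, fm: float) -> float:
        return self.adult * fm

    def male(self, fm: float) -> float:
        return self.adult * (1.0 - fm)


@dataclass(frozen=True)
class FlowSet:
    """Annual flows evaluated at one state (all in dogs/year except kt)."""

    kt: float
    bi: float
    death1: float
    death2: float
    maturation: float

    @property
    def di(self) -> float:
        return self.death1 + self.death2


def derive_rates(params: VitalRateParams) -> DerivedRates:
    """Finite-to-instantaneous rate conversion, continuous at B == M."""
    B = params.fm * params.Q * params.Np
    diff = B - params.M
    if 1.0 + diff <= 0:
        raise ValueError(f"1 + (B - M) must be positive, got {1.0 + diff!r}")
    if abs(diff) < _B_EQ_M_TOL:
        A, D = B, params.M
    else:
        log_term = math.log1p(diff)
        A = (B / diff) * log_term
        D = (params.M / diff) * log_term
    return DerivedRates(B=B, A=A, D=D, fm=params.fm, du1=params.du1)


def density_factor(population, K):
    """kt = 1 - population / K, clamped to [0, 1]."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("carrying capacity K must be positive")
    population = np.asarray(population, dtype=float)
    if np.any(population < 0):
        raise ValueError("population must be non-negative")
    out = np.clip(1.0 - population / K, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


def _flows(py, ad, A, D, s, K, fm, du1):
    """Flow evaluation shared by the scalar stepper and the ensemble runner.

    Accepts floats or numpy arrays (broadcasting); returns one value per
    flow in a dict.  Written once so that a degenerate ensemble reproduces
    the deterministic trajectory bit-for-bit.
    """
    pop = py + ad
    kt = np.clip(1.0 - pop / K, 0.0, 1.0)
    female = ad * fm
    male = ad - female
    female_w = female * s
    female_f = female - female_w
    birth_rate_eff = A * (1.0 - s)
    qs = np.where(pop > 0, female_w / np.where(pop > 0, pop * fm, 1.0), 0.0)
    bi = birth_rate_eff * (male + female_f) * kt
    death1 = py * D * kt + py * qs * birth_rate_eff
    death2 = ad * D * kt + qs * birth_rate_eff * ad
    maturation = py * (1.0 / du1)
    return {
        "kt": kt,
        "bi": bi,
        "death1": death1,
        "death2": death2,
        "maturation": maturation,
    }


def _euler_update(py, ad, flows, dt):
    # term-by-term as specified: the young-stock death flow cancels against
    # the maturation bracket, leaving births minus maturation
    net_maturation = flows["maturation"] - flows["death1"]
    d_py = flows["bi"] - flows["death1"] - net_maturation
    d_ad = net_maturation - flows["death2"]
    py2 = np.maximum(py + dt * d_py, 0.0)
    ad2 = np.maximum(ad + dt * d_ad, 0.0)
    return py2, ad2


def step(
    state: PopulationState,
    rates: DerivedRates,
    s: float,
    K: float,
    dt: float = 1.0,
) -> tuple[PopulationState, FlowSet]:
    """One explicit-Euler step of length ``dt`` years at spay rate ``s``."""
    if not 0 <= s <= 1:
        raise ValueError(f"spay rate s must be in [0, 1], got {s!r}")
    if K <= 0:
        raise ValueError(f"carrying capacity K must be positive, got {K!r}")
    flows = _flows(
        np.float64(state.puppy_young), np.float64(state.adult),
        rates.A, rates.D, s, K, rates.fm, rates.du1,
    )
    py2, ad2 = _euler_update(state.puppy_young, state.adult, flows, dt)
    if not (np.isfinite(py2) and np.isfinite(ad2)):
        raise ArithmeticError("non-finite stock after update")
    flowset = FlowSet(
        kt=float(flows["kt"]),
        bi=float(flows["bi"]),
        death1=float(flows["death1"]),
        death2=float(flows["death2"]),
        maturation=float(flows["maturation"]),
    )
    return PopulationState(float(py2), float(ad2)), flowset


def constant_schedule(s: float, horizon: int) -> list[float]:
    if not 0 <= s <= 1:
        raise ValueError(f"spay rate must be in [0, 1], got {s!r}")
    return [float(s)] * horizon


def ramp_schedule(target: float, horizon: int) -> list[float]:
    """Linear ramp reaching ``target`` coverage in the final year:
    s_t = target * t / horizon for t = 1..horizon."""
    if not 0 <= target <= 1:
        raise ValueError(f"ramp target must be in [0, 1], got {target!r}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon!r}")
    return [target * t / horizon for t in range(1, horizon + 1)]


@dataclass(frozen=True)
class ScenarioSpec:
    """One intervention scenario: carrying capacity, per-year spay rates,
    horizon in years and integration step."""

    K: float
    spay_schedule: Union[float, Sequence[float]]
    horizon: int
    initial_state: PopulationState
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K!r}")
        if self.horizon < 0:
            raise ValueError(f"horizon must be >= 0, got {self.horizon!r}")
        steps = 1.0 / self.dt
        if self.dt <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError(f"dt must divide 1 year evenly, got {self.dt!r}")
        sched = self.spay_schedule
        if np.isscalar(sched):
            sched = constant_schedule(float(sched), max(self.horizon, 1))
        else:
            sched = [float(x) for x in sched]
            if len(sched) < self.horizon:
                raise ValueError(
                    f"spay schedule has {len(sched)} entries for a "
                    f"{self.horizon}-year horizon"
                )
        for x in sched:
            if not 0 <= x <= 1:
                raise ValueError(f"spay rates must be in [0, 1], got {x!r}")
        object.__setattr__(self, "spay_schedule", tuple(sched))

    @property
    def steps_per_year(self) -> int:
        return int(round(1.0 / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """Annual snapshots of one scenario run.

    ``frame`` has one row per year 0..horizon with stocks, population, the
    flows evaluated at that year's state, and fold change vs the initial
    population.  Year 0 is the initial state.
    """

    frame: pd.DataFrame
    spec: ScenarioSpec

    def population(self, year: int) -> float:
        return float(self.frame.loc[self.frame["year"] == year, "population"].iloc[0])

    @property
    def final_population(self) -> float:
        return float(self.frame["population"].iloc[-1])

    def fold_vs(self, other: "Trajectory") -> pd.Series:
        """Year-by-year population ratio against a matched reference run."""
        return self.frame["population"] / other.frame["population"].to_numpy()


def run_scenario(spec: ScenarioSpec, rates: DerivedRates) -> Trajectory:
    """Iterate the Euler stepper over the horizon, recording annual rows."""
    state = spec.initial_state
    baseline = state.population
    rows = []

    def snapshot(year, st, s):
        fl = _flows(
            np.float64(st.puppy_young), np.float64(st.adult),
            rates.A, rates.D, s, spec.K, rates.fm, rates.du1,
        )
        rows.append(
            {
                "year": year,
                "puppy_young": st.puppy_young,
                "adult": st.adult,
                "population": st.population,
                "spay_rate": s,
                "kt": float(fl["kt"]),
                "bi": float(fl["bi"]),
                "death1": float(fl["death1"]),
                "death2": float(fl["death2"]),
                "maturation": float(fl["maturation"]),
            }
        )

    schedule = spec.spay_schedule
    snapshot(0, state, schedule[0] if spec.horizon > 0 else 0.0)
    for year in range(spec.horizon):
        s = schedule[year]
        for _ in range(spec.steps_per_year):
            state, _fl = step(state, rates, s, spec.K, spec.dt)
        snapshot(year + 1, state, s)
    frame = pd.DataFrame(rows)
    frame["fold_vs_baseline"] = (
        frame["population"] / baseline if baseline > 0 else np.nan
    )
    return Trajectory(frame=frame, spec=spec)


def simulate_paths(
    spec: ScenarioSpec,
    A: np.ndarray,
    D: np.ndarray,
    fm: float,
    du1: float,
) -> np.ndarray:
    """Vectorised scenario run over parameter draws.

    ``A`` and ``D`` are 1-D arrays of instantaneous rates (one entry per
    Monte Carlo draw).  Returns an array of shape ``(horizon + 1, n_draws)``
    of total population by year, using exactly the same update as
    :func:`step`.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    py = np.full_like(A, spec.initial_state.puppy_young)
    ad = np.full_like(A, spec.initial_state.adult)
    out = np.empty((spec.horizon + 1, A.size))
    out[0] = py + ad
    for year in range(spec.horizon):
        s = spec.spay_schedule[year]
        for _ in range(spec.steps_per_year):
            flows = _flows(py, ad, A, D, s, spec.K, fm, du1)
            py, ad = _euler_update(py, ad, flows, spec.dt)
        out[year + 1] = py + ad
    return out
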