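"""Time-invariant distributed-maturation-time population dynamics.

Each life stage is a chain of k identical age classes; transit through the
chain is Erlang distributed with mean delta dd and SD delta/sqrt(k) dd.
Stages are chained egg-larva -> pupa -> adult, stepped once per day by
weather, with oviposition computed after the flow update and injected the
next day.

The daily flow update uses the analytic within-day propagator of the linear
chain: with flow rate nu = k*dx/delta per day, each class advances j
classes with Poisson(nu) probabilities, which reproduces the continuous
Erlang transit statistics exactly and conserves mass to float precision.
A forward-Euler sub-stepping integrator is retained for audit
(``method="euler"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import poisson

from .species_params import (
    SpeciesParams,
    dev_increment,
    fecundity_profile,
    mortality_rate,
    phi_RH,
    phi_T,
)
from .reproduction import oviposition_demand, realized_oviposition, search_alpha

__all__ = [
    "StageState",
    "PopulationState",
    "DailyOutputs",
    "erlang_stats",
    "step_stage",
    "step_day",
    "initialize_population",
]

# reproduction is considered shut off (quiescent adults) below this value
# of phi_T * phi_RH
QUIESCENCE_THRESHOLD = 0.05

# Euler integrator stability bound per sub-step (flow ratio and mortality)
_EULER_BOUND = 0.5


def erlang_stats(delta: float, k: int) -> tuple[float, float]:
    """Mean and SD (dd) of the Erlang stage-transit distribution.

    From k = delta^2 / var: mean = delta, SD = delta / sqrt(k).
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    if not k >= 1:
        raise ValueError("k must be >= 1")
    return float(delta), float(delta) / np.sqrt(k)


@dataclass
class StageState:
    """Age-class densities for one life stage."""

    stage_id: str
    k: int
    delta: float
    densities: np.ndarray  # shape (k,), individuals per class

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (self.k,):
            raise ValueError(
                f"{self.stage_id}: densities must have length k={self.k}"
            )
        if np.any(self.densities < 0):
            raise ValueError(f"{self.stage_id}: negative density")

    @property
    def total(self) -> float:
        return float(self.densities.sum())

    @classmethod
    def empty(cls, stage_id: str, k: int, delta: float) -> "StageState":
        return cls(stage_id=stage_id, k=k, delta=delta, densities=np.zeros(k))


@dataclass
class PopulationState:
    """Full population state: one StageState per stage plus bookkeeping."""

    stages: dict[str, StageState]
    day: int = 0
    pending_eggs: float = 0.0   # oviposition from the previous day
    quiescent: bool = False

    @property
    def total(self) -> float:
        return sum(s.total for s in self.stages.values())


@dataclass
class DailyOutputs:
    """Per-day diagnostics emitted by :func:`step_day`."""

    day: int
    dx: dict[str, float]
    mu: dict[str, float]
    phi_T: float
    phi_RH: float
    demand: float
    realized_oviposition: float
    new_pupae: float
    new_adults: float
    adult_deaths: float
    totals: dict[str, float] = field(default_factory=dict)


def _poisson_kernel(lam: float, k: int) -> np.ndarray:
    # shift pmf over 0..k; mass beyond k exits regardless of source class
    return poisson.pmf(np.arange(k + 1), lam)


def step_stage(
    state: StageState,
    dx: float,
    mu: float,
    inflow: float,
    method: str = "analytic",
) -> tuple[StageState, float]:
    """Advance one stage by one day; returns the new state and the outflow.

    Mortality is applied to standing densities first, then ``inflow``
    enters class 1 and the chain advances by the day's flow. With mu = 0,
    total change equals inflow - outflow to float precision.
    """
    if dx < 0 or inflow < 0:
        raise ValueError("dx and inflow must be >= 0")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")

    N = state.densities * (1.0 - mu)
    N = N.copy()
    N[0] += inflow
    lam = state.k * dx / state.delta
    if lam <= 0:
        return replace(state, densities=N), 0.0

    if method == "analytic":
        kern = _poisson_kernel(lam, state.k)
        before = N.sum()
        advanced = np.convolve(N, kern)[: state.k]
        outflow = before - advanced.sum()
    elif method == "euler":
        nsub = max(1, int(np.ceil(lam / _EULER_BOUND)))
        r = lam / nsub
        outflow = 0.0
        advanced = N
        for _ in range(nsub):
            flow = r * advanced
            advanced = advanced - flow
            advanced[1:] += flow[:-1]
            outflow += flow[-1]
    else:
        raise ValueError(f"unknown integration method {method!r}")

    # guard against convolution round-off dipping below zero
    advanced = np.maximum(advanced, 0.0)
    return replace(state, densities=advanced), max(0.0, float(outflow))


def initialize_population(sp: SpeciesParams, n0: float) -> PopulationState:
    """Deterministic start: n0 adults spread over the first 10% of adult classes."""
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    stages = {
        sid: StageState.empty(sid, sp.stages[sid].erlang_k, sp.stages[sid].delta)
        for sid in ("egg_larva", "pupa", "adult")
    }
    if n0 > 0:
        k = sp.stages["adult"].erlang_k
        nfill = max(1, int(np.ceil(0.1 * k)))
        stages["adult"].densities[:nfill] = n0 / nfill
    return PopulationState(stages=stages)


def adult_age_days(sp: SpeciesParams) -> np.ndarray:
    """Age (days at the reference temperature) at each adult class midpoint."""
    adult = sp.stages["adult"]
    age_dd = (np.arange(adult.erlang_k) + 0.5) * adult.delta / adult.erlang_k
    return age_dd / (sp.reproduction.T_opt - adult.theta_L)


def _fecundity_by_class(sp: SpeciesParams) -> np.ndarray:
    return np.array([fecundity_profile(x, sp) for x in adult_age_days(sp)])


def step_day(
    pop: PopulationState,
    wx,
    sp: SpeciesParams,
    quiescence: bool = True,
    method: str = "analytic",
    _fec_cache: dict = {},
) -> tuple[PopulationState, DailyOutputs]:
    """Advance the whole population by one day of weather.

    ``wx`` must expose ``tmean`` (degC) and ``rh`` (%). Daily order:
    scalars, mortality, flows (egg-larva -> pupa -> adult), then
    oviposition from the post-flow adult structure, injected next day.
    """
    for attr in ("tmean", "rh"):
        if not hasattr(wx, attr):
            raise ValueError(f"weather record lacks '{attr}'")
    T = float(wx.tmean)
    RH = float(wx.rh)

    pT = phi_T(T, sp)
    pRH = phi_RH(RH, sp)
    is_quiescent = quiescence and (pT * pRH <= QUIESCENCE_THRESHOLD)

    dx = {
        sid: dev_increment(T, sp.stages[sid]) for sid in ("egg_larva", "pupa", "adult")
    }
    adult_dx_raw = dx["adult"]
    if is_quiescent:
        # quiescent adults age on the longer quiescent delay
        dx["adult"] *= sp.stages["adult"].delta / sp.stages["quiescent_adult"].delta

    mu_el = mortality_rate(T, "egg_larva", sp)
    mu_pa = mortality_rate(T, "pupa_adult", sp)

    egg_state, egg_out = step_stage(
        pop.stages["egg_larva"], dx["egg_larva"], mu_el, pop.pending_eggs, method
    )
    pupa_state, pupa_out = step_stage(
        pop.stages["pupa"], dx["pupa"], mu_pa, egg_out, method
    )
    adult_state, adult_out = step_stage(
        pop.stages["adult"], dx["adult"], mu_pa, pupa_out, method
    )
    # adults leaving the last class die of old age

    key = sp.name
    if key not in _fec_cache:
        _fec_cache[key] = _fecundity_by_class(sp)
    demand = oviposition_demand(
        adult_state, T, RH, sp, fecundity_by_class=_fec_cache[key]
    )
    alpha = search_alpha(adult_dx_raw, sp)
    S = realized_oviposition(demand.D, sp.reproduction.H, alpha)

    new_pop = PopulationState(
        stages={"egg_larva": egg_state, "pupa": pupa_state, "adult": adult_state},
        day=pop.day + 1,
        pending_eggs=S,
        quiescent=is_quiescent,
    )
    out = DailyOutputs(
        day=pop.day,
        dx=dx,
        mu={"egg_larva": mu_el, "pupa_adult": mu_pa},
        phi_T=pT,
        phi_RH=pRH,
        demand=demand.D,
        realized_oviposition=S,
        new_pupae=egg_out,
        new_adults=pupa_out,
        adult_deaths=adult_out,
        totals={sid: st.total for sid, st in new_pop.stages.items()},
    )
    return new_pop, out
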