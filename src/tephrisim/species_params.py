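"""Per-species biodemographic functions (BDFs) and constants.

Each species ships as a frozen, human-readable YAML file transcribing the
published parameter table: stage delays and thermal thresholds, Erlang age
class counts, the nonlinear developmental rate, age-specific fecundity,
temperature/humidity oviposition scalars, and temperature-dependent
mortality.  This module loads, validates and evaluates those functions.

All scalar evaluators are total functions of finite inputs: rates are
floored at zero below the lower threshold and scalars are clamped to
[0, 1] after evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "StageParams",
    "ReproductionParams",
    "MortalityForm",
    "SpeciesParams",
    "available_species",
    "load_species",
    "dev_rate",
    "dev_increment",
    "symmetric_window",
    "phi_T",
    "phi_RH",
    "mortality_rate",
    "fecundity_profile",
    "daily_rate_from_survival",
]

STAGE_IDS = ("egg_larva", "pupa", "adult", "quiescent_adult")
STAGE_GROUPS = ("egg_larva", "pupa_adult")

_SPECIES_FILES = {
    "medfly": "medfly.yaml",
    "melon_fly": "melon_fly.yaml",
    "oriental_fly": "oriental_fly.yaml",
    "mexfly": "mexfly.yaml",
}

# Oviposition scalars are max-normalized over [theta_L, theta_U + margin]
# so every species' temperature scalar attains 1 somewhere in its range.
_PHI_T_MARGIN = 5.0
_PHI_T_GRID = 4001


@dataclass(frozen=True)
class StageParams:
    """Delay-model constants for one life stage."""

    stage_id: str
    delta: float        # thermal delay, degree-days
    theta_L: float      # lower developmental threshold, degC
    theta_U: float      # upper inflection temperature, degC
    b: float            # nonlinear decay base
    a: float            # printed rate coefficient, 1/day/degC
    erlang_k: int       # number of age classes

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"{self.stage_id}: delta must be > 0")
        if not self.theta_L < self.theta_U:
            raise ValueError(f"{self.stage_id}: theta_L must be < theta_U")
        if not self.erlang_k >= 1:
            raise ValueError(f"{self.stage_id}: erlang_k must be >= 1")
        if not self.b > 1:
            raise ValueError(f"{self.stage_id}: b must be > 1")


@dataclass(frozen=True)
class ReproductionParams:
    """Fecundity profile, oviposition scalars and functional-response constants."""

    gamma: float
    phi_base: float
    x0: float               # pre-oviposition age offset, days at 25 degC
    exp_offset: float       # extra offset in the decay exponent
    sr: float               # sex ratio
    H: float                # constant host level
    alpha_coeff: float      # host fraction discoverable per dd of adult time
    T_opt: float
    phiT_spec: dict
    phiRH_spec: dict
    phiT_norm: float = 1.0  # computed max of the raw temperature scalar

    def __post_init__(self) -> None:
        if not 0 < self.sr <= 1:
            raise ValueError("sr must be in (0, 1]")
        if not self.H > 0:
            raise ValueError("H must be > 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not self.phi_base > 1:
            raise ValueError("phi_base must be > 1")


@dataclass(frozen=True)
class MortalityForm:
    """Tagged temperature-mortality form for one stage group."""

    form: Literal["polynomial", "piecewise_exponential", "alias"]
    spec: dict


@dataclass(frozen=True)
class SpeciesParams:
    name: str
    stages: dict[str, StageParams]
    reproduction: ReproductionParams
    mortality: dict[str, MortalityForm]
    rate_audit: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [s for s in STAGE_IDS if s not in self.stages]
        if missing:
            raise ValueError(f"{self.name}: missing stages {missing}")

    def stage(self, stage_id: str) -> StageParams:
        return self.stages[stage_id]


def available_species() -> tuple[str, ...]:
    return tuple(sorted(_SPECIES_FILES))


def _read_yaml(name: str) -> dict:
    path = resources.files("tephrisim.data").joinpath(_SPECIES_FILES[name])
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def _validate_raw(raw: dict, name: str) -> None:
    for key in ("name", "stages", "reproduction", "mortality"):
        if key not in raw:
            raise ValueError(f"{name}: parameter file missing '{key}'")
    for sid in STAGE_IDS:
        if sid not in raw["stages"]:
            raise ValueError(f"{name}: parameter file missing stage '{sid}'")
    for grp in STAGE_GROUPS:
        if grp not in raw["mortality"]:
            raise ValueError(f"{name}: parameter file missing mortality '{grp}'")
    for scalar in ("phi_T", "phi_RH"):
        form = raw["reproduction"][scalar].get("form")
        known = {"window", "rational", "polynomial", "scaled_polynomial"}
        if form not in known:
            raise ValueError(f"{name}: unknown {scalar} form {form!r}")


def load_species(name: str) -> SpeciesParams:
    """Load the frozen parameter set for one of the four shipped species.

    Parameters
    ----------
    name : str
        One of ``medfly``, ``melon_fly``, ``oriental_fly``, ``mexfly``.
    """
    if name not in _SPECIES_FILES:
        raise KeyError(
            f"unknown species {name!r}; available: {', '.join(available_species())}"
        )
    raw = _read_yaml(name)
    _validate_raw(raw, name)

    stages = {
        sid: StageParams(stage_id=sid, **raw["stages"][sid]) for sid in STAGE_IDS
    }
    rep_raw = dict(raw["reproduction"])
    phiT_spec = rep_raw.pop("phi_T")
    phiRH_spec = rep_raw.pop("phi_RH")
    mortality = {
        grp: MortalityForm(form=raw["mortality"][grp]["form"],
                           spec=dict(raw["mortality"][grp]))
        for grp in STAGE_GROUPS
    }
    # max-normalization constant for phi_T, computed on a fixed fine grid
    lo = stages["adult"].theta_L
    hi = stages["adult"].theta_U + _PHI_T_MARGIN
    grid = np.linspace(lo, hi, _PHI_T_GRID)
    raw_vals = np.array([_phi_T_raw(float(t), phiT_spec) for t in grid])
    norm = float(raw_vals.max())
    if norm <= 0:
        raise ValueError(f"{name}: phi_T vanishes over [{lo}, {hi}]")

    reproduction = ReproductionParams(
        phiT_spec=phiT_spec, phiRH_spec=phiRH_spec, phiT_norm=norm, **rep_raw
    )
    audit = tuple(
        (float(item["a"]), tuple(item["stages"]))
        for item in raw.get("rate_audit", [])
    )
    return SpeciesParams(
        name=raw["name"],
        stages=stages,
        reproduction=reproduction,
        mortality=mortality,
        rate_audit=audit,
    )


# ---------------------------------------------------------------------------
# developmental rate and physiological time


def dev_rate(T: float, sp: StageParams) -> float:
    """Proportional development per day, R(T) = a(T-θL)/(1+b^(T-θU)).

    Evaluated with the printed coefficient `a`; floored at 0 for T <= θL.
    """
    if T <= sp.theta_L:
        return 0.0
    return sp.a * (T - sp.theta_L) / (1.0 + sp.b ** (T - sp.theta_U))


def dev_increment(T: float, sp: StageParams) -> float:
    """Daily increment of physiological time Δx(T) in dd/day.

    Normalized form of the developmental rate (a ≡ 1/Δ): equals (T - θL)
    on the linear range and decays toward 0 above the inflection θU.
    """
    if T <= sp.theta_L:
        return 0.0
    return (T - sp.theta_L) / (1.0 + sp.b ** (T - sp.theta_U))


# ---------------------------------------------------------------------------
# oviposition scalars


def symmetric_window(x: float, lo: float, hi: float) -> float:
    """Concave symmetric scalar: 0 at both limits, 1 at the midpoint.

    Implemented as the normalized parabola 4(x-lo)(hi-x)/(hi-lo)^2,
    floored at 0 outside [lo, hi].
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got ({lo}, {hi})")
    return max(0.0, 4.0 * (x - lo) * (hi - x) / (hi - lo) ** 2)


def _polyval_ascending(coeffs, x: float) -> float:
    # coefficient lists are stored constant-first, as printed
    return sum(c * x ** i for i, c in enumerate(coeffs))


def _phi_T_raw(T: float, spec: dict) -> float:
    form = spec["form"]
    if form == "window":
        return symmetric_window(T, spec["lo"], spec["hi"])
    if form == "rational":
        if T <= spec["theta_L"]:
            return 0.0
        return spec["a"] * (T - spec["theta_L"]) / (
            1.0 + spec["b"] ** (T - spec["theta_U"])
        )
    if form == "polynomial":
        return max(0.0, _polyval_ascending(spec["coeffs"], T))
    raise ValueError(f"unknown phi_T form {form!r}")


def phi_T(T: float, sp: SpeciesParams) -> float:
    """Oviposition temperature scalar in [0, 1] (max-normalized)."""
    rep = sp.reproduction
    return min(1.0, max(0.0, _phi_T_raw(T, rep.phiT_spec) / rep.phiT_norm))


def phi_RH(RH: float, sp: SpeciesParams) -> float:
    """Oviposition relative-humidity scalar in [0, 1]."""
    if not 0.0 <= RH <= 100.0:
        raise ValueError(f"RH must be in [0, 100], got {RH}")
    spec = sp.reproduction.phiRH_spec
    form = spec["form"]
    if form == "window":
        v = symmetric_window(RH, spec["lo"], spec["hi"])
    elif form == "polynomial":
        v = _polyval_ascending(spec["coeffs"], RH)
    elif form == "scaled_polynomial":
        v = spec["factor"] * _polyval_ascending(spec["coeffs"], RH)
    else:
        raise ValueError(f"unknown phi_RH form {form!r}")
    return min(1.0, max(0.0, v))


# ---------------------------------------------------------------------------
# mortality


def _mortality_raw(T: float, form: MortalityForm) -> float:
    if form.form == "polynomial":
        return _polyval_ascending(form.spec["coeffs"], T)
    if form.form == "piecewise_exponential":
        s = form.spec
        if T < s["T_break"]:
            return s["c1"] * math.exp(s["r1"] * T)
        return s["c2"] * math.exp(s["r2"] * T)
    raise ValueError(f"cannot evaluate mortality form {form.form!r}")


def mortality_rate(T: float, stage_group: str, sp: SpeciesParams) -> float:
    """Proportion dying per day in [0, 1] for a stage group.

    ``stage_group`` is ``egg_larva`` or ``pupa_adult``; alias forms resolve
    to the referenced group before evaluation.
    """
    if stage_group not in STAGE_GROUPS:
        raise KeyError(f"unknown stage group {stage_group!r}")
    form = sp.mortality[stage_group]
    if form.form == "alias":
        form = sp.mortality[form.spec["of"]]
    return min(1.0, max(0.0, _mortality_raw(T, form)))


# ---------------------------------------------------------------------------
# fecundity


def fecundity_profile(x: float, sp: SpeciesParams) -> float:
    """Eggs per female per day at reference temperature, for age x in days.

    Zero before the pre-oviposition offset x0; afterwards
    gamma*(x - x0)/phi_base^(x - x0 - exp_offset).
    """
    if x < 0:
        raise ValueError("age must be >= 0")
    rep = sp.reproduction
    if x < rep.x0:
        return 0.0
    u = x - rep.x0
    return rep.gamma * u / rep.phi_base ** (u - rep.exp_offset)


# ---------------------------------------------------------------------------
# life-table arithmetic


def daily_rate_from_survival(p: float, d: float) -> tuple[float, float]:
    """Convert a stage survival proportion over d days to daily rates.

    Returns ``(daily survivorship, daily mortality)`` where the daily
    survivorship is the geometric mean p**(1/d).
    """
    if not 0 < p <= 1:
        raise ValueError("survival proportion must be in (0, 1]")
    if not d > 0:
        raise ValueError("duration must be > 0")
    s = p ** (1.0 / d)
    return s, 1.0 - s
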