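"""Oviposition demand and the ratio-dependent demand-driven functional response.

Daily demand D sums the age-specific fecundity over the adult age classes,
scaled by the temperature and humidity scalars and the sex ratio. Realized
oviposition S saturates with both the demand/host ratio and host
discoverability:

    S = H * (1 - exp(-(D/H) * (1 - exp(-alpha*H/D))))

so S <= min(D, H) and S -> H*(1 - exp(-alpha)) as D -> inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .species_params import SpeciesParams, fecundity_profile, phi_RH, phi_T

__all__ = [
    "DemandBreakdown",
    "oviposition_demand",
    "realized_oviposition",
    "search_alpha",
]

_ALPHA_CAP = 1.0 - 1e-9


@dataclass(frozen=True)
class DemandBreakdown:
    phi_T: float
    phi_RH: float
    fecundity_sum: float  # sum over adult classes of f(x_i) * N_i, eggs/day
    sr: float
    D: float              # eggs/day


def oviposition_demand(
    adults, T: float, RH: float, sp: SpeciesParams, fecundity_by_class=None
) -> DemandBreakdown:
    """Daily demand for oviposition sites by all adult females.

    ``adults`` is the adult StageState; class ages are taken at class
    midpoints, converted to days at the reference temperature via
    x = age_dd / (T_opt - theta_L_adult).
    """
    rep = sp.reproduction
    pT = phi_T(T, sp)
    pRH = phi_RH(RH, sp)
    N = np.asarray(adults.densities, dtype=float)
    if fecundity_by_class is None:
        stage = sp.stages["adult"]
        age_dd = (np.arange(stage.erlang_k) + 0.5) * stage.delta / stage.erlang_k
        ages = age_dd / (rep.T_opt - stage.theta_L)
        fecundity_by_class = np.array([fecundity_profile(x, sp) for x in ages])
    fsum = float(np.dot(fecundity_by_class, N))
    D = pT * pRH * rep.sr * fsum
    return DemandBreakdown(phi_T=pT, phi_RH=pRH, fecundity_sum=fsum, sr=rep.sr, D=D)


def realized_oviposition(D: float, H: float, alpha: float) -> float:
    """Realized oviposition S (eggs/day) given demand D, hosts H, search alpha.

    Continuous at D = 0 (S -> D in the demand-limited regime).
    """
    if D < 0 or H <= 0 or not 0.0 <= alpha < 1.0:
        raise ValueError("require D >= 0, H > 0, 0 <= alpha < 1")
    if D == 0.0:
        return 0.0
    # expm1 keeps the demand- and search-limited tails accurate
    inner = -math.expm1(-alpha * H / D)
    return -H * math.expm1(-(D / H) * inner)


def search_alpha(dx_adult: float, sp: SpeciesParams) -> float:
    """Proportion of hosts discoverable during the day's adult increment."""
    if dx_adult < 0:
        raise ValueError("dx_adult must be >= 0")
    return min(_ALPHA_CAP, sp.reproduction.alpha_coeff * dx_adult)
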