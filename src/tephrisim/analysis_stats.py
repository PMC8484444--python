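"""Marginal-effects OLS on simulation outputs.

Fits annual pupal production against user-chosen covariates plus optional
pairwise interaction products, and evaluates marginal effects as the
partial derivative at the sample means of the partner variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .species_params import SpeciesParams, mortality_rate
from .weather import WeatherSeries

__all__ = [
    "RegressionModel",
    "fit_marginal_regression",
    "marginal_effect",
    "thermal_stress_covariates",
]


@dataclass(frozen=True)
class RegressionModel:
    intercept: float
    coefficients: dict[str, float]          # main effects, by variable name
    interaction_coefficients: dict[tuple[str, str], float]
    means: dict[str, float]                 # sample means of main effects
    r_squared: float
    residual_variance: float
    stderr: dict[str, float]


def _interaction_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}:{pair[1]}"


def fit_marginal_regression(
    table: pd.DataFrame,
    interactions: list[tuple[str, str]] | None = None,
    response: str = "pupae",
) -> RegressionModel:
    """OLS of ``response`` on all other columns plus pairwise products.

    Raises on rank deficiency, naming the collinear terms.
    """
    interactions = [tuple(p) for p in (interactions or [])]
    if response not in table.columns:
        raise ValueError(f"table lacks response column {response!r}")
    main_vars = [c for c in table.columns if c != response]
    if not main_vars:
        raise ValueError("no predictor columns")
    for a, b in interactions:
        for v in (a, b):
            if v not in main_vars:
                raise ValueError(f"interaction references unknown variable {v!r}")

    zero_var = [v for v in main_vars if table[v].std() == 0]
    if zero_var:
        raise ValueError(f"zero-variance predictors: {zero_var}")

    X = table[main_vars].astype(float).copy()
    for pair in interactions:
        X[_interaction_name(pair)] = table[pair[0]] * table[pair[1]]
    if len(table) <= X.shape[1] + 1:
        raise ValueError("need more rows than coefficients")

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        pairs = [
            (a, b)
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1:]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {pairs}")

    fit = sm.OLS(table[response].astype(float), Xc).fit()
    params = fit.params
    bse = fit.bse
    return RegressionModel(
        intercept=float(params["const"]),
        coefficients={v: float(params[v]) for v in main_vars},
        interaction_coefficients={
            pair: float(params[_interaction_name(pair)]) for pair in interactions
        },
        means={v: float(table[v].mean()) for v in main_vars},
        r_squared=float(fit.rsquared),
        residual_variance=float(fit.mse_resid),
        stderr={k: float(bse[k]) for k in params.index},
    )


def marginal_effect(model: RegressionModel, var: str) -> float:
    """d(response)/d(var) at the sample means of interaction partners."""
    if var not in model.coefficients:
        raise KeyError(
            f"unknown variable {var!r}; have {sorted(model.coefficients)}"
        )
    effect = model.coefficients[var]
    for (a, b), coef in model.interaction_coefficients.items():
        if var == a:
            effect += coef * model.means[b]
        elif var == b:
            effect += coef * model.means[a]
    return effect


def thermal_stress_covariates(
    series: WeatherSeries, sp: SpeciesParams, stage_group: str = "egg_larva"
) -> dict[str, float]:
    """Ready-made regression covariates for a cell's weather.

    Returns the average annual sum of daily mortality rates on days below
    the lower developmental threshold (``cold_mu``) and above the upper
    inflection (``heat_mu``), plus the annual mean temperature and RH.
    """
    stage = sp.stages["egg_larva"]
    df = series.frame
    years = df["date"].dt.year
    mu = np.array([mortality_rate(t, stage_group, sp) for t in df["tmean"]])
    cold = pd.Series(np.where(df["tmean"] < stage.theta_L, mu, 0.0)).groupby(
        years
    ).sum()
    heat = pd.Series(np.where(df["tmean"] > stage.theta_U, mu, 0.0)).groupby(
        years
    ).sum()
    return {
        "cold_mu": float(cold.mean()),
        "heat_mu": float(heat.mean()),
        "tmean": float(df["tmean"].mean()),
        "rh": float(df["rh"].mean()),
    }
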