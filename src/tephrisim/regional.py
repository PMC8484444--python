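"""Multi-year, multi-cell simulation runs and the favorability index.

A cell is run continuously (no annual reset) through its whole weather
series; the annual metric is the cumulative daily flux of individuals
entering the pupal stage. Cross-year statistics omit the first calendar
year (model equilibration), cells above the elevation cutoff are masked,
and the favorability index normalizes each cell's mean annual pupae by the
map maximum over unmasked cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .population_dynamics import initialize_population, step_day
from .species_params import SpeciesParams
from .weather import WeatherSeries

__all__ = [
    "CellSummary",
    "run_cell",
    "run_cell_trace",
    "summarize_years",
    "favorability_map",
    "run_lattice",
    "export_table",
    "export_ascii_grid",
    "read_ascii_grid",
    "ELEVATION_CUTOFF_M",
]

log = logging.getLogger(__name__)

ELEVATION_CUTOFF_M = 2000.0
DEFAULT_N0 = 10.0
FI_BOUNDARY = 0.5  # favorability classification boundary for isoline export


@dataclass
class CellSummary:
    cell_id: str
    lon: float
    lat: float
    elevation_m: float
    annual_pupae: dict[int, float]
    mean: float = np.nan
    sd: float = np.nan
    cv: float = np.nan
    fi: float = np.nan
    masked: bool = False


def run_cell(
    series: WeatherSeries,
    sp: SpeciesParams,
    n0: float = DEFAULT_N0,
    quiescence: bool = True,
) -> dict[int, float]:
    """Continuous multi-year run; returns {calendar year: cumulative new pupae}."""
    annual, _ = run_cell_trace(series, sp, n0, quiescence, keep_daily=False)
    return annual


def run_cell_trace(
    series: WeatherSeries,
    sp: SpeciesParams,
    n0: float = DEFAULT_N0,
    quiescence: bool = True,
    keep_daily: bool = True,
) -> tuple[dict[int, float], pd.DataFrame | None]:
    """As :func:`run_cell`, optionally also returning the full daily trace."""
    years = np.unique(series.years)
    if len(years) < 2:
        raise ValueError(
            f"need >= 2 calendar years of weather, got {len(years)}"
        )
    pop = initialize_population(sp, n0)
    annual: dict[int, float] = {int(y): 0.0 for y in years}
    rows = [] if keep_daily else None
    year_arr = series.years
    for i, wx in enumerate(series):
        pop, out = step_day(pop, wx, sp, quiescence=quiescence)
        annual[int(year_arr[i])] += out.new_pupae
        if keep_daily:
            rows.append(
                {
                    "date": wx.date,
                    "tmean": wx.tmean,
                    "rh": wx.rh,
                    "phi_T": out.phi_T,
                    "phi_RH": out.phi_RH,
                    "demand": out.demand,
                    "oviposition": out.realized_oviposition,
                    "new_pupae": out.new_pupae,
                    "egg_larva": out.totals["egg_larva"],
                    "pupa": out.totals["pupa"],
                    "adult": out.totals["adult"],
                }
            )
    trace = pd.DataFrame(rows) if keep_daily else None
    return annual, trace


def summarize_years(annual) -> tuple[float, float, float]:
    """Mean, SD and CV of yearly values, omitting the first (burn-in) year.

    SD uses the sample estimator (ddof=1); CV = SD/mean (nan when mean is 0).
    """
    values = list(annual.values()) if isinstance(annual, dict) else list(annual)
    if len(values) < 2:
        raise ValueError("need >= 2 yearly values (first year is discarded)")
    kept = np.asarray(values[1:], dtype=float)
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1)) if len(kept) > 1 else 0.0
    cv = sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def favorability_map(
    cells: list[CellSummary], elevation_cutoff: float = ELEVATION_CUTOFF_M
) -> list[CellSummary]:
    """Compute the favorability index FI = mean / map-max over unmasked cells.

    Cells above the elevation cutoff are masked: excluded from the map
    maximum and left with FI = nan.
    """
    for c in cells:
        c.masked = c.elevation_m > elevation_cutoff
    unmasked = [c for c in cells if not c.masked]
    if not unmasked:
        raise ValueError("all cells masked by the elevation cutoff")
    top = max(c.mean for c in unmasked)
    if not top > 0:
        raise ValueError("no unmasked cell with positive mean annual pupae")
    for c in cells:
        c.fi = np.nan if c.masked else c.mean / top
    return cells


def run_lattice(
    lattice: pd.DataFrame,
    weather_for_cell,
    sp: SpeciesParams,
    n0: float = DEFAULT_N0,
    elevation_cutoff: float = ELEVATION_CUTOFF_M,
    quiescence: bool = True,
) -> list[CellSummary]:
    """Run every cell of a lattice table and summarize.

    ``lattice`` needs columns cell_id, lon, lat, elev_m; ``weather_for_cell``
    maps a lattice row to a WeatherSeries (e.g. a file reader or a seeded
    synthetic generator). Cells are independent; any order gives identical
    results.
    """
    required = {"cell_id", "lon", "lat", "elev_m"}
    missing = required - set(lattice.columns)
    if missing:
        raise ValueError(f"lattice table missing columns {sorted(missing)}")
    cells = []
    for row in lattice.itertuples(index=False):
        series = weather_for_cell(row)
        annual = run_cell(series, sp, n0=n0, quiescence=quiescence)
        mean, sd, cv = summarize_years(annual)
        cells.append(
            CellSummary(
                cell_id=str(row.cell_id),
                lon=float(row.lon),
                lat=float(row.lat),
                elevation_m=float(row.elev_m),
                annual_pupae=annual,
                mean=mean,
                sd=sd,
                cv=cv,
            )
        )
        log.info("cell %s: mean annual pupae %.2f", row.cell_id, mean)
    return favorability_map(cells, elevation_cutoff)


# ---------------------------------------------------------------------------
# export


def export_table(cells: list[CellSummary], path) -> pd.DataFrame:
    """Write the per-cell summary as CSV and return the frame."""
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "lon": [c.lon for c in cells],
            "lat": [c.lat for c in cells],
            "elev_m": [c.elevation_m for c in cells],
            "mean_pupae": [c.mean for c in cells],
            "sd_pupae": [c.sd for c in cells],
            "cv_pupae": [c.cv for c in cells],
            "fi": [c.fi for c in cells],
            "masked": [c.masked for c in cells],
            "above_boundary": [
                (not c.masked) and c.fi > FI_BOUNDARY for c in cells
            ],
        }
    )
    df.to_csv(path, index=False)
    return df


_NODATA = -9999.0


def _lattice_axes(cells: list[CellSummary]):
    lons = np.array(sorted({round(c.lon, 9) for c in cells}))
    lats = np.array(sorted({round(c.lat, 9) for c in cells}))
    if len(lons) * len(lats) != len(cells):
        raise ValueError(
            "cells do not form a regular lattice; use export_table instead"
        )
    for axis in (lons, lats):
        if len(axis) > 1:
            steps = np.diff(axis)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "irregular cell spacing; use export_table instead"
                )
    if len(lons) > 1 and len(lats) > 1:
        if not np.isclose(lons[1] - lons[0], lats[1] - lats[0]):
            raise ValueError("ESRI ASCII grids require square cells")
    return lons, lats


def export_ascii_grid(cells: list[CellSummary], path, value: str = "fi") -> None:
    """Write one value per cell as an ESRI ASCII grid (regular lattices only).

    Masked cells and NaNs become the nodata value. Round-trips exactly
    through :func:`read_ascii_grid`.
    """
    lons, lats = _lattice_axes(cells)
    size = lons[1] - lons[0] if len(lons) > 1 else (
        lats[1] - lats[0] if len(lats) > 1 else 1.0
    )
    grid = np.full((len(lats), len(lons)), _NODATA)
    li = {v: i for i, v in enumerate(lons)}
    la = {v: i for i, v in enumerate(lats)}
    for c in cells:
        v = getattr(c, "mean" if value == "mean_pupae" else value)
        if c.masked or not np.isfinite(v):
            continue
        grid[la[round(c.lat, 9)], li[round(c.lon, 9)]] = v
    with open(path, "w") as fh:
        fh.write(f"ncols {len(lons)}\n")
        fh.write(f"nrows {len(lats)}\n")
        fh.write(f"xllcorner {lons[0] - size / 2:.10g}\n")
        fh.write(f"yllcorner {lats[0] - size / 2:.10g}\n")
        fh.write(f"cellsize {size:.10g}\n")
        fh.write(f"NODATA_value {_NODATA:.10g}\n")
        for row in grid[::-1]:  # north row first
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array with NaN nodata, header dict)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    grid = np.array(rows)
    nodata = header.get("nodata_value", _NODATA)
    grid[grid == nodata] = np.nan
    return grid, header


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
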