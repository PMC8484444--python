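"""Daily weather series: CSV ingestion, RH reconstruction, synthetic regimes.

The file dialect is a comma-separated table with a header naming
``date`` (ISO), ``tmax``, ``tmin`` and optionally ``rh``; one cell per
file. When RH is absent it is reconstructed from temperatures assuming the
daily minimum approximates the dew point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "read_weather",
    "rh_from_temps",
    "synth_weather",
    "PROFILES",
]


@dataclass(frozen=True)
class DailyWeather:
    date: pd.Timestamp
    tmax: float
    tmin: float
    tmean: float
    rh: float


class WeatherSeries:
    """Contiguous ordered daily weather for one cell.

    Wraps a DataFrame with columns date, tmax, tmin, tmean, rh; dates are
    strictly increasing with no gaps.
    """

    def __init__(self, frame: pd.DataFrame, cell_id: str = "cell",
                 provenance: str = "unknown"):
        required = {"date", "tmax", "tmin", "tmean", "rh"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"weather frame missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self.cell_id = cell_id
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield DailyWeather(
                date=row.date, tmax=row.tmax, tmin=row.tmin,
                tmean=row.tmean, rh=row.rh,
            )

    @property
    def years(self) -> np.ndarray:
        return self.frame["date"].dt.year.to_numpy()

    def to_csv(self, path) -> None:
        out = self.frame[["date", "tmax", "tmin", "rh"]].copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def rh_from_temps(tmean: float, tmin: float) -> float:
    """Reconstruct %RH from mean and minimum temperature.

    Uses saturated vapor pressure at Tmean and ambient vapor pressure at
    Tmin (dew-point approximation); clamped to [0, 100].
    """
    if tmin > tmean:
        raise ValueError(f"tmin ({tmin}) exceeds tmean ({tmean})")
    es = 610.78 * math.exp(17.269 * tmean / (237.3 + tmean))
    em = 610.78 * math.exp(17.269 * tmin / (237.3 + tmin))
    return min(100.0, max(0.0, 100.0 * em / es))


def _validate_dates(dates: pd.Series, path) -> None:
    diffs = dates.diff().dropna()
    bad = diffs[diffs <= pd.Timedelta(0)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"{path}: dates not strictly increasing at row {row + 1} "
            f"({dates.iloc[row].date()})"
        )
    gaps = diffs[diffs > pd.Timedelta(days=1)]
    if len(gaps):
        row = gaps.index[0]
        missing = dates.iloc[row - 1] + pd.Timedelta(days=1)
        raise ValueError(f"{path}: gap in series, missing {missing.date()}")


def read_weather(path, cell_id: str | None = None) -> WeatherSeries:
    """Read a daily weather CSV (date,tmax,tmin[,rh]) into a WeatherSeries."""
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("date", "tmax", "tmin"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable date ({exc})") from exc
    _validate_dates(df["date"], path)

    bad = df.index[df["tmin"] > df["tmax"]]
    if len(bad):
        raise ValueError(f"{path}: tmin > tmax at row {bad[0] + 1}")
    df["tmean"] = (df["tmax"] + df["tmin"]) / 2.0
    if "rh" not in df.columns:
        df["rh"] = [
            rh_from_temps(tm, tn) for tm, tn in zip(df["tmean"], df["tmin"])
        ]
        provenance = f"file:{path.name}:rh-reconstructed"
    else:
        df["rh"] = df["rh"].clip(0.0, 100.0)
        provenance = f"file:{path.name}"
    return WeatherSeries(
        df[["date", "tmax", "tmin", "tmean", "rh"]],
        cell_id=cell_id or path.stem,
        provenance=provenance,
    )


# seasonal regime defaults: annual mean/amplitude of Tmean, diurnal range,
# RH mean/amplitude, noise SDs; desert RH runs anti-phased with temperature
PROFILES = {
    "tropical": dict(mean=26.0, amplitude=3.0, diurnal_range=8.0,
                     rh_mean=80.0, rh_amplitude=10.0, rh_antiphase=False,
                     sigma=1.5, rh_sigma=5.0),
    "temperate": dict(mean=12.0, amplitude=10.0, diurnal_range=10.0,
                      rh_mean=70.0, rh_amplitude=15.0, rh_antiphase=False,
                      sigma=2.0, rh_sigma=5.0),
    "desert": dict(mean=25.0, amplitude=10.0, diurnal_range=14.0,
                   rh_mean=25.0, rh_amplitude=10.0, rh_antiphase=True,
                   sigma=2.0, rh_sigma=5.0),
}

# summer peak at day-of-year ~196 for the sinusoid
_PHASE_DAY = 196 - 365.25 / 4


def synth_weather(
    profile: str = "tropical",
    years: int = 3,
    seed: int = 0,
    start_year: int = 2000,
    cell_id: str | None = None,
    **overrides,
) -> WeatherSeries:
    """Generate a seeded synthetic daily weather series.

    Tmean follows a sinusoidal annual cycle with Gaussian daily noise;
    Tmax/Tmin sit half the diurnal range above/below. RH follows its own
    seasonal cycle (anti-phased for the desert profile), clamped to
    [0, 100]. Fully reproducible for a given (profile, years, seed).

    Parameter overrides (``mean``, ``amplitude``, ``sigma``, ...) may be
    passed as keyword arguments; ``profile="custom"`` starts from the
    tropical defaults.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    base = PROFILES.get("tropical" if profile == "custom" else profile)
    if base is None:
        raise KeyError(
            f"unknown profile {profile!r}; available: "
            f"{', '.join(sorted(PROFILES))} or 'custom'"
        )
    cfg = {**base, **overrides}
    unknown = set(cfg) - set(base)
    if unknown:
        raise TypeError(f"unknown profile overrides {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    season = np.sin(2.0 * np.pi * (doy - _PHASE_DAY) / 365.0)
    tmean = cfg["mean"] + cfg["amplitude"] * season
    tmean = tmean + rng.normal(0.0, cfg["sigma"], len(dates))
    half = cfg["diurnal_range"] / 2.0
    rh_season = -season if cfg["rh_antiphase"] else season
    rh = cfg["rh_mean"] + cfg["rh_amplitude"] * rh_season
    rh = rh + rng.normal(0.0, cfg["rh_sigma"], len(dates))
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax": tmean + half,
            "tmin": tmean - half,
            "tmean": tmean,
            "rh": np.clip(rh, 0.0, 100.0),
        }
    )
    return WeatherSeries(
        df,
        cell_id=cell_id or f"synthetic-{profile}",
        provenance=f"synthetic:{profile}:{seed}",
    )
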