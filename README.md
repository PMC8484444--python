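# tephrisim

Weather-driven, age-structured population simulator for four tropical
tephritid fruit flies — Mediterranean fruit fly (`medfly`), melon fly
(`melon_fly`), oriental fruit fly (`oriental_fly`) and Mexican fruit fly
(`mexfly`) — with regional favorability mapping and marginal-effects
regression for post-hoc analysis.

Each life stage (egg-larva, pupa, adult) is a distributed-maturation-time
chain of k age classes: stage transit is Erlang distributed with mean Δ
degree-days and SD Δ/√k. Daily temperature drives development (degree-day
increments with a nonlinear high-temperature fall-off) and stage mortality;
temperature and relative humidity scale oviposition, and realized egg lay
follows a ratio-dependent demand-driven functional response against a
constant host level. Multi-year, multi-cell runs aggregate annual cumulative
new pupae into a normalized favorability index (FI), masking cells above
2000 m elevation and omitting the first (burn-in) year.

## Layout

| module | contents |
|---|---|
| `tephrisim.species_params` | parameter registry (YAML per species), developmental rate/increment, oviposition scalars φT/φRH, mortality, fecundity profile, survival↔daily-rate arithmetic |
| `tephrisim.population_dynamics` | stage chains, daily step, Erlang statistics, population initialization |
| `tephrisim.reproduction` | oviposition demand and the saturating functional response |
| `tephrisim.weather` | weather CSV ingestion, RH reconstruction from temperatures, seeded synthetic regimes (tropical / temperate / desert / custom) |
| `tephrisim.regional` | per-cell multi-year runs, year summaries, favorability map, CSV / ESRI ASCII grid export |
| `tephrisim.analysis_stats` | OLS with pairwise interactions, marginal effects at covariate means, thermal-stress covariate helpers |

## CLI

```sh
# generate a seeded synthetic weather file (date,tmax,tmin,rh)
tephrisim synth-weather --profile tropical --years 3 --seed 42 --out wx.csv

# run one cell and dump the daily trace
tephrisim simulate --species medfly --weather wx.csv --out trace.csv

# run a lattice (CSV: cell_id,lon,lat,elev_m,weather_path) and map FI
tephrisim map --species medfly --lattice lattice.csv \
    --out-table cells.csv --out-grid fi.asc
```

Real weather files are comma-separated with a header naming `date` (ISO),
`tmax`, `tmin` and optionally `rh`; when `rh` is absent it is reconstructed
from the temperatures assuming the daily minimum approximates the dew point.

## Python API sketch

```python
import tephrisim as ts

sp = ts.load_species("medfly")
wx = ts.synth_weather("tropical", years=5, seed=1)
annual = ts.run_cell(wx, sp, n0=10)          # {year: cumulative new pupae}
mean, sd, cv = ts.summarize_years(annual)    # first year omitted
```

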