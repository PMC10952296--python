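# spac — a soil–plant–atmosphere continuum simulator

`spac` simulates hourly water and carbon exchange of a vegetated land surface
and is built to answer one question: **how much does the representation of
plant hydraulics matter for simulated drought responses?** It implements five
variants of the same big-leaf model that differ only in how plant water
stress is represented:

| variant    | plant water potentials | storage (capacitance) | irreversible xylem damage |
|------------|-----------------------|-----------------------|---------------------------|
| `baseline` | not resolved          | –                     | –                         |
| `H`        | steady-state          | –                     | –                         |
| `HC`       | dynamic               | yes                   | –                         |
| `H-d`      | steady-state          | –                     | yes                       |
| `HC-d`     | dynamic               | yes                   | yes                       |

It is aimed at ecohydrologists and land-surface modellers who want a small,
transparent test bed for plant-hydraulics formulations, with synthetic
dry-down experiments built in.

## The model in brief

Water flows from soil (potential ψ<sub>s</sub>, MPa) through a stem-xylem
node (ψ<sub>x</sub>) to a leaf node (ψ<sub>l</sub>) along conductances that
lose capacity under tension through exponential-sigmoid vulnerability
curves, k(ψ) = k<sub>max</sub> exp(−q|ψ|<sup>p</sup>). The steady variant
solves the two-node flux balance

&nbsp;&nbsp;k̄<sub>s→x</sub>(ψ<sub>s</sub>−ψ<sub>x</sub>) =
k̄<sub>x→l</sub>(ψ<sub>x</sub>−ψ<sub>l</sub>) = T(ψ<sub>s</sub>, ψ<sub>l</sub>, M)

each hour (k̄ are geometric means of the node conductances, M the
meteorological forcing). The capacitance variant instead integrates storage
ODEs, dV<sub>x</sub>/dt = J<sub>s→x</sub> − J<sub>x→l</sub> and
dV<sub>l</sub>/dt = J<sub>x→l</sub> − T, with linear pressure–volume curves
ψ = c(1 − V/V<sub>max</sub>), so stored water buffers the diurnal demand
cycle and refills at night. Transpiration demand comes from a Farquhar C3 /
stomatal-conductance coupling: the empirical baseline uses the Leuning model
with a soil-stress factor f<sub>s</sub> = exp(−q|ψ<sub>s</sub>|<sup>p</sup>),
while the hydraulic variants use a Tuzet-style model whose down-regulation
factor

&nbsp;&nbsp;f<sub>l</sub> = exp(−a<sub>l</sub>|ψ<sub>s</sub>−ψ<sub>l</sub>|<sup>γ<sub>l</sub></sup>)

is calibrated in closed form so that a 1.0 MPa soil-to-leaf potential drop
halves stomatal conductance and a 0.2 MPa drop cuts it by 10%. The damage
variants track an age-structured cohort distribution of conducting tissue in
which each cohort keeps the minimum potential it has ever experienced —
embolised conduits never refill, and conductivity only returns through
tissue turnover (oldest cohorts die first, new tissue is born undamaged).

## Worked example

Run a 40-day synthetic dry-down for the steady-hydraulics and storage
variants and compare their stress responses:

```python
from spac.experiments import ExperimentConfig, run_e1, metric_decline_time, metric_wue

cfg = ExperimentConfig(scenario="e1a", n_days=40, variants=("baseline", "H", "HC"))
results = run_e1(cfg)
for variant, res in results.items():
    daily = res.daily
    print(variant,
          "decline t90->t50 [d]:", round(metric_decline_time(daily["gpp"].to_numpy()), 2),
          "| pre-drought WUE:", round(metric_wue(daily["gpp"][:10], daily["T_mm"][:10]), 3))
```

prints

```
baseline decline t90->t50 [d]: 7.63 | pre-drought WUE: 1.311
H decline t90->t50 [d]: 10.26 | pre-drought WUE: 1.587
HC decline t90->t50 [d]: 13.45 | pre-drought WUE: 1.581
```

Read this as: on the same repeated warm-and-sunny percentile day with no
rain, the empirical baseline collapses from 90% to 50% of its initial gross
primary productivity in ~7.6 days, while the hydraulic variants decline more
gradually (extra xylem/leaf resistance closes stomata earlier, saving soil
water). The storage variant transpires stored water in the morning hours
without a proportional carbon gain, so its water-use efficiency
(GPP per unit transpiration, here μmol CO₂ m⁻² s⁻¹ per mm day⁻¹) is lower
than the steady variant's — and it consequently reaches soil-water stress a
few days earlier.

The same experiments are available from the shell:

```bash
spac e1 --seed 0 --out out_e1          # 250-day dry-down, three variants
spac e2 --seed 0 --out out_e2          # dry-down to fs=0.2 + relief, HC vs HC-d
spac run --forcing my_site.csv --variant HC --out out_site
spac metrics --daily out_e1/H_daily.csv
```

Each run writes per-variant hourly and daily CSV series plus a
`metrics.json` block; a YAML config (see `spac.config`) overrides any trait,
soil, gas-exchange or experiment parameter.

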