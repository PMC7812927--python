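# soilweb

A daily simulator of soil carbon, the soil food web, pore-size structure and
the soil water balance — with Bayesian calibration of the food web's growth
rates and a posterior-ensemble scenario runner.

Most soil carbon models reduce decomposition to first-order decay of "fast"
and "slow" pools.  `soilweb` instead couples three things that field soil
science says belong together: **who eats whom** (a nine-guild food web from
bacteria to predators), **where the carbon physically sits** (five pore-size
classes that determine which organisms can reach it, and how wet or aerated
each class is), and **who restructures the soil** (fungal aggregation and
earthworm-type ecosystem engineers, whose burrows feed back on infiltration
and water storage).  It is written for soil and ecosystem modellers who want
to explore trophic cascades, soil-structure feedbacks and hydrology in one
consistent carbon budget, at the cost of a single soil layer and a daily
time step.

## The model in brief

Twelve carbon pools B (g C m⁻³): nine biotic guilds plus litter, SOM and
DOM.  Each guild grows by Monod kinetics over its accessible substrates and
loses carbon to respiration, turnover and predation:

    dB/dt = Σₙ g_max·m_tot·(Sₙ·f_aₙ)/(K_sₙ + Sₙ)·B  −  r·f_T·B  −  d·B  −  P_d

* `f_a` — the fraction of substrate S the consumer can physically reach,
  from the pore-size distribution and per-class moisture (activity sits at
  the wetting front; water-logged and bone-dry classes contribute nothing).
* `m_tot` — the product of moisture, temperature (Q10 with a plateau above
  the optimum), pH, substrate C:N and substrate recalcitrance modifiers.
* Respiration shares the Q10 curve but has no plateau, so warming past the
  optimum turns growth negative.
* Consumption exceeds growth by egestion (faeces → SOM); predation costs the
  prey G·(1 + f_faec).
* Porosity is dynamic: PV_tot = PV_text + PV_Ag + f_PV·PV_B, with
  aggregation porosity built by fungal+mycorrhizal biomass and burrow volume
  dug by engineers (ten-year mean burrow lifespan).
* Water follows a daily spilling bucket with preferential macropore bypass;
  stored water fills pore classes smallest-first.
* DOM is produced from respiration and exudation, adsorbs as a function of
  pH and clay, and leaches with drainage.

The nine `g_max` parameters are calibrated by Metropolis–Hastings with
reflection against pool-stability observations (each pool observed once a
year, Gaussian errors); scenario ensembles propagate the last 100 accepted
parameter vectors.

## Worked example

A ten-year run of the packaged sandy pine-forest site under synthetic
climate:

```python
import soilweb as sw

cfg = sw.brasschaat_config()                    # acidic sandy topsoil fixture
climate = sw.synthetic_climate(3653, seed=1)    # 10 y of daily weather
res = sw.run(cfg, climate, 3653)

print(f"mean soil water content: {res.mean_swc():.1f} l m^-3")
print(f"cumulative respiration:  {res.final_pools.co2_cum:.0f} g C m^-3")
print(f"DOM leached:             {res.final_pools.dom_leached_cum:.1f} g C m^-3")
```

prints

```
mean soil water content: 173.2 l m^-3
cumulative respiration:  21118 g C m^-3
DOM leached:             11.3 g C m^-3
```

i.e. the 0.9 m layer holds on average 173 l of water per m³ of soil (field
capacity is ~228 l m⁻³; summers dry it down), the soil respires ~21 kg C m⁻³
over the decade (litter and root inputs resupply ~17 kg, the rest is mined
from the large initial litter/SOM stocks), and ~11 g C m⁻³ leaves as
dissolved organic carbon.  The carbon balance closes to ~4×10⁻¹⁴ relative —
every gram is accounted for across pools, CO₂, leaching, bioturbation and
inputs.  At the default (mid-prior) growth rates this acidic, recalcitrant-
litter soil is strongly fungal-dominated (decade-mean fungi ≈ 1277 vs
bacteria ≈ 2 g C m⁻³); calibration and the predator-exclusion scenario
reshape that balance.

Command-line equivalents:

```bash
soilweb simulate --config brasschaat --climate synthetic --seed 1 --out trace.csv
soilweb calibrate --iterations 20000 --seed 1 --out chain.csv
soilweb scenarios --sample posterior_sample.csv --out-dir scenario_out
soilweb report --scenario-dir scenario_out --out report.json
```

## Configuration and data files

Everything is plain text: the site configuration is YAML
(`src/soilweb/data/brasschaat.yaml` documents every key and unit — soil
texture, initial pools, litter quality, external inputs, structural and
leaching constants), guild biology and the diet matrix are CSV tables, and
outputs (daily traces, MCMC chains, scenario summaries) are CSV with
headers.  Climate files need `date`, `precipitation_mm` and either `et_mm`
or `temperature_c` (a Hamon-type PET fallback is derived from temperature
and flagged).

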