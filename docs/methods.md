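# Methods

`soilweb` simulates the coupled dynamics of soil carbon, a nine-guild soil
food web, pore-size structure and the soil water balance of a single soil
layer at a daily time step, and calibrates the guilds' maximum growth rates
by Markov-chain Monte Carlo against pool-stability observations.  This note
documents the model equations as implemented, the parameters that matter and
their defaults, the numerical choices, and what the packaged synthetic data
can and cannot show.

## State and units

Twelve dynamic carbon pools, all in g C per m^3 of soil: bacteria, fungi,
mycorrhiza, bacterivores, fungivores, detritivores, ecosystem engineers
(earthworm-type fauna), herbivores, predators, surface litter, soil organic
matter (SOM) and dissolved organic matter (DOM).  Roots and above-ground
litter production are boundary inputs; respired CO2, leached DOM and
bioturbation exports accumulate in diagnostic counters so that

    total = sum(pools) + CO2_cum + DOM_leached_cum + bioturb_export_cum - inputs_cum

is exactly conserved (the test suite requires relative drift < 1e-6 per
simulated year; in practice it is at float round-off, ~1e-14).

Pore volumes and water are in litres per m^3 of soil.  Precipitation and
evapotranspiration arrive in mm day^-1; 1 mm over 1 m^2 is 1 l, so dividing
by the layer thickness (m) converts between the two unit systems.

## Pore structure

Five pore-size classes: inaccessible (< 0.1 um), bacterial (0.1–2 um),
micro (2–30 um), meso (30 um–1.5 mm), macro (> 1.5 mm).  Total porosity
decomposes into a constant textural part, an aggregation part and the
engineer burrow (biopore) volume:

    PV_tot = PV_text + PV_Ag + f_PV * PV_B

* Particle density D_s mixes mineral (2.65 g cm^-3) and organic
  (1.35 g cm^-3) densities harmonically by SOM mass fraction; total porosity
  is (D_s - D_b)/D_s.
* Aggregation: the aggregated SOM fraction is Ag = min(1, 10*(B_fungi +
  B_myc)/B_SOM); the extra porosity is k*Ag*B_SOM with k = 2 l gC^-1,
  capped at 20 l m^-3 (2 % of the soil volume) and split equally between the
  micro and bacterial classes.  Aggregation also converts half of the
  affected textural mesoporosity into micro/bacterial porosity (Ag/2 of the
  textural meso volume leaves, Ag/4 arrives in each of the two finer
  classes).  The quantitative aggregation-to-pore-class mapping is a
  hypothesis; all coefficients are configurable.
* Burrows: PV_B = max(min(PV_Bmax, VE_ratio*B_eng), (PV_macro -
  PV_textmacro)*(1 - tPV_B)), i.e. engineers dig in proportion to their
  biomass (VE_ratio, default 0.05 l per g C; PV_Bmax 50 l m^-3) and
  abandoned burrows decay geometrically at tPV_B = 1/3650 day^-1 (a ten-year
  mean lifespan).  A fraction f_PV (default 0.5) of the burrow volume adds
  to total porosity; the rest displaces mesopores.  Because the class
  volumes are recomputed from PV_B daily, collapsing burrows return to
  mesoporosity through the identities themselves; no separate bookkeeping is
  needed.
* The class equations are evaluated, then clamped at zero; a clamp is logged
  as a warning and recorded on the state, and the total identity is asserted
  only for unclamped states.

## Water balance

A daily spilling bucket with macropore bypass:

* Net precipitation P_net = P - E.  Runoff occurs only above the combined
  macropore and matrix infiltration capacities; the macropore capacity is
  the macropore volume (as mm) plus the subsoil's matrix capacity.
* The matrix fill is min(remaining pore space, I_maxMat*(1 - SA_macro),
  P_net*(1 - SA_macro)); SA_macro, the macropore surface-area fraction, is
  the macropore volume fraction (vertical-cylinder assumption).  Everything
  else bypasses through macropores.  Drainage is computed by exact mass
  balance — bypass plus the matrix spill above field capacity — rather than
  by the printed bucket formula, which double-counts part of P_net in some
  regimes; the literal formula is retained behind a `literal=True` flag for
  comparison.
* Field capacity is the water content with macropores and (by default)
  mesopores empty.  Negative P_net extracts water from storage down to the
  wilting point, taken as the water held in inaccessible pores.
* Stored water fills classes smallest-first (matric-potential ordering), so
  at most one class is partially filled.  I_maxMat defaults to
  60*exp(-6*fClay) mm day^-1 when not measured — ~50 for sand, ~24 at 15 %
  clay — and the textural class volumes come from a small pedotransfer
  table in which the fine-pore share of porosity grows linearly with clay.

## Growth, consumption and losses

Growth of guild B over its substrates n follows Monod kinetics:

    G = sum_n g_max_eff * (S_n * f_a_n / (K_s_n + S_n)) * B

* Accessibility f_a: a pore-resident substrate (SOM, prey, roots) is
  distributed over its home classes in proportion to pore volume; the
  consumer reaches the intersection of those classes with its own size-
  admissible classes, each weighted by the per-class moisture modifier.
  Surface litter, outside the matrix, uses the microbial-habitat moisture
  modifier (pore-volume-weighted over the bacterial and larger classes).
* Moisture: the overall modifier is 4x(1-x) for saturation x < 0.5 and 1
  above (continuous at 0.5).  Activity sits at the wetting front: the
  partially filled class receives the aerated share, the class one size
  above receives the complementary share, saturated classes below and dry
  classes further above receive 0.  The weighting of the class above is as
  printed (water-filled share); an aerated-share alternative sits behind a
  flag.
* Temperature: a Q10 curve (Q default 2) from T_min (default 0 C) to T_opt,
  with a plateau from T_opt to T_max for growth.  Respiration uses the same
  curve without the plateau, so warming beyond the optimum raises
  respiration while growth saturates — the crossover produces net biomass
  loss.
* pH: bacteria lose an order of magnitude of g_max per pH unit below 3,
  fungi per unit above 8 (mycorrhiza follow the fungal rule).  Engineer
  g_max ramps linearly from 0 at pH 3 to its full value at pH 5.
* Substrate quality (litter/SOM links only): the C:N modifier is
  min(1, (CN_consumer/CN_substrate)^p_mCN); the recalcitrance modifier is
  linear, min(1, 1 - p_mRec*Rec), so a fully recalcitrant substrate is
  inert only at p_mRec = 1.
* Modifiers multiply (an optional most-limiting mode takes their minimum).
  Moisture enters exactly once: through f_a for pore-resident substrates and
  through the litter moisture modifier for surface litter.

Losses: respiration R = r * Q10-factor * B; turnover D_t = d * B routed to
SOM.  Consumption exceeds growth by egestion: on litter/SOM links,
consumption = G/(1 - f_faecEff) with f_faecEff = f_faec*(1 +
m_faec*(CN_sub - CN_consumer)/CN_sub) clamped to [0, 0.95] (the form is
singular at 1; the clamp never binds with the shipped table).  On live-prey
and root links the prey loses G*(1 + f_faec).  Microbes egest nothing
(f_faec = 0); microbivores and other fauna do.  Faeces carry the substrate's
quality into SOM; turnover carries the guild's C:N with zero recalcitrance;
pool C:N mixes on a nitrogen-mass basis (harmonic in C:N) and recalcitrance
by carbon mass.

DOM is produced as f_DOM (default 0.02) of each day's total respiration plus
root exudation, partitions between dissolved and adsorbed states via
K_D = a - b*pH + c*fClay (Orchidee-SOM coefficients 0.001226, 0.000212,
0.00374), leaches with the draining water at its dissolved concentration,
and re-stabilizes into SOM at 0.05 day^-1 (a short-half-life assumption
keeping the pool from accumulating without bound).

Bioturbation exports litter and SOM at configurable rates per unit engineer
biomass (defaults 0.01 and 0.05 g C g C^-1 day^-1), capped at the available
pool.  With a single layer these exports leave the system and are tracked.

## Food-web topology and parameter table

The diet matrix is an editable CSV: bacteria and fungi consume litter and
SOM; bacterivores consume bacteria; fungivores consume fungi and mycorrhiza;
detritivores and engineers consume litter and SOM (engineers through every
pore class except the inaccessible one); herbivores graze a fixed root
boundary pool (replenished to its configured value daily, mirroring
constant-input runs); predators consume the five faunal guilds.  Mycorrhiza
receive a fixed daily plant-carbon allocation instead of a Monod substrate
(an optional SOM-uptake link can be added through the diet table).

K_s defaults follow the "existing concentration" rule for fauna: each link's
half-saturation equals the initial density of its substrate.  For microbes,
whose g_max priors are laboratory-scale, K_s is inflated — 5x the initial
substrate density for bacteria and 2x for fungi.  The asymmetry encodes
hyphal foraging: fungal mycelia exploit sparse, recalcitrant substrate far
better than dispersal-limited bacteria, which keeps an acidic, recalcitrant-
litter pine-forest soil fungal-competitive, as observed in such systems.
Guild respiration and death rates are literature-scale choices (microbes
~1 %/day of biomass for each; fauna ~1 %/day respiration with lifespans of
months to years for the larger guilds); all sit in `data/guilds.csv`.

## Daily calculation order and integration

Per day: (a) pore-size distribution from yesterday's biology, (b) water
balance and allocation, (c) DOM leaching with today's drainage, (d)
accessibility, (e) growth modifiers, (f) the twelve pool derivatives, (g) a
forward-Euler update at dt = 1 day, (h) litter/SOM quality update, (i)
engineer effects (burrow volume, bioturbation), (j) an optional structural
hook (default none).  Litter temperature equals soil temperature.

The Euler step uses a carbon-conserving flux limiter: every flux has a
unique source pool, and if a pool's outgoing fluxes exceed its content the
whole outgoing set is scaled by available/required.  Pools therefore never
go negative and the balance closes in every regime; a pool driven to zero
stays at zero until an external inflow reseeds it (growth is multiplicative
in biomass, so extinction is absorbing — by design, e.g. predator-exclusion
runs).

Two code paths produce the same numbers: a readable `daily_step` that
composes the module operations, and a numba-compiled whole-run kernel used
for calibration and ensembles (~4 us per day after one-time compilation).
The test suite asserts their agreement to a relative tolerance of 1e-9 over
multi-month runs (observed agreement is ~1e-15).

## Calibration

The nine g_max values are calibrated by a Metropolis–Hastings random walk
with reflection at the uniform prior bounds (`data/gmax_priors.csv`).  The
likelihood is independent Gaussian around pool-stability observations
(`data/calibration_obs.csv`): each of the 11 pools is observed at day
180 + 365k with errors of 20 % (fauna), 10 % (predators) and 12.5 %
(litter/SOM) of the observed value — nine years of a ten-year run give 99
data points.  The Gaussian form is this package's choice; the source data
state values and error margins but no density.

Numerical settings: the proposal is a diagonal Gaussian with standard
deviation 5 % of each prior range by default; the posterior concentrates on
a thin, correlated ridge, so the shipped calibration runs use 1.5–2.5 % and
more iterations instead of adaptation (adaptive MCMC is out of scope).  The
walk starts from the best of an initial prior screen (default 500 draws), a
burn-in accelerator that leaves the kernel untouched; if too few proposals
have been accepted after the 50 % burn-in, the chain is extended from its
last state.  The working posterior sample is the last 100 accepted vectors
after burn-in, taken literally (no thinning).  Chains are bit-reproducible
given the seed.

## Scenarios and summaries

Six scenarios: basal, litter recalcitrance 0.20, litter C:N 40, pH 5.9,
predator exclusion (initial predator biomass 0), and clay 15 % (textural
pore volumes and I_maxMat regenerated through the pedotransfer helpers).
Each scenario runs once per posterior vector (the basal sample is reused;
no re-calibration) for ten years at a daily step.  Summaries: time-and-
ensemble pool means, ensemble-wide min/max, cumulative respiration by
microbial guild, litter/SOM turnover attributed to bacteria and engineers
(consumption, plus bioturbation export for engineers), mean soil water
content, and the fungi:bacteria ratio computed as a ratio of means.

Directional expectations checked by the test suite at calibrated growth
rates: higher clay raises mean soil water content; predator exclusion
raises microbivore biomass and lowers the fungi:bacteria ratio (the
trophic cascade); higher pH raises engineer biomass.

## Synthetic climate

The packaged generator produces a temperate-maritime climate: a sinusoidal
annual temperature cycle (mean 10.5 C, amplitude 7.5 C, Gaussian daily noise
of 2 C) peaking in late July, Bernoulli–exponential rainfall (wet-day
probability 0.45, expected annual total 850 mm), and Hamon-type potential
evapotranspiration from the generated temperature and daylength at 51.3 N.
It reproduces the seasonal forcing that drives the model's moisture and
temperature modifiers but has no interannual trends, drought spells with
realistic persistence, or rain-intensity extremes; passing tests on it show
the model's internal consistency and qualitative behavior, not predictive
skill for any real site.  Measured daily climate can be supplied as CSV
(date, precipitation_mm, and et_mm or temperature_c; PET is derived from
temperature when absent, flagged in the series metadata).

## Problem sizes used in checks

The shipped verification runs use a two-year likelihood window with 6,000 to
20,000 MCMC iterations and 100-member, ten-year scenario ensembles; the
synthetic-truth recovery experiment uses one-year forward runs and 20,000
iterations.  These sizes give stable results for the quantities checked
(signs, closures, recovery within two posterior standard deviations) while
keeping a full verification run in the minutes range on a single core.

## Known limitations

* One soil layer; the water routing contract is written per-layer but
  multi-layer profiles, Richards-equation matrix flow and snow are not
  implemented.
* Nitrogen appears only through C:N bookkeeping; no explicit N pools.
* Guilds are aggregates; no population structure or life stages.
* The herbivore root pool is a constant boundary condition, so sustained
  herbivore booms import carbon (tracked in the balance, but ecologically a
  simplification).
* The aggregation-porosity and burrow coefficients are hypotheses with wide
  uncertainty; they are exposed in the configuration rather than fixed.
* The posterior is multi-modal and strongly correlated; the fixed-scale
  random walk mixes slowly (acceptance of a few percent), which the package
  addresses with iterations rather than adaptive proposals.
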