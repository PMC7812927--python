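# Sandy, acidic Scots-pine forest topsoil (Campine region, Belgium).
# Pools in g C m^-3, rates per day unless the key says otherwise.
site:
  name: brasschaat
  latitude: 51.3
soil:
  pct_sand: 93
  pct_clay: 3
  pct_som: 2.0
  bulk_density: 1.4      # g cm^-3
  ph: 3.5
  layer_thickness: 0.9   # m
structure:
  f_pv: 0.5              # share of biopore volume that adds to macroporosity
  pv_bmax: 50.0          # l m^-3
  ve_ratio: 0.05         # l per g C engineer
  burrow_lifespan_days: 3650
  k_ag: 2.0              # l per g C (aggregation porosity)
  c_ag: 10.0
  pv_ag_cap: 20.0        # l m^-3 (max 2% extra porosity)
pools:
  bacteria: 15.1
  fungi: 15.1
  mycorrhiza: 160.0
  bacterivores: 0.1
  fungivores: 0.8
  detritivores: 0.6
  engineers: 0.2
  herbivores: 0.2
  predators: 0.4
  litter: 2680.0
  som: 11470.0
  dom: 5.0
quality:
  cn_litter: 55.0
  rec_litter: 0.45
  cn_som: 30.0
  rec_som: 0.6
  cn_litterfall: 55.0
  rec_litterfall: 0.45
  cn_rootlitter: 50.0
  rec_rootlitter: 0.4
inputs:
  litter_fall_annual: 400.0     # g C m^-3 yr^-1
  root_litter_annual: 740.0     # g C m^-3 yr^-1
  myc_allocation_annual: 197.0  # g C m^-3 yr^-1
  exudation_daily: 0.1          # g C m^-3 day^-1
  root_biomass: 400.0           # g C m^-3 boundary pool
hydrology:
  i_max_mat: null               # mm day^-1; derived from clay when null
  i_max_mat_subsoil: 50.0       # mm day^-1
  fc_includes_meso: false
  initial_water: field_capacity
leaching:
  f_dom: 0.02
  dom_return_rate: 0.05
  a_kd: 0.001226
  b_kd: 0.000212
  c_kd: 0.00374
bioturbation:
  litter_rate: 0.01   # g C litter per g C engineer per day
  som_rate: 0.05      # g C SOM per g C engineer per day
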