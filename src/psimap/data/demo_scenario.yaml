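# Packaged demo scenario: one small synthetic country, three susceptibility
# components (two bounded proportions, one count/median), modest survey and
# mesh sizes so the full pipeline runs in about a minute.
country_id: SYN
seed: 42

simulate:
  n_provinces: 3
  districts_per_province: 4
  extent_km: [150.0, 150.0]
  cell_km: 1.5
  n_clusters: 220
  households_per_cluster: 25
  mask_jitter_m: 2000.0
  shdi_noise_sd: 0.02
  components:
    - name: owns_car
      direction: HSLS
      table: households
      response_type: proportion
      beta0: -0.8
      betas: {ACCESS: 0.9}
      matern_range_km: 30.0
      matern_sd: 0.5
    - name: chronic_sickness
      direction: HSHS
      table: roster
      response_type: proportion
      beta0: -1.2
      betas: {ACCESS: -0.6, LST: 0.7}
      matern_range_km: 30.0
      matern_sd: 0.5
    - name: household_size
      direction: HSHS
      table: households
      response_type: median_count
      beta0: 0.2
      betas: {POPPP: 0.6, ACCESS: -0.4}
      matern_range_km: 30.0
      matern_sd: 0.4

mesh:
  cutoff_km: 6.0
  max_edge_km: [18.0, 50.0]

model:
  candidates: [ACCESS, LST, POPPP, DMROADS]
  forward_selection: false
  aggregation_factor: 2
  n_draws: 200

prepare:
  correlation_threshold: 0.7

scoring:
  jenks_k: 5
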