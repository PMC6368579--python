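scenario:
  n_regions: 15
  start_year: 2000
  end_year: 2010
  break_year: 2008
  pop_size: 2000000.0
  pop_growth: 0.003
  seasonal_amplitude: 0.15
  temp_mean: 10.0
  temp_amplitude: 8.0
  temp_sd: 2.0
  temp_ar1: 0.7
  g_exp: null
  g_rec: null
  m_exp: -0.022
  beta: 1.0
  gdp_start: null
  temp_coupling: 0.0
  temp_optimum: 18.0
  seed: 1
data_dir: null
out_dir: out/demo
n_bins: 20
lag_scheme: window
windows: default
subperiods:
  P1: [2000, 2003]
  P2: [2004, 2007]
  P3: [2008, 2010]
percentile_subset: [10, 25, 40, 60, 75, 90]
n_sims: 1000
run_mc: true
seed: 1
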