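# Self-contained demo: simulates the synthetic registry (2001-2023),
# extracts the elective cohort, fits all six models on 2001-2019,
# forecasts to 2050 and runs the full validation protocol.
# Run:  tha-forecast run --config configs/demo.yaml
out_dir: results/demo
records_csv: null
population_csv: null
start_year: 2001
end_year: 2023
horizon_end: 2050
cutoff_year: 2019
reference_year: 2019
models: [LM, PM, LogM, IP, PLN, HPTE]
n_sims: 10000
seed: 20250101
initial_window: 10
rolling_horizon: 1
rolling_step: 1
rolling_models: null
hpte: {}
sim:
  n_distractor_per_year: 500
  fracture_fraction: 0.1
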