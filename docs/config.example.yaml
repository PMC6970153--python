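# Full run configuration for `matchingpennies run-all --config <this file>`.
# Every field is optional; omitted sections fall back to the defaults below.

schedule:
  n_runs: 4
  blocks_per_run: 3          # must equal the number of opponent types
  trials_per_block: 12
  counterbalance_seed: 0

payoff:                      # JPY; loser of each trial receives 0
  p_win_high: 60.0           # participant's payoff on a HIGH match
  p_win_low: 20.0            # ... on a LOW match
  o_win_after_p_high: 40.0   # opponent's payoff on a mismatch after participant HIGH
  o_win_after_p_low: 20.0    # ... after participant LOW

cohort:
  n_participants: 30
  alpha_mean: {HUM: 0.34, FIX: 0.34, LRN: 0.40}
  alpha_sd:   {HUM: 0.15, FIX: 0.15, LRN: 0.15}
  beta_mean: 5.0
  beta_sd: 1.5
  hum_proxy_alpha: 0.26      # learning rate of the simulated human opponent
  hum_proxy_beta: 5.0
  master_seed: 0

betas:                       # synthetic ROI pattern generator
  n_voxels: 200
  lambda_shared: 1.0         # loading of the HUM/LRN-shared component (0 = null)
  sigma_choice: 0.5
  sigma_noise: 1.0
  seed: 1

fit:
  n_starts: 10
  seed: 0
  beta_max: 50.0
  tol: 1.0e-6
  v_init: 0.5

seed: 0
ppc_reps: 200
output_dir: pipeline_output
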