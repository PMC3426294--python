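# Obesity epidemic model for adults (24-65) classified by body-mass index:
# normal weight N, overweight S, obese O (population proportions, weeks).
# Transmission parameters are Uniform(0, 2*theta_hat) so each mean equals the
# survey point estimate; mu and the age-group inflow proportions are fixed.
model:
  builtin: obesity
  variant: reduced

parameters:
  beta: {dist: uniform_about, mean: 0.00085}     # social-pressure transmission
  gamma: {dist: uniform_about, mean: 0.0003}     # overweight -> obese
  epsilon: {dist: uniform_about, mean: 0.000004} # obese -> overweight
  rho: {dist: uniform_about, mean: 0.000035}     # overweight -> normal weight
  mu: 0.000469                                   # demographic turnover
  N0: 0.704                                      # inflow proportions (sum to 1)
  S0: 0.25
  O0: 0.046

chaos:
  order: 2

time:
  t_end: 800
  stride: 4
  extra_times: [520, 572, 780]   # years 2010, 2011, 2015

analyses: [deterministic, chaos, sobol]

mc:
  n_samples: 50000
  seed: 20120815

output_dir: epichaos_out
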