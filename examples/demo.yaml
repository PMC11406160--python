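# Demo scenario: three synthetic ant colonies vs 100 plants, 20-30 C sweep.
# All synthetic defaults are invented placeholders; override to taste.
synthetic:
  seed: 42
  n_consumers: 3
  n_resources: 100
  consumer_mass_median: 10.0      # mg
  consumer_mass_sigma: 0.3        # log-scale sd
  allometry_prefactor: 10.0       # mN * mg^(-exponent)
  allometry_exponent: 0.6666666666666666
  cutting_force_median: 40.0      # mN
  cutting_force_sigma: 0.6        # log-scale sd
  alpha: 0.98                     # body-mass factor per +1 C
  reference_temperature: 20.0     # C

rule:
  alpha: 0.98
  reference_temperature: 20.0

t_grid: "20:30:0.5"               # inclusive of both endpoints

robustness:
  strategy: random
  n_replicates: 200
  seed: 0

output_dir: thermoweb_out
graphml: false
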