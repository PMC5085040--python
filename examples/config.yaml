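# Example pipeline configuration: a three-scheme synthetic study with a
# quadratic temperature law on the closed-complex formation rate k1.
seed: 7
n_starts: 5
gof_rounds: 500
structure: {n_steps: 1, switching: true}
stages: [moments, select, fit_temperature, shared_shape, gof]

simulate:
  n_cells: 400
  movie_length: 7200      # s
  sampling_interval: 60   # s
  temperatures: [24, 30, 35, 41]   # deg C
  schemes:
    Full:
      # inverse rates in seconds: k_x(T)^-1 = A*T^2 + B*T + C
      k1:    {order: 2, coefficients: [3.4974, -227.06, 5227.0]}
      k_on:  {order: 0, coefficients: [0, 0, 200.0]}
      k_off: {order: 0, coefficients: [0, 0, 200.0]}
    IPTG:
      k1:    {order: 2, coefficients: [5.2461, -340.59, 7840.5]}
      k_on:  {order: 0, coefficients: [0, 0, 300.0]}
      k_off: {order: 0, coefficients: [0, 0, 200.0]}
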