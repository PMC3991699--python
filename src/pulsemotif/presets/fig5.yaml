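name: fig5
description: b-model duration-compensated flat frequency response (A0=1, d0=10, T0=100).
output_dir: results/fig5
grid: {f_min: 0.001, f_max: 0.1, n: 21}
runs:
  - label: b_duration_comp_hill
    model: {name: b}
    rate_function: "hill2:K=1"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: duration_compensated
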