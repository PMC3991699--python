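name: fig6
description: ab-model duration-compensated bell response for sigmoidal F (A0=3, d0=10, f0=0.01), with on-phase means of the filtered input and example trajectories.
output_dir: results/fig6
grid: {f_min: 0.001, f_max: 0.1, n: 25}
runs:
  - label: ab_duration_comp
    model: {name: ab, params: {tau_a: 10}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
    trajectory_frequencies: [0.002, 0.01, 0.05]
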