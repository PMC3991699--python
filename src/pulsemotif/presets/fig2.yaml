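name: fig2
description: Receptor-binding one-period trajectories for the reference signal (A0=1, d0=10, f0=0.01) and fourfold-frequency dose-conserved variants.
output_dir: results/fig2
grid: {f_min: 0.001, f_max: 0.1, n: 9}
runs:
  - label: receptor_amplitude_comp
    model: {name: receptor}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    trajectory_frequencies: [0.01, 0.04]
  - label: receptor_duration_comp
    model: {name: receptor}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: duration_compensated
    trajectory_frequencies: [0.01, 0.04]
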