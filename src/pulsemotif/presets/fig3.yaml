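name: fig3
description: Receptor (monotone increasing) and dimer (bell-shaped) frequency responses under both dose-conservation protocols; ref A0=1, d0=10, f0=0.01.
output_dir: results/fig3
grid: {f_min: 0.001, f_max: 0.1, n: 21}
runs:
  - label: receptor_amplitude_comp
    model: {name: receptor}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: receptor_duration_comp
    model: {name: receptor}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: dimer_amplitude_comp
    model: {name: dimer}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: dimer_duration_comp
    model: {name: dimer}
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: duration_compensated
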