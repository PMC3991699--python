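name: fig10
description: Goldbeter-Koshland phosphorylation cycle - dose tuning (A0 in {100, 350, 600}) and kinetic scaling (lambda in {0.2, 1, 5} at A0=350) under both protocols; d0=10, f0=0.01.
output_dir: results/fig10
grid: {f_min: 0.001, f_max: 0.1, n: 17}
runs:
  - label: amp_A0_100
    model: {name: gk}
    signal: {A0: 100, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: amp_A0_350
    model: {name: gk}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: amp_A0_600
    model: {name: gk}
    signal: {A0: 600, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: dur_A0_100
    model: {name: gk}
    signal: {A0: 100, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: dur_A0_350
    model: {name: gk}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: dur_A0_600
    model: {name: gk}
    signal: {A0: 600, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: amp_lambda_0p2
    model: {name: gk, params: {lambda: 0.2}}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: amp_lambda_5
    model: {name: gk, params: {lambda: 5}}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: dur_lambda_0p2
    model: {name: gk, params: {lambda: 0.2}}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: dur_lambda_5
    model: {name: gk, params: {lambda: 5}}
    signal: {A0: 350, d0: 10, f0: 0.01}
    protocol: duration_compensated
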