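name: fig7
description: ab-model frequency responses (A0=3, d0=10, f0=0.01) under both protocols for sublinear, superlinear, and sigmoidal production-rate functions.
output_dir: results/fig7
grid: {f_min: 0.001, f_max: 0.1, n: 25}
runs:
  - label: sublinear_amplitude_comp
    model: {name: ab}
    rate_function: "saturating:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: sublinear_duration_comp
    model: {name: ab}
    rate_function: "saturating:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: superlinear_amplitude_comp
    model: {name: ab}
    rate_function: "power:p=2"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: superlinear_duration_comp
    model: {name: ab}
    rate_function: "power:p=2"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
  - label: sigmoidal_amplitude_comp
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
  - label: sigmoidal_duration_comp
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
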