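name: fig4
description: Single-period pulse-shape scans (amplitude vs duration at fixed T0=100, dose conserved) of the b-model for saturating, superlinear, and sigmoidal production-rate functions.
output_dir: results/fig4
grid: {f_min: 0.001, f_max: 0.1, n: 30}
runs:
  - label: saturating_scan
    kind: pulse_shape
    model: {name: b}
    rate_function: "saturating:K=1"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: uncompensated
  - label: superlinear_scan
    kind: pulse_shape
    model: {name: b}
    rate_function: "power:p=2"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: uncompensated
  - label: sigmoidal_scan
    kind: pulse_shape
    model: {name: b}
    rate_function: "hill2:K=1"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: uncompensated
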