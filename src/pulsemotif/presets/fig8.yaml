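name: fig8
description: Input dose selects the ab-model response shape (hill2 K=1, d0=10, f0=0.01) - A0 in {1, 3, 10} under both protocols, with on-phase means.
output_dir: results/fig8
grid: {f_min: 0.001, f_max: 0.1, n: 25}
runs:
  - label: amp_A0_1
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: amp_A0_3
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: amp_A0_10
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 10, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: dur_A0_1
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 1, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
  - label: dur_A0_3
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
  - label: dur_A0_10
    model: {name: ab}
    rate_function: "hill2:K=1"
    signal: {A0: 10, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
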