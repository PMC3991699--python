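name: fig9
description: Kinetics set the peak frequency - ab-model (hill2 K=1, A0=3, d0=10, f0=0.01) with tau_a in {1, 10, 100} under both protocols.
output_dir: results/fig9
grid: {f_min: 0.001, f_max: 0.1, n: 25}
runs:
  - label: amp_tau_1
    model: {name: ab, params: {tau_a: 1}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: amp_tau_10
    model: {name: ab, params: {tau_a: 10}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: amp_tau_100
    model: {name: ab, params: {tau_a: 100}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: amplitude_compensated
    with_on_phase_means: true
  - label: dur_tau_1
    model: {name: ab, params: {tau_a: 1}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
  - label: dur_tau_10
    model: {name: ab, params: {tau_a: 10}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
  - label: dur_tau_100
    model: {name: ab, params: {tau_a: 100}}
    rate_function: "hill2:K=1"
    signal: {A0: 3, d0: 10, f0: 0.01}
    protocol: duration_compensated
    with_on_phase_means: true
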