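# pulsemotif

Many hormones — GnRH, corticosteroids, insulin — are secreted as rectangular
pulses, and target cells can respond very differently to the same total dose
depending on how it is packaged in time. `pulsemotif` is a Python library and
command-line tool for analyzing how simple **feedforward signaling motifs**
decode **dose-conserved pulsatile inputs**: pulse trains whose amplitude or
duration is varied along with frequency so that the mean dose A·d/T stays
fixed (*amplitude compensation*, A = A₀T/T₀ with d = d₀; *duration
compensation*, d = d₀T/T₀ with A = A₀).

It is aimed at systems biologists and modelers who want to predict — before
running a perfusion experiment — whether a pathway's mean output will rise,
fall, or peak at an optimal frequency when stimulated with dose-conserved
pulses.

## The models and the theory

Five forced ODE motifs are included, each driven by a pulse train γ(t):

| model | equations | output |
|---|---|---|
| single-stage (`b`) | τ_b·ḃ = −b + F(γ) | ⟨b⟩∞ |
| cascade (`ab`) | τ_a·ȧ = −a + γ, τ_b·ḃ = −b + F(a) | ⟨b⟩∞ |
| receptor | ṘL = k_on·γ·(1−RL) − k_off·RL | ⟨RL⟩∞ |
| dimer | receptor + 2 RL ⇌ D, R + RL + 2D = 1 | ⟨D⟩∞ |
| Goldbeter–Koshland | kinase/phosphatase modification cycle, input E₁T(t) | ⟨W*⟩∞/W_T |

Because these systems are feedforward and globally stable, a periodic input
drives them to a unique periodic solution; the package computes its period
mean (and on-phase mean) in closed form wherever the dynamics are linear in
the state, and by segment-wise stiff integration with transient discard
otherwise.

The central result it implements: for the single-stage model the slope of the
dose-conserved frequency response carries the sign of the **tangent-intercept
quantity**

    Δ(A) = [F(A) − A·F′(A)] − F(0),

the y-intercept of the tangent to F at A minus F(0). Concave (saturating) F
gives Δ > 0 and an increasing response, convex F gives Δ < 0 and a decreasing
one, and a sigmoidal F changes sign, producing a bell-shaped response whose
peak sits at the amplitude where Δ = 0 — for the Hill function A²/(A²+K²)
that is exactly A* = K. For motifs with kinetics (cascade, phosphorylation
cycle) the same selection acts through the filtered effective amplitude: the
bell peak sits at the frequency where the on-phase mean ⟨a⟩_on,∞ crosses K.

## Worked example

```python
import pulsemotif as pm

ref = pm.make_pulse_train(3, 10, 100)        # A0=3, d0=10, f0=0.01
model = pm.ABModel(F=pm.hill(K=1))           # cascade with sigmoidal F

curve = pm.sweep(model, "amplitude_compensated", ref, 1e-3, 1e-1, n=25)
print(curve.shape)                            # 'bell'
print(pm.refine_peak(model, "amplitude_compensated", ref, curve)[0])
# 0.011349374651890674
print(pm.predict_peak_frequency(model, "amplitude_compensated", ref))
# 0.011040179033387016
```

The swept response is bell-shaped and its refined peak frequency
(≈ 0.0113) agrees with the theoretical prediction — the frequency where the
on-phase mean of the filtered input crosses K (≈ 0.0110) — to within a grid
step: the optimal pulse pattern is the one whose effective amplitude matches
the nonlinearity's half-max constant.

The same computations are available from the shell; shipped presets
regenerate the data behind each response-curve figure as CSV + JSON:

```bash
pulsemotif list-presets
pulsemotif run fig8 -o results/fig8
pulsemotif sweep --model gk --protocol duration_compensated \
    --A0 350 --d0 10 --f0 0.01 -o results/gk350
```

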