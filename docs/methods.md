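# Methods

## Input signals and dose conservation

A pulse train is the T-periodic rectangular signal that equals A on [0, d) of
each period and 0 otherwise (amplitude A in input concentration units, pulse
duration d and period T in time units, 0 < d ≤ T). Its mean dose is A·d/T and
its duty cycle d/T. The pulse is placed at the start of the period; period
means are phase-invariant, so this is purely a convention (verified by an
integration test that runs the off phase first).

Two protocols map a reference train (A₀, d₀, T₀) to a new period T while
conserving the mean dose exactly:

* **amplitude compensation** — A = A₀·T/T₀, d = d₀. Because the fixed
  duration must fit in the period, frequencies above 1/d₀ are infeasible;
  grid points beyond the bound are dropped with a logged warning rather than
  clipped, so amplitude-compensated response curves are truncated at 1/d₀.
* **duration compensation** — d = d₀·T/T₀, A = A₀. The duty cycle is
  invariant and every frequency is admissible.

A third, `uncompensated`, mode (period change only; the dose then scales with
frequency) is provided for comparison. Frequency grids are log-spaced by
default because the response curves of interest span about two decades
(10⁻³–10⁻¹); linear spacing is available. Dose conservation holds to
floating-point round-off (tested at 1e-12 relative), not merely to a
tolerance, since both protocols are pure rescalings.

## Production-rate nonlinearities and Δ

A `RateFunction` packages F, its derivative and F(0). Built-in families —
linear cA, power A^p, saturating A/(A+K), Hill A^n/(A^n+K^n) with n = 2 by
default — carry closed-form derivatives; user-supplied functions without one
fall back to a central difference with step h = max(1e-6, 1e-6·A), which is
adequate (~1e-9 relative on smooth F) but documented as lower accuracy.

The tangent-intercept quantity

Δ(A) = [F(A) − A·F′(A)] − F(0)

is the y-intercept of the tangent line to F at A minus the basal rate.
For the single-stage model the slope of the dose-conserved response with
respect to amplitude at fixed period is −(A₀d₀)/(T·A²)·Δ(A), and with
respect to frequency under amplitude compensation it is d₀·Δ(A(f)); both
follow by differentiating the closed-form mean below. The peak of a
bell-shaped response therefore sits at the Δ root, which for Hill n = 2 is
A* = K exactly — notably *not* at the inflection point of F. Roots are
located by Brent's method on a user-supplied bracket to 1e-10 absolute in A
(Δ is cheap and smooth, so a tight tolerance costs nothing); a bracket
without a sign change raises a dedicated error, since for strictly concave or
convex F the absence of a root is the scientifically meaningful outcome.

## Motif models

All five models are single-branch feedforward systems; their common interface
is a state derivative under a constant input level, which lets the driver
integrate pulse-on and pulse-off segments separately so the integrator never
steps across the forcing discontinuity.

* **Single-stage (b-model)**: τ_b·ḃ = −b + F(γ). τ_b (default 1) only sets
  the relaxation time; the asymptotic period mean is τ_b-free.
* **Cascade (ab-model)**: a linear stage τ_a·ȧ = −a + γ (unit steady-state
  gain, default τ_a = 10) feeding τ_b·ḃ = −b + F(a). The first stage is a
  low-pass filter that converts pulse duration into effective amplitude,
  which is what makes duration-compensated inputs frequency-selective at all.
* **Receptor**: ṘL = k_on·γ·(1−RL) − k_off·RL with RL the bound fraction.
  The rates are generic (no particular receptor is modeled): k_on = 0.1,
  k_off = 0.01, chosen so binding during a reference pulse (k_on·A₀ = 0.1)
  outpaces the slow inter-pulse dissociation.
* **Dimer**: adds homodimerization of bound receptors with conservation
  R + RL + 2D = 1 (a dimer holds two receptors). Defaults k_on = 0.1,
  k_off = 0.05, k_dim_on = 0.3, k_dim_off = 0.1 place the tangent-intercept
  crossing of the (sigmoidal) steady-state D(L) curve inside the amplitude
  decade swept by the protocols, so the motif shows the bell-shaped response
  characteristic of sigmoidal input–output functions under both protocols.
  The monomeric receptor keeps its own defaults; both sets are fully
  configurable, and every test on these two motifs is property-based
  (monotonicity, conservation, sigmoidality, shape class), never tied to the
  specific rate values.
* **Goldbeter–Koshland cycle**: kinase E₁ and phosphatase E₂ interconvert a
  protein between W and W* through complexes C₁, C₂; three states (C₁, C₂,
  W*) plus conservation laws. The input is total active kinase E₁T(t); the
  output is the phosphorylated fraction W*/W_T. Parameters W_T = 1000 nM,
  E₂T = 50 nM, a₁ = a₂ = 50 nM⁻¹s⁻¹, d₁ = d₂ = 499 s⁻¹, k₁ = k₂ = 1 s⁻¹
  put the cycle deep in the zero-order regime (Michaelis constants 10 nM ≪
  W_T), giving an ultrasensitive steady-state sigmoid in E₁T. A dimensionless
  factor λ multiplies all six rate constants, rescaling kinetics without
  moving fixed points; trajectories satisfy the time-rescaling identity
  x_λ(t) = x₁(λt) with a correspondingly stretched input (tested).

  Off-phase kinase handling: when E₁T(t) falls below the complexed amount
  C₁, free kinase is clamped at zero and C₁ drains at rate d₁ + k₁. This
  avoids negative concentrations while keeping the mass-action terms
  well-defined. Whether the pulse offset should also deactivate
  receptor-bound kinase is not determined by the model's source; clamping
  only free kinase is the weaker assumption and is the one implemented.

  Two steady-state facts worth noting because they are easy to get wrong:
  with the symmetric parameter set at E₁T = E₂T the fixed point has W* = W,
  but W*/W_T ≈ 0.451 rather than 1/2, and at large E₁T the fraction
  saturates near 0.90 rather than 1 — in both cases because the complexes
  hold ≈ 2×50 nM of protein. The half-activation input (where the fraction
  crosses 1/2) is nevertheless within ~0.5% of E₂T = 50 nM, because the
  sigmoid is extremely steep there.

## Periodic steady states

Feedforward + global stability + periodic forcing ⇒ a unique attracting
T-periodic solution (verified operationally by the initial-condition
independence of the asymptotic period means, at 1e-6 relative). Two paths
compute it:

**Closed form.** For scalar stages linear in the state (receptor; the
cascade's a-variable), the one-period affine map x(T) = M·x(0) + c of the
piecewise-exponential flow is contracting (factor e^(−d/τ_on)·e^(−(T−d)/τ_off)),
and its fixed point yields the periodic solution, period mean, and on-phase
mean analytically. When both phases share τ, the period mean reduces exactly
to the input mean u_on·d/T + u_off·(T−d)/T, independent of τ. The
single-stage mean is the closed form ⟨b⟩∞ = [d·F(A) + (T−d)·F(0)]/T, and the
cascade mean is the period average of F(a(t)) over the closed-form a(t),
evaluated by adaptive quadrature with absolute tolerance 1e-6 per phase
(generously tighter in practice; the relative tolerance is set to 1e-10).

**Numeric.** Everything else is integrated period by period (LSODA,
rtol 1e-9; atol 1e-12 scaled by the model's state magnitude, i.e. 1e-9 nM
for the stiff phosphorylation cycle whose rates span five orders of
magnitude), with an auxiliary cumulative-integral state per model state
supplying the running period mean. The initial transient is discarded by
iterating until consecutive period means agree to 1e-8 relative (floored by
the absolute tolerance for identically-zero outputs). The period budget is
estimated from the contraction rate — about ln(1/tol) slowest-timescale
multiples — with a generous floor of 500 periods, because conservation
structure can hide modes slower than any single rate constant (the dimer
pool drains only through a small monomer fraction); the loop exits at
convergence, so headroom is free. Exceeding the budget raises an error
carrying the last two period means. Initial conditions default to the zero
state, justified by global stability.

## Response curves, classification, and peak prediction

A sweep maps each feasible grid frequency through the protocol, computes the
periodic mean output (closed form where available), and classifies the curve.
Classification tolerance is relative: a curve is *flat* when its total range
is below 1e-3 of its magnitude, successive differences within 1e-3 of the
range are ties, and a *bell* requires a single interior maximum exceeding
both endpoints; anything with multiple interior extrema beyond tolerance is
labeled `unclassifiable` rather than forced into a class. The 1e-3 figure
sits two to three orders of magnitude above the integrator noise in numeric
means (~1e-6–1e-5 relative) and three below the O(1) relative variation of
genuinely non-flat curves, so the calls are insensitive to its exact value.

Bell peaks found on the grid (log-spaced, ~15 points/decade by default) are
refined by bounded golden-section search on log-frequency between the argmax's
grid neighbours before being compared with theory; the raw grid resolution
would otherwise dominate the comparison. For the cascade the theoretical peak
is the frequency where ⟨a⟩_on,∞(f) = K, located by a dense scan for a sign
change followed by Brent refinement; the absence of a crossing is a valid
result and predicts a monotone response (increasing when the on-phase mean
stays above K, decreasing when below). The Δ-slope formulas apply exactly to
the single-stage model only; for the cascade and the phosphorylation cycle
the theory enters solely through the crossing rule.

## What the generator emulates, and what it does not

The pulse-train module is the study's synthetic-data generator: all inputs are
idealized rectangular, perfectly periodic, noise-free pulse trains at the
reference conditions A₀ ∈ {1, 3, 10, 100, 350, 600}, d₀ = 10, f₀ = 0.01 used
throughout. Real secretory patterns have jittered timing, non-rectangular
pulse shapes (and dispersion during transport low-pass filters them),
stochastic amplitudes, and receptor desensitization/feedback — none of which
are modeled. Passing tests therefore demonstrate the internal consistency of
the deterministic feedforward theory, not its robustness to biological noise;
the linear-F dose-invariance result is the only one that extends unchanged to
arbitrary pulse shapes.

## Numerical choices and known limitations

* Integration is segmented exactly at pulse edges; discontinuous forcing
  inside a step would degrade LSODA's step-size control.
* Degenerate inputs: d = T is treated as constant input (the off-segment is
  skipped); the amplitude-compensation boundary f = 1/d₀ is feasible with
  duty cycle exactly 1.
* The Δ-root bracket and the crossing scan assume a single sign change, which
  holds for all monotone built-in F (Δ is monotone-signed per concavity
  region); multi-modal F is out of scope.
* Problem sizes: response curves use 17–25 grid points over two decades and
  the oracle-equivalence checks use 20 frequencies, enough to resolve every
  shape class and peak comparison reported while keeping the full analysis in
  the minutes range on a single CPU.
* Ligand/kinase depletion by binding is neglected (the input is an imposed
  signal), and no feedback loops are modeled; both are deliberate scope
  limits of the feedforward analysis.
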