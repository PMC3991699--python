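"""Feedforward signaling motif models driven by a pulsatile input.

Five ODE models, all single-branch feedforward systems forced by a rectangular
pulse train γ(t):

* b-model       τ_b·db/dt = −b + F(γ)            — a single relaxation variable
                                                    produced at nonlinear rate F.
* ab-model      τ_a·da/dt = −a + γ,
                τ_b·db/dt = −b + F(a)            — a linear low-pass stage feeding
                                                    the nonlinearity; converts pulse
                                                    duration into effective amplitude.
* receptor      dRL/dt = k_on·γ·(1−RL) − k_off·RL — ligand–receptor binding, with RL
                                                    the bound fraction.
* dimer         receptor binding plus homodimerization of bound receptors,
                with conservation R + RL + 2D = 1.
* Goldbeter–Koshland phosphorylation cycle, input = total active kinase
                E1T(t); in the zero-order regime (W_T ≫ E2_T) the steady-state
                phosphorylated fraction is an ultrasensitive sigmoid of E1T
                with half-maximum set by E2_T.

Because the systems are feedforward and globally stable, a periodic input
drives each to a unique attracting periodic solution; the period mean of the
output is the quantity the frequency-response analysis works with.

Every model exposes ``rhs(y, u)`` (state derivative under the constant input
level ``u``), so the numeric driver can integrate pulse-on and pulse-off
segments exactly between the input discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .errors import ConvergenceError, InvalidStateError
from .rates import RateFunction, hill
from .signals import PulseTrain, evaluate_signal

__all__ = [
    "BModel",
    "ABModel",
    "ReceptorModel",
    "DimerModel",
    "GoldbeterKoshlandModel",
    "b_model_rhs",
    "ab_model_rhs",
    "receptor_rhs",
    "dimer_rhs",
    "gk_rhs",
    "gk_steady_state_curve",
    "MODEL_REGISTRY",
]

_BOUND_TOL = 1e-7  # slack on conservation bounds for integrator round-off


class MotifModel:
    """Common interface of the five motif models."""

    state_names: tuple = ()
    output: str = ""
    #: multiplies the raw output state in reported means (e.g. 1/W_T)
    output_scale: float = 1.0
    #: magnitude of a typical state value (sets integrator absolute tolerance)
    state_scale: float = 1.0
    stiff: bool = False

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def output_index(self) -> int:
        return self.state_names.index(self.output)

    def rhs(self, y, u):  # pragma: no cover - abstract
        raise NotImplementedError

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.n_states)

    def validate_state(self, y) -> None:
        """Raise :class:`InvalidStateError` if ``y`` violates the model's
        bounds/conservation laws (up to integrator slack)."""

    def slowest_timescale(self, train: PulseTrain | None = None) -> float:
        return 1.0

    def periodic_mean(self, train: PulseTrain, method: str = "auto", **kwargs) -> float:
        """Period mean of the output at periodic steady state (closed form
        where the dynamics allow, numerically otherwise)."""
        from . import periodic

        if method in ("auto", "closed") and self._closed_form_mean is not None:
            return self._closed_form_mean(train)
        if method == "closed":
            raise NotImplementedError(f"{type(self).__name__} has no closed-form mean")
        means = periodic.numeric_periodic_mean(self, train, **kwargs)
        return means[self.output] * self.output_scale

    _closed_form_mean = None


@dataclass
class BModel(MotifModel):
    """Single relaxation variable with nonlinear production rate F.

    τ_b only sets the approach time; the steady-state period mean
    [d·F(A) + (T−d)·F(0)]/T is independent of it.
    """

    F: RateFunction = field(default_factory=hill)
    tau_b: float = 1.0

    state_names = ("b",)
    output = "b"

    def __post_init__(self):
        if self.tau_b <= 0:
            raise ValueError(f"tau_b must be positive, got {self.tau_b}")

    def rhs(self, y, u):
        return np.array([(-y[0] + self.F(u)) / self.tau_b])

    def equilibrium(self, u: float) -> np.ndarray:
        return np.array([float(self.F(u))])

    def slowest_timescale(self, train=None) -> float:
        return self.tau_b

    def _closed_form_mean(self, train: PulseTrain) -> float:
        from .periodic import b_model_mean

        return b_model_mean(self.F, train)


@dataclass
class ABModel(MotifModel):
    """Linear low-pass stage a (unit steady-state gain, time constant τ_a)
    feeding the b-model nonlinearity."""

    F: RateFunction = field(default_factory=hill)
    tau_a: float = 10.0
    tau_b: float = 1.0

    state_names = ("a", "b")
    output = "b"

    def __post_init__(self):
        if self.tau_a <= 0 or self.tau_b <= 0:
            raise ValueError("tau_a and tau_b must be positive")

    def rhs(self, y, u):
        a, b = y
        return np.array([(-a + u) / self.tau_a, (-b + self.F(a)) / self.tau_b])

    def equilibrium(self, u: float) -> np.ndarray:
        return np.array([u, float(self.F(u))])

    def slowest_timescale(self, train=None) -> float:
        return max(self.tau_a, self.tau_b)

    def _closed_form_mean(self, train: PulseTrain) -> float:
        from .periodic import ab_model_mean

        return ab_model_mean(self, train)


@dataclass
class ReceptorModel(MotifModel):
    """Ligand–receptor binding: RL is the fraction of ligand-bound receptor.

    The rates are generic (no specific receptor system is modeled); defaults
    satisfy k_on·A0 > k_off so that binding during a pulse outpaces the slow
    dissociation between pulses.
    """

    k_on: float = 0.1
    k_off: float = 0.01

    state_names = ("RL",)
    output = "RL"

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be positive")

    def rhs(self, y, u):
        return np.array([self.k_on * u * (1.0 - y[0]) - self.k_off * y[0]])

    def equilibrium(self, u: float) -> np.ndarray:
        return np.array([self.k_on * u / (self.k_on * u + self.k_off)])

    def validate_state(self, y) -> None:
        if not (-_BOUND_TOL <= y[0] <= 1.0 + _BOUND_TOL):
            raise InvalidStateError(f"RL = {y[0]} outside [0, 1]")

    def slowest_timescale(self, train=None) -> float:
        return 1.0 / self.k_off

    def _closed_form_mean(self, train: PulseTrain) -> float:
        from .periodic import receptor_periodic_solution

        return receptor_periodic_solution(self, train).period_mean["RL"]


@dataclass
class DimerModel(MotifModel):
    """Receptor binding with homodimerization of bound receptors (output D).

    Total receptor is conserved as R + RL + 2D = 1 (a dimer holds two
    receptors).  The steady-state D as a function of constant ligand is
    sigmoidal, which turns the motif's dose-conserved frequency response
    bell-shaped.  The default rates are generic, chosen so that (i) binding
    during a reference pulse (A0 = 1) outpaces off-pulse dissociation and
    (ii) the sigmoid's tangent-intercept crossing falls inside the amplitude
    decade swept by the dose-conserved protocols, giving the bell under both.
    """

    k_on: float = 0.1
    k_off: float = 0.05
    k_dim_on: float = 0.3
    k_dim_off: float = 0.1

    state_names = ("RL", "D")
    output = "D"

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.k_dim_on, self.k_dim_off) <= 0:
            raise ValueError("all rate constants must be positive")

    def rhs(self, y, u):
        RL, D = y
        free = 1.0 - RL - 2.0 * D
        dim_on = self.k_dim_on * RL * RL
        dim_off = self.k_dim_off * D
        return np.array(
            [
                self.k_on * u * free - self.k_off * RL - 2.0 * dim_on + 2.0 * dim_off,
                dim_on - dim_off,
            ]
        )

    def validate_state(self, y) -> None:
        RL, D = y
        if RL < -_BOUND_TOL or D < -_BOUND_TOL or RL + 2.0 * D > 1.0 + _BOUND_TOL:
            raise InvalidStateError(
                f"(RL, D) = ({RL}, {D}) violates receptor conservation "
                "0 <= RL, D and RL + 2D <= 1"
            )

    def slowest_timescale(self, train=None) -> float:
        return max(1.0 / self.k_off, 1.0 / self.k_dim_off)

    def steady_state(self, u: float) -> np.ndarray:
        """Closed-form equilibrium under constant ligand level ``u``:
        D = (k_dim_on/k_dim_off)·RL² with RL solving the binding balance."""
        if u == 0.0:
            return np.zeros(2)
        kappa = self.k_dim_on / self.k_dim_off
        # 2*k_on*u*kappa*RL^2 + (k_on*u + k_off)*RL - k_on*u = 0
        a = 2.0 * self.k_on * u * kappa
        b = self.k_on * u + self.k_off
        c = -self.k_on * u
        RL = (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
        return np.array([RL, kappa * RL * RL])


@dataclass
class GoldbeterKoshlandModel(MotifModel):
    """Covalent-modification (phosphorylation) cycle of Goldbeter & Koshland.

    W ⇌ W* interconverted by kinase E1 and phosphatase E2 through complexes
    C1 = E1·W and C2 = E2·W*.  With total protein, kinase and phosphatase
    conserved, three ODE states (C1, C2, W*) suffice; W = W_T − W* − C1 − C2.
    The pulsatile input is the total active kinase E1T(t); when it drops below
    the amount already in complex, free kinase is clamped at zero and C1
    drains at rate d1 + k1.

    ``lam`` multiplies all six rate constants, rescaling the cycle's kinetics
    without moving its steady states.  Defaults put the cycle deep in the
    zero-order regime (W_T = 1000 nM ≫ E2_T = 50 nM, Michaelis constants
    (d+k)/a = 10 nM), so the steady-state phosphorylated fraction is a steep
    sigmoid of E1T with half-maximum near E2_T.  Rates span several orders of
    magnitude, so the numeric path uses a stiff-capable integrator.
    """

    W_T: float = 1000.0
    E2_T: float = 50.0
    a1: float = 50.0
    a2: float = 50.0
    d1: float = 499.0
    d2: float = 499.0
    k1: float = 1.0
    k2: float = 1.0
    lam: float = 1.0

    state_names = ("C1", "C2", "Wstar")
    output = "Wstar"
    stiff = True

    def __post_init__(self):
        vals = (self.W_T, self.E2_T, self.a1, self.a2, self.d1, self.d2,
                self.k1, self.k2, self.lam)
        if min(vals) <= 0:
            raise ValueError("all Goldbeter–Koshland parameters must be positive")
        self.output_scale = 1.0 / self.W_T
        self.state_scale = self.W_T

    def rhs(self, y, u):
        C1, C2, Wstar = y
        W = self.W_T - Wstar - C1 - C2
        E1_free = max(u - C1, 0.0)
        E2_free = self.E2_T - C2
        dC1 = self.a1 * W * E1_free - (self.d1 + self.k1) * C1
        dC2 = self.a2 * Wstar * E2_free - (self.d2 + self.k2) * C2
        dWstar = self.k1 * C1 - self.a2 * Wstar * E2_free + self.d2 * C2
        return self.lam * np.array([dC1, dC2, dWstar])

    def validate_state(self, y) -> None:
        C1, C2, Wstar = y
        tol = _BOUND_TOL * self.W_T
        if (min(C1, C2, Wstar) < -tol or C1 + C2 + Wstar > self.W_T + tol
                or C2 > self.E2_T + tol):
            raise InvalidStateError(
                f"(C1, C2, W*) = ({C1}, {C2}, {Wstar}) outside the conservation "
                f"polytope (W_T = {self.W_T}, E2_T = {self.E2_T})"
            )

    def slowest_timescale(self, train=None) -> float:
        # limiting net interconversion flux is ~ k*E2_T, moving up to W_T of protein
        return self.W_T / (self.lam * min(self.k1, self.k2) * self.E2_T)

    def steady_state(self, E1T: float, tol: float = 1e-10) -> np.ndarray:
        """Asymptotic state under constant kinase input (long integration to
        the attractor, polished by Newton on the RHS)."""
        if E1T == 0.0:
            return np.zeros(3)
        t_end = 50.0 * self.slowest_timescale()
        sol = solve_ivp(lambda t, y: self.rhs(y, E1T), (0.0, t_end),
                        self.initial_state(), method="LSODA",
                        rtol=1e-10, atol=1e-10 * self.W_T)
        if not sol.success:  # pragma: no cover
            raise ConvergenceError(f"steady-state integration failed: {sol.message}")
        y = fsolve(lambda s: self.rhs(s, E1T), sol.y[:, -1], xtol=tol)
        resid = np.abs(self.rhs(y, E1T)).max()
        if resid > 1e-6 * self.lam * self.W_T:  # pragma: no cover
            raise ConvergenceError(
                f"steady state at E1T={E1T} did not converge (|rhs| = {resid:g})"
            )
        self.validate_state(y)
        return y


def gk_steady_state_curve(params: GoldbeterKoshlandModel, E1T_values) -> np.ndarray:
    """Steady-state phosphorylated fraction W*/W_T for each constant kinase
    input in ``E1T_values`` (non-decreasing in E1T)."""
    return np.array(
        [params.steady_state(e)[2] / params.W_T for e in np.asarray(E1T_values, float)]
    )


def gk_half_activation_input(params: GoldbeterKoshlandModel,
                             bracket=(1.0, 600.0)) -> float:
    """Kinase input E1T at which the steady-state phosphorylated fraction
    crosses one half (near E2_T in the zero-order regime)."""
    return float(
        brentq(lambda e: params.steady_state(e)[2] / params.W_T - 0.5, *bracket,
               xtol=1e-6)
    )


# --- thin functional wrappers (signal-aware right-hand sides) ---------------

def b_model_rhs(b, t, train: PulseTrain, params: BModel):
    return params.rhs(np.atleast_1d(b), evaluate_signal(train, t))[0]


def ab_model_rhs(state, t, train: PulseTrain, params: ABModel):
    return params.rhs(np.asarray(state, float), evaluate_signal(train, t))


def receptor_rhs(RL, t, train: PulseTrain, params: ReceptorModel):
    return params.rhs(np.atleast_1d(RL), evaluate_signal(train, t))[0]


def dimer_rhs(state, t, train: PulseTrain, params: DimerModel):
    return params.rhs(np.asarray(state, float), evaluate_signal(train, t))


def gk_rhs(state, t, train: PulseTrain, params: GoldbeterKoshlandModel):
    return params.rhs(np.asarray(state, float), evaluate_signal(train, t))


MODEL_REGISTRY = {
    "b": BModel,
    "ab": ABModel,
    "receptor": ReceptorModel,
    "dimer": DimerModel,
    "gk": GoldbeterKoshlandModel,
    "goldbeter_koshland": GoldbeterKoshlandModel,
}
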