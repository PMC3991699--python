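"""Periodic steady states of pulse-forced motif models.

A globally stable feedforward system driven by a T-periodic input approaches a
unique T-periodic solution x(t).  The quantities of interest are its

* period mean     (1/T)·∫₀ᵀ x(t) dt, and
* on-phase mean   (1/d)·∫₀ᵈ x(t) dt   (mean over the pulse-on interval),

the latter being the effective amplitude the downstream nonlinearity sees.

For stages that are linear in the state (the receptor under rectangular
forcing, and the a-variable of the two-stage cascade) the periodic solution is
a piecewise exponential obtained in closed form by solving the one-period
affine map x(T) = M·x(0) + c for its unique fixed point.  Everything else is
integrated numerically, pulse-on and pulse-off segments in sequence, with an
auxiliary cumulative-integral state supplying the running period mean; the
initial transient is discarded by iterating periods until consecutive period
means agree to a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from .errors import ConvergenceError
from .rates import RateFunction
from .signals import PulseTrain

__all__ = [
    "PeriodicSolution",
    "linear_periodic_solve",
    "receptor_periodic_solution",
    "b_model_mean",
    "ab_model_mean",
    "on_phase_mean_a",
    "numeric_periodic_mean",
    "numeric_periodic_solution",
    "solution_to_frame",
]

#: absolute tolerance for adaptive quadrature of closed-form means
QUAD_TOL = 1e-6


@dataclass
class PeriodicSolution:
    """The asymptotic one-period solution of a pulse-forced model."""

    train: PulseTrain
    state_names: tuple
    period_mean: Mapping[str, float]
    on_phase_mean: Mapping[str, float]
    evaluator: Callable[[np.ndarray], np.ndarray]
    periods_to_converge: Optional[int] = None

    def __call__(self, t):
        """State at phase(s) ``t`` (T-periodic: t is wrapped into [0, T))."""
        return self.evaluator(np.mod(np.asarray(t, dtype=float), self.train.period))


def linear_periodic_solve(tau: float, u_on: float, u_off: float,
                          train: PulseTrain, tau_off: Optional[float] = None,
                          name: str = "x") -> PeriodicSolution:
    """Closed-form periodic solution of the scalar relaxation system
    τ·x′ = −x + u(t) with u = ``u_on`` during the pulse and ``u_off`` after it.

    ``tau_off`` allows a different relaxation time off-pulse (the receptor
    model maps onto this form with τ = 1/(k_on·A + k_off) on-pulse and
    τ = 1/k_off off-pulse).  The one-period affine map is a contraction
    (factor e^{−d/τ_on}·e^{−(T−d)/τ_off} < 1), so the fixed point always
    exists and is unique.

    When both phases share τ, the period mean is exactly the input mean
    u_on·d/T + u_off·(T−d)/T, independent of τ.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    tau_on = float(tau)
    tau_off = tau_on if tau_off is None else float(tau_off)
    d, T = train.duration, train.period
    off = T - d

    E1 = np.exp(-d / tau_on)
    E2 = np.exp(-off / tau_off)
    # fixed point of x(T) = E1*E2*x(0) + (affine terms)
    x0 = (u_off * (1.0 - E2) + u_on * E2 * (1.0 - E1)) / (1.0 - E1 * E2)
    xd = u_on + (x0 - u_on) * E1

    int_on = u_on * d + (x0 - u_on) * tau_on * (1.0 - E1)
    int_off = u_off * off + (xd - u_off) * tau_off * (1.0 - E2)
    period_mean = (int_on + int_off) / T
    on_phase_mean = int_on / d

    def evaluator(t):
        t = np.asarray(t, dtype=float)
        on = t < d
        x_on = u_on + (x0 - u_on) * np.exp(-t / tau_on)
        x_off = u_off + (xd - u_off) * np.exp(-np.clip(t - d, 0.0, None) / tau_off)
        out = np.where(on, x_on, x_off)
        return out if out.ndim else float(out)

    return PeriodicSolution(
        train=train,
        state_names=(name,),
        period_mean={name: float(period_mean)},
        on_phase_mean={name: float(on_phase_mean)},
        evaluator=evaluator,
    )


def receptor_periodic_solution(model, train: PulseTrain) -> PeriodicSolution:
    """Closed-form periodic solution RL(t) of the receptor model: binding at
    rate k_on·A + k_off toward k_on·A/(k_on·A + k_off) during the pulse,
    exponential dissociation at rate k_off toward zero between pulses."""
    A = train.amplitude
    rate_on = model.k_on * A + model.k_off
    return linear_periodic_solve(
        tau=1.0 / rate_on,
        u_on=model.k_on * A / rate_on,
        u_off=0.0,
        train=train,
        tau_off=1.0 / model.k_off,
        name="RL",
    )


def b_model_mean(F: RateFunction, train: PulseTrain) -> float:
    """Asymptotic period mean of the single-stage model,
    ⟨b⟩∞ = [d·F(A) + (T−d)·F(0)]/T (independent of τ_b).

    Obtained by time-averaging the ODE over one period at steady state: the
    production term spends a fraction d/T of the period at F(A) and the rest
    at F(0)."""
    d, T = train.duration, train.period
    return (d * float(F(train.amplitude)) + (T - d) * F.at_zero) / T


def a_periodic_solution(params, train: PulseTrain) -> PeriodicSolution:
    """Closed-form periodic solution of the linear first stage a(t)
    (unit gain, time constant τ_a)."""
    return linear_periodic_solve(params.tau_a, train.amplitude, 0.0, train, name="a")


def on_phase_mean_a(params, train: PulseTrain) -> float:
    """⟨a⟩_on,∞ — mean of the first-stage variable over the pulse-on interval
    at periodic steady state; the effective amplitude seen by F."""
    return a_periodic_solution(params, train).on_phase_mean["a"]


def ab_model_mean(params, train: PulseTrain, quad_tol: float = QUAD_TOL) -> float:
    """Period mean of the cascade output, ⟨b⟩∞ = (1/T)·∫₀ᵀ F(a(t)) dt with
    a(t) the closed-form periodic first-stage solution (time-averaging the b
    equation over one period makes ⟨b⟩ equal the period mean of F(a)).
    The integral is evaluated by adaptive quadrature on each pulse phase."""
    sol = a_periodic_solution(params, train)
    F = params.F
    d, T = train.duration, train.period

    def integrand(t):
        return float(F(sol.evaluator(t)))

    total, _ = quad(integrand, 0.0, d, epsabs=quad_tol, epsrel=1e-10, limit=200)
    if T > d:
        part, _ = quad(integrand, d, T, epsabs=quad_tol, epsrel=1e-10, limit=200)
        total += part
    return total / T


# --------------------------------------------------------------------------
# numeric path
# --------------------------------------------------------------------------

def _default_max_periods(model, train: PulseTrain, tol: float) -> int:
    # the transient contracts by ~e^{-T/tau} per period, so reaching a
    # relative tolerance tol from an O(1) start needs about ln(1/tol)
    # slowest-timescale multiples; pad for the O(1) prefactor
    # the estimate can be off when slow modes hide behind conservation
    # (e.g. a dimer pool draining through a small monomer fraction), so a
    # generous floor protects correctness; the loop exits at convergence,
    # so unused headroom costs nothing
    tau = model.slowest_timescale(train)
    multiples = np.log(1.0 / tol) + 5.0
    return max(int(np.ceil(multiples * max(tau, train.period) / train.period)) + 10,
               500)

def _segments(train: PulseTrain, on_first: bool):
    d, T = train.duration, train.period
    segs = [(d, train.amplitude), (T - d, 0.0)]
    if not on_first:
        segs.reverse()
    return [(length, level) for length, level in segs if length > 0.0]


def _integrate_periods(model, train, tol, max_periods, initial_state, on_first,
                       rtol, atol):
    """Iterate one-period integrations (with cumulative-integral auxiliaries)
    until consecutive period means of every state agree to ``tol`` relative.

    Returns (state at period start on the attractor, per-state means of the
    last period, number of periods integrated)."""
    n = model.n_states
    scale = getattr(model, "state_scale", 1.0)
    rtol = 1e-9 if rtol is None else rtol
    atol = 1e-12 * scale if atol is None else atol
    method = "LSODA"
    if max_periods is None:
        max_periods = _default_max_periods(model, train, tol)

    y = np.array(model.initial_state() if initial_state is None
                 else initial_state, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"initial state must have shape ({n},)")
    model.validate_state(y)

    segs = _segments(train, on_first)
    T = train.period
    floor = max(atol, 1e-300)
    prev_means = None
    means = None

    for k in range(1, max_periods + 1):
        z = np.concatenate([y, np.zeros(n)])
        for seg_len, level in segs:
            def fun(t, z, _u=level):
                dy = model.rhs(z[:n], _u)
                return np.concatenate([dy, z[:n]])

            sol = solve_ivp(fun, (0.0, seg_len), z, method=method,
                            rtol=rtol, atol=atol)
            if not sol.success:  # pragma: no cover
                raise ConvergenceError(
                    f"integration failed in period {k}: {sol.message}"
                )
            z = sol.y[:, -1]
        y = z[:n]
        model.validate_state(y)
        means = z[n:] / T
        if prev_means is not None:
            diff = np.abs(means - prev_means)
            ref = np.maximum(np.abs(means), floor)
            if np.all(diff <= tol * ref):
                return y, means, k
        prev_means = means

    raise ConvergenceError(
        f"period means did not converge to relative tolerance {tol:g} within "
        f"{max_periods} periods (last two: {prev_means}, {means})",
        last_means=(prev_means, means),
    )


def numeric_periodic_mean(model, train: PulseTrain, outputs=None,
                          tol: float = 1e-8, max_periods: Optional[int] = None,
                          initial_state=None, on_first: bool = True,
                          rtol: Optional[float] = None,
                          atol: Optional[float] = None) -> dict:
    """Period means of the model states at periodic steady state, by direct
    integration with transient discard.

    Integration proceeds pulse-segment by pulse-segment (the forcing is
    discontinuous only at segment boundaries, so the integrator never steps
    across a jump), accumulating ∫x dt in auxiliary states.  Convergence is
    declared when consecutive period means differ by less than ``tol``
    relative; exceeding ``max_periods`` (default 10·ceil(max(τ_slowest, T)/T))
    raises :class:`ConvergenceError` carrying the last two period means.

    Returns a dict mapping state name to mean (restricted to ``outputs`` if
    given).  Means are raw state averages; any output normalization (e.g.
    division by total protein) is left to the caller.
    """
    _, means, _ = _integrate_periods(model, train, tol, max_periods,
                                     initial_state, on_first, rtol, atol)
    result = dict(zip(model.state_names, means))
    if outputs is not None:
        result = {k: result[k] for k in outputs}
    return result


def numeric_periodic_solution(model, train: PulseTrain, tol: float = 1e-8,
                              max_periods: Optional[int] = None,
                              initial_state=None,
                              rtol: Optional[float] = None,
                              atol: Optional[float] = None) -> PeriodicSolution:
    """Like :func:`numeric_periodic_mean`, but returns the full
    :class:`PeriodicSolution` with a dense one-period evaluator and both
    period and on-phase means for every state."""
    n = model.n_states
    scale = getattr(model, "state_scale", 1.0)
    _rtol = 1e-9 if rtol is None else rtol
    _atol = 1e-12 * scale if atol is None else atol
    y0, _, k = _integrate_periods(model, train, tol, max_periods,
                                  initial_state, True, rtol, atol)

    d, T = train.duration, train.period
    dense = []
    z = np.concatenate([y0, np.zeros(n)])
    for t0, t1, level in ((0.0, d, train.amplitude), (d, T, 0.0)):
        if t1 <= t0:
            continue

        def fun(t, z, _u=level):
            return np.concatenate([model.rhs(z[:n], _u), z[:n]])

        sol = solve_ivp(fun, (t0, t1), z, method="LSODA", rtol=_rtol, atol=_atol,
                        dense_output=True)
        if not sol.success:  # pragma: no cover
            raise ConvergenceError(f"dense one-period integration failed: {sol.message}")
        dense.append((t0, t1, sol.sol))
        z = sol.y[:, -1]
        if t1 == d:
            int_on = z[n:].copy()
    int_period = z[n:]
    period_mean = dict(zip(model.state_names, int_period / T))
    on_phase_mean = dict(zip(model.state_names, int_on / d))

    def _at(ti: float):
        for _, t1, interp in dense:
            if ti <= t1:
                return interp(ti)[:n]
        return dense[-1][2](ti)[:n]

    def evaluator(t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return _at(float(t))
        return np.stack([_at(float(ti)) for ti in t], axis=-1)

    return PeriodicSolution(
        train=train,
        state_names=model.state_names,
        period_mean=period_mean,
        on_phase_mean=on_phase_mean,
        evaluator=evaluator,
        periods_to_converge=k,
    )


def solution_to_frame(sol: PeriodicSolution, n_points: int = 201) -> pd.DataFrame:
    """Dense one-period time series of a periodic solution as a DataFrame
    (column ``t`` plus one column per state), for figure regeneration."""
    t = np.linspace(0.0, sol.train.period, n_points, endpoint=False)
    values = np.atleast_2d(np.stack([np.atleast_1d(sol(ti)) for ti in t], axis=-1))
    data = {"t": t}
    for i, name in enumerate(sol.state_names):
        data[name] = values[i]
    return pd.DataFrame(data)
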