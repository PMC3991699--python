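"""Production-rate nonlinearities and the tangent-intercept quantity Δ.

The static nonlinearity F maps an input level to a production rate.  Its
concavity decides how a fixed input dose is best packaged into pulses: for the
single-variable relaxation model driven by a dose-conserved pulse train, the
slope of the mean response with respect to pulse amplitude is proportional to

    Δ(A) = [F(A) - A·F'(A)] - F(0),

the y-intercept of the tangent line to F at A, minus F(0).  Δ > 0 for strictly
concave F with F(0) = 0 (saturating kinetics: smaller, longer pulses win),
Δ < 0 for convex F (brief, large pulses win), and a sigmoidal F changes sign,
giving a bell-shaped frequency response whose peak sits at the amplitude where
Δ = 0 — for the Hill function A²/(A²+K²) that amplitude is exactly K (and is
not the inflection point of F).
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalDomainError, RootNotBracketedError

__all__ = [
    "RateFunction",
    "linear",
    "power",
    "saturating",
    "hill",
    "delta",
    "find_delta_root",
    "classify_shape_from_delta",
    "rate_function_from_spec",
    "BUILTIN_RATE_FUNCTIONS",
]

_FD_STEP = 1e-6  # relative step for the fallback central difference


class RateFunction:
    """A production-rate nonlinearity F with value and derivative.

    Built-in family members carry closed-form derivatives; a user-supplied
    function without one falls back to a central finite difference with step
    h = max(1e-6, 1e-6·A), which is lower accuracy (~1e-9 relative for smooth
    F) than the closed forms.
    """

    def __init__(self, func: Callable[[float], float],
                 deriv: Optional[Callable[[float], float]] = None,
                 label: str = "F", K: Optional[float] = None,
                 params: Optional[dict] = None):
        self._func = func
        self._deriv = deriv
        self.label = label
        self.K = K
        self.params = dict(params or {})

    def __call__(self, a):
        return self._func(np.asarray(a, dtype=float)) if np.ndim(a) else self._func(float(a))

    def derivative(self, a: float) -> float:
        if self._deriv is not None:
            out = self._deriv(float(a))
        else:
            h = max(_FD_STEP, _FD_STEP * abs(a))
            out = (self._func(a + h) - self._func(a - h)) / (2.0 * h)
        if not np.isfinite(out):
            raise NumericalDomainError(
                f"derivative of {self.label} at A={a} is not finite ({out})"
            )
        return float(out)

    @property
    def at_zero(self) -> float:
        """F(0), the basal production rate."""
        return float(self._func(0.0))

    def __repr__(self):
        return f"RateFunction({self.label})"


def linear(c: float = 1.0) -> RateFunction:
    """F(A) = c·A."""
    return RateFunction(lambda a: c * a, lambda a: c, label=f"linear(c={c:g})",
                        params={"c": c})


def power(p: float = 2.0) -> RateFunction:
    """F(A) = A**p (superlinear/convex for p > 1)."""
    return RateFunction(lambda a: a ** p, lambda a: p * a ** (p - 1.0),
                        label=f"power(p={p:g})", params={"p": p})


def saturating(K: float = 1.0) -> RateFunction:
    """Michaelis–Menten-type F(A) = A/(A+K): sublinear, strictly concave."""
    return RateFunction(lambda a: a / (a + K), lambda a: K / (a + K) ** 2,
                        label=f"saturating(K={K:g})", K=K, params={"K": K})


def hill(K: float = 1.0, n: float = 2.0) -> RateFunction:
    """Sigmoidal Hill function F(A) = A^n/(A^n + K^n) (default n = 2)."""

    def f(a):
        an = a ** n
        return an / (an + K ** n)

    def df(a):
        an, kn = a ** n, K ** n
        return n * a ** (n - 1.0) * kn / (an + kn) ** 2

    return RateFunction(f, df, label=f"hill{n:g}(K={K:g})", K=K,
                        params={"K": K, "n": n})


def delta(F: RateFunction, A: float) -> float:
    """Tangent-intercept quantity Δ(A) = [F(A) − A·F'(A)] − F(0)."""
    if A <= 0:
        raise ValueError(f"Δ is defined for A > 0, got {A}")
    return float(F(A) - A * F.derivative(A) - F.at_zero)


def find_delta_root(F: RateFunction, bracket, tol: float = 1e-10) -> float:
    """Amplitude A* in ``bracket`` where Δ(A*) = 0 (the peak of a bell-shaped
    dose-conserved response).  Uses bracketed root finding (Brent) to absolute
    tolerance ``tol`` in A.

    Raises
    ------
    RootNotBracketedError
        If Δ does not change sign on the bracket (e.g. any strictly concave
        or strictly convex F, whose response is monotone with no peak).
    """
    a_lo, a_hi = float(bracket[0]), float(bracket[1])
    d_lo, d_hi = delta(F, a_lo), delta(F, a_hi)
    if d_lo == 0.0:
        return a_lo
    if d_hi == 0.0:
        return a_hi
    if math.copysign(1.0, d_lo) == math.copysign(1.0, d_hi):
        raise RootNotBracketedError(
            f"Δ does not change sign on [{a_lo}, {a_hi}] for {F.label}: "
            f"Δ({a_lo}) = {d_lo:g}, Δ({a_hi}) = {d_hi:g}"
        )
    return float(brentq(lambda a: delta(F, a), a_lo, a_hi, xtol=tol))


def classify_shape_from_delta(F: RateFunction, amplitudes) -> str:
    """Predict the amplitude-compensated frequency-response shape from the
    sign of Δ over the sampled amplitude range.

    Amplitude decreases as frequency increases (A ∝ 1/f), and the response
    slope with respect to frequency carries the sign of Δ(A(f)).  Hence
    Δ > 0 throughout → increasing, Δ < 0 throughout → decreasing, Δ < 0 at
    small A and Δ > 0 at large A (sigmoidal F) → bell, Δ ≡ 0 → flat.
    """
    amps = np.asarray(sorted(amplitudes), dtype=float)
    if amps.size == 0:
        raise ValueError("amplitudes must be non-empty")
    d = np.array([delta(F, a) for a in amps])
    scale = max(abs(F(a)) for a in amps) + abs(F.at_zero)
    tol = 1e-12 * max(scale, 1.0)
    sign = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    if np.all(sign == 0):
        return "flat"
    if np.all(sign >= 0):
        return "increasing"
    if np.all(sign <= 0):
        return "decreasing"
    # mixed signs: sigmoidal case has Δ<0 at small A, Δ>0 at large A
    nz = sign[sign != 0]
    if nz[0] == -1 and nz[-1] == 1 and np.all(np.diff(nz) >= 0):
        return "bell"
    raise ValueError(
        "Δ sign pattern is not monotone over the amplitude range; "
        "shape is not one of increasing/decreasing/bell/flat"
    )


BUILTIN_RATE_FUNCTIONS = {
    "linear": (linear, "c"),
    "power": (power, "p"),
    "saturating": (saturating, "K"),
    "hill": (hill, "K"),
    "hill2": (hill, "K"),
}


def rate_function_from_spec(spec: str) -> RateFunction:
    """Parse a rate-function spec string such as ``hill2:K=1``,
    ``saturating:K=0.5``, ``power:p=2`` or ``linear`` into a RateFunction."""
    name, _, argstr = spec.partition(":")
    name = name.strip().lower()
    if name not in BUILTIN_RATE_FUNCTIONS:
        raise ValueError(
            f"unknown rate function {name!r}; known: {sorted(set(BUILTIN_RATE_FUNCTIONS))}"
        )
    factory = BUILTIN_RATE_FUNCTIONS[name][0]
    kwargs = {}
    if argstr.strip():
        for item in argstr.split(","):
            key, _, val = item.partition("=")
            if not _:
                raise ValueError(f"malformed parameter {item!r} in spec {spec!r}")
            kwargs[key.strip()] = float(val)
    if name == "hill2":
        kwargs.setdefault("n", 2.0)
    return factory(**kwargs)
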