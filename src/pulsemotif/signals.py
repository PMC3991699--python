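"""Dose-conserved rectangular pulse trains.

A pulse train is a T-periodic rectangular signal that is "on" at level A for
the first d time units of each period and zero otherwise.  Its mean dose is
A*d/T.  Two protocols vary the pulse frequency f = 1/T while holding the mean
dose fixed at that of a reference train (A0, d0, T0):

* amplitude compensation: d stays at d0 and A = A0*T/T0, so faster pulsing
  means smaller pulses.  Because d0 must fit inside the period, the protocol
  only admits frequencies f <= 1/d0.
* duration compensation: A stays at A0 and d = d0*T/T0, so the duty cycle
  d/T is frequency-invariant.

Both satisfy A*d/T = A0*d0/T0 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleSignalError

__all__ = [
    "PulseTrain",
    "CompensationProtocol",
    "PROTOCOL_MODES",
    "make_pulse_train",
    "amplitude_compensate",
    "duration_compensate",
    "single_pulse_rescale",
    "evaluate_signal",
    "frequency_grid",
    "trains_to_frame",
]

logger = logging.getLogger(__name__)

PROTOCOL_MODES = ("amplitude_compensated", "duration_compensated", "uncompensated")


@dataclass(frozen=True)
class PulseTrain:
    """A rectangular periodic pulse signal.

    Parameters
    ----------
    amplitude : float
        Pulse height A (input concentration units), non-negative.
    duration : float
        Pulse width d (time units), 0 < d <= T.
    period : float
        Signal period T (time units).  d == T is a constant input at level A.
    """

    amplitude: float
    duration: float
    period: float

    def __post_init__(self):
        A, d, T = self.amplitude, self.duration, self.period
        for name, val in (("amplitude", A), ("duration", d), ("period", T)):
            if not np.isfinite(val):
                raise InfeasibleSignalError(f"{name} must be finite, got {val!r}")
        if A < 0:
            raise InfeasibleSignalError(f"amplitude must be non-negative, got {A}")
        if d <= 0:
            raise InfeasibleSignalError(f"duration must be positive, got {d}")
        if T <= 0:
            raise InfeasibleSignalError(f"period must be positive, got {T}")
        if d > T:
            raise InfeasibleSignalError(
                f"duration {d} exceeds period {T}: the pulse does not fit "
                "(requires 0 < d <= T)"
            )

    @property
    def frequency(self) -> float:
        """Pulse frequency f = 1/T."""
        return 1.0 / self.period

    @property
    def duty_cycle(self) -> float:
        """Fraction of the period the pulse is on, d/T."""
        return self.duration / self.period

    @property
    def mean_dose(self) -> float:
        """Time-averaged input level over one period, A*d/T."""
        return self.amplitude * self.duration / self.period

    @property
    def is_constant(self) -> bool:
        """True when d == T, i.e. the signal is a constant at level A."""
        return self.duration == self.period

    def __call__(self, t):
        """Evaluate the signal at time(s) ``t`` (the pulse occupies [0, d) of
        each period)."""
        t = np.asarray(t, dtype=float)
        level = np.where(np.mod(t, self.period) < self.duration, self.amplitude, 0.0)
        return level if level.ndim else float(level)


def make_pulse_train(amplitude: float, duration: float, period: float) -> PulseTrain:
    """Construct and validate a :class:`PulseTrain`."""
    return PulseTrain(float(amplitude), float(duration), float(period))


def amplitude_compensate(ref: PulseTrain, new_period: float) -> PulseTrain:
    """Rescale the reference train to period ``new_period`` holding dose and
    duration fixed: A = A0*T/T0, d = d0.

    Raises
    ------
    InfeasibleSignalError
        When ``new_period`` < ``ref.duration``: the fixed pulse duration no
        longer fits, which is why the protocol caps frequency at 1/d0.
    """
    if new_period < ref.duration:
        raise InfeasibleSignalError(
            f"period {new_period} is shorter than the fixed pulse duration "
            f"{ref.duration}; amplitude compensation admits frequencies up to "
            f"{1.0 / ref.duration:g} only"
        )
    return PulseTrain(ref.amplitude * new_period / ref.period, ref.duration, new_period)


def duration_compensate(ref: PulseTrain, new_period: float) -> PulseTrain:
    """Rescale the reference train to period ``new_period`` holding dose and
    amplitude fixed: d = d0*T/T0, A = A0.  The duty cycle is invariant."""
    return PulseTrain(ref.amplitude, ref.duration * new_period / ref.period, new_period)


def single_pulse_rescale(ref_amplitude: float, ref_duration: float,
                         new_duration: float) -> float:
    """Dose trade-off for a single pulse: the amplitude A = A0*d0/d that keeps
    the single-pulse dose A*d constant when the duration is changed to ``d``."""
    if new_duration <= 0:
        raise InfeasibleSignalError(f"duration must be positive, got {new_duration}")
    return ref_amplitude * ref_duration / new_duration


def evaluate_signal(train: PulseTrain, t):
    """Signal level at time(s) ``t``: A if (t mod T) < d else 0."""
    return train(t)


@dataclass(frozen=True)
class CompensationProtocol:
    """A dose-conservation protocol anchored at a reference train.

    ``mode`` is one of ``amplitude_compensated``, ``duration_compensated`` or
    ``uncompensated`` (the latter changes only the period, so the mean dose
    scales with frequency)."""

    mode: str
    reference: PulseTrain

    def __post_init__(self):
        if self.mode not in PROTOCOL_MODES:
            raise InfeasibleSignalError(
                f"unknown protocol mode {self.mode!r}; expected one of {PROTOCOL_MODES}"
            )

    @property
    def max_frequency(self) -> float:
        """Largest admissible pulse frequency (1/d0 under amplitude
        compensation, unbounded otherwise)."""
        if self.mode == "amplitude_compensated":
            return 1.0 / self.reference.duration
        return np.inf

    def train_at_period(self, period: float) -> PulseTrain:
        if self.mode == "amplitude_compensated":
            return amplitude_compensate(self.reference, period)
        if self.mode == "duration_compensated":
            return duration_compensate(self.reference, period)
        return PulseTrain(self.reference.amplitude, self.reference.duration, period)

    def train_at_frequency(self, frequency: float) -> PulseTrain:
        return self.train_at_period(1.0 / frequency)


def frequency_grid(ref: PulseTrain, mode: str, f_min: float, f_max: float,
                   n: int, spacing: str = "log") -> list[PulseTrain]:
    """Build ``n`` trains at log- (default) or linearly spaced frequencies in
    [f_min, f_max], mapped through the protocol.

    Under amplitude compensation, frequencies above 1/d0 are infeasible and
    are dropped with a logged warning (the response curve is truncated, not
    clipped).  An empty feasible grid raises :class:`InfeasibleSignalError`.
    """
    if not (0 < f_min < f_max):
        raise InfeasibleSignalError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if n < 2:
        raise InfeasibleSignalError(f"need at least 2 grid points, got {n}")
    if spacing == "log":
        freqs = np.logspace(np.log10(f_min), np.log10(f_max), n)
    elif spacing == "linear":
        freqs = np.linspace(f_min, f_max, n)
    else:
        raise InfeasibleSignalError(f"unknown spacing {spacing!r}")
    # guard against logspace round-off pushing the endpoint past 1/d0
    freqs[0], freqs[-1] = f_min, f_max

    protocol = CompensationProtocol(mode, ref)
    f_cap = protocol.max_frequency
    feasible = freqs[freqs <= f_cap]
    n_dropped = len(freqs) - len(feasible)
    if n_dropped:
        logger.warning(
            "%s: dropped %d frequencies above the admissible maximum 1/d0 = %g",
            mode, n_dropped, f_cap,
        )
    if len(feasible) == 0:
        raise InfeasibleSignalError(
            f"no feasible frequencies in [{f_min}, {f_max}] under {mode} "
            f"(maximum admissible frequency is {f_cap:g})"
        )
    return [protocol.train_at_frequency(f) for f in feasible]


def trains_to_frame(trains) -> pd.DataFrame:
    """Flat table of a list of trains (frequency, period, amplitude, duration,
    mean_dose), suitable for CSV export."""
    return pd.DataFrame(
        {
            "frequency": [tr.frequency for tr in trains],
            "period": [tr.period for tr in trains],
            "amplitude": [tr.amplitude for tr in trains],
            "duration": [tr.duration for tr in trains],
            "mean_dose": [tr.mean_dose for tr in trains],
        }
    )
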