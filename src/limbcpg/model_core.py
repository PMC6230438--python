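"""Closed-form phase and cycle durations of a single-limb half-center CPG.

The rhythm generator for one limb is a pair of reciprocal leaky
integrators (half-centers).  At any moment exactly one half-center is
active; its state ``x`` grows from 0 according to

    dx/dt = x0 + g * u + r_leak * x

until it reaches the threshold 1, at which point it resets to 0 and the
antagonist half-center takes over.  ``u`` is the descending drive — a
scaled desired limb speed — ``x0`` a background excitability offset,
``g`` the input gain and ``r_leak`` a small negative self-feedback that
makes the integrator leaky.

For constant drive the crossing time of each half-center has a closed
form, and the step cycle duration is the sum of the two phase durations.
Two solutions are provided:

* :func:`phase_duration_exact` — the exponential solution
  ``t = ln(1 + r/(x0 + g*u)) / r``;
* :func:`phase_duration_taylor` — its small-leak first-order limit
  ``t = 1/(x0 + g*u)``.

Summing the Taylor phases gives a rational function of the drive,
``Tc(u) = (a + b*u) / (a~ + b~*u + c~*u**2)``, whose five coefficients
follow from the half-center parameters (:func:`rational_coefficients`).

Threshold and reset level are fixed at 1 and 0: the state normalisation
(max − min = 1 per phase) is baked into the closed forms, so a general
threshold is deliberately not exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "THRESHOLD",
    "HalfCenterParams",
    "LimbCPGParams",
    "CycleSolution",
    "RationalFormCoefficients",
    "ThresholdCrossingError",
    "NonPositiveRateError",
    "SaturationError",
    "rational_coefficients",
    "phase_duration_taylor",
    "phase_duration_exact",
    "cycle_duration",
]

#: Switching threshold of every half-center state (state units). Fixed by
#: the per-phase normalisation max − min = 1.
THRESHOLD = 1.0


class ThresholdCrossingError(ValueError):
    """The active half-center state can never reach the threshold.

    Parameters
    ----------
    message : str
        Human-readable description of the failure.
    u_min : float or None
        Smallest admissible drive: for any ``u > u_min`` the phase
        terminates.  ``None`` when no drive can rescue the phase
        (non-positive input gain).
    """

    def __init__(self, message: str, u_min: float | None = None):
        self.base_message = message
        if u_min is not None:
            message = f"{message} (minimal admissible drive u > {u_min:.6g})"
        super().__init__(message)
        self.u_min = u_min


class NonPositiveRateError(ThresholdCrossingError):
    """Effective integration rate x0 + g*u is not positive."""


class SaturationError(ThresholdCrossingError):
    """The leaky state saturates below the threshold.

    With r_leak < 0 the state approaches the asymptote
    (x0 + g*u)/|r_leak|; if that asymptote does not exceed the threshold
    the phase never ends even though the rate at x = 0 is positive.
    """


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class HalfCenterParams:
    """Parameters of one half-center integrator.

    Attributes
    ----------
    x0 : float
        Background offset rate (state units / s).  May be negative; the
        optimised flexor offset of the cat model is −0.0007.
    g : float
        Input gain ((state units / s) per unit drive).
    """

    x0: float
    g: float

    def __post_init__(self) -> None:
        _check_finite("x0", self.x0)
        _check_finite("g", self.g)

    def rate(self, u: float) -> float:
        """Effective integration rate x0 + g*u at drive ``u``."""
        return self.x0 + self.g * u


@dataclass(frozen=True)
class LimbCPGParams:
    """Full parameter set of a single-limb two-half-center CPG.

    ``hc1`` and ``hc2`` are the two reciprocal half-centers (indices 1
    and 2; the phase-name mapping to stance/swing is a reporting label,
    see the package docs).  ``r_leak`` is the shared leak rate (1/s,
    non-positive).  ``threshold`` is fixed at 1.
    """

    hc1: HalfCenterParams
    hc2: HalfCenterParams
    r_leak: float
    threshold: float = THRESHOLD

    def __post_init__(self) -> None:
        _check_finite("r_leak", self.r_leak)
        if self.r_leak > 0:
            raise ValueError(
                f"r_leak must be non-positive (leaky integrator), got {self.r_leak}"
            )
        if self.threshold != THRESHOLD:
            raise ValueError(
                "threshold is fixed at 1 by the state normalisation; "
                f"got {self.threshold}"
            )

    @property
    def half_centers(self) -> tuple[HalfCenterParams, HalfCenterParams]:
        return (self.hc1, self.hc2)


@dataclass(frozen=True)
class CycleSolution:
    """Phase durations and cycle duration at one drive level.

    ``Tc = tau1 + tau2`` holds by construction.
    """

    tau1: float
    tau2: float
    Tc: float

    @classmethod
    def from_phases(cls, tau1: float, tau2: float) -> "CycleSolution":
        if tau1 <= 0 or tau2 <= 0:
            raise ValueError(f"phase durations must be positive, got {tau1}, {tau2}")
        return cls(tau1=tau1, tau2=tau2, Tc=tau1 + tau2)


@dataclass(frozen=True)
class RationalFormCoefficients:
    """Coefficients of the rational cycle-duration law.

    ``Tc(u) = (a + b*u) / (a_t + b_t*u + c_t*u**2)`` where, writing the
    two half-centers as (x01, g1) and (x02, g2):

        a   = x01 + x02          b   = g1 + g2
        a_t = x01 * x02          b_t = x01*g2 + x02*g1       c_t = g1 * g2

    i.e. the numerator is the sum and the denominator the product of the
    two effective rates.
    """

    a: float
    b: float
    a_t: float
    b_t: float
    c_t: float

    def __call__(self, u: float) -> float:
        """Evaluate the rational cycle-duration law at drive ``u``."""
        return (self.a + self.b * u) / (self.a_t + (self.b_t + self.c_t * u) * u)


def rational_coefficients(params: LimbCPGParams) -> RationalFormCoefficients:
    """Expand the sum of the two Taylor phase durations into rational form.

    Pure arithmetic on the half-center parameters; the leak rate does not
    enter (the rational form is the zero-leak limit).
    """
    h1, h2 = params.hc1, params.hc2
    return RationalFormCoefficients(
        a=h1.x0 + h2.x0,
        b=h1.g + h2.g,
        a_t=h1.x0 * h2.x0,
        b_t=h1.x0 * h2.g + h2.x0 * h1.g,
        c_t=h1.g * h2.g,
    )


def _u_min_for_rate(hc: HalfCenterParams, rate_floor: float) -> float | None:
    """Smallest drive with hc.rate(u) > rate_floor, or None if unreachable."""
    if hc.g > 0:
        return (rate_floor - hc.x0) / hc.g
    return None


def phase_duration_taylor(hc: HalfCenterParams, u: float) -> float:
    """Phase duration in the small-leak (Taylor) limit: 1/(x0 + g*u).

    Raises
    ------
    NonPositiveRateError
        If the effective rate x0 + g*u is not positive, i.e. the state
        never reaches the threshold.  The error carries the minimal
        admissible drive when a positive gain makes one exist.
    """
    rate = hc.rate(u)
    if rate <= 0:
        raise NonPositiveRateError(
            f"effective rate x0 + g*u = {rate:.6g} <= 0 at u = {u:.6g}: "
            "state never reaches threshold",
            u_min=_u_min_for_rate(hc, 0.0),
        )
    return 1.0 / rate


def phase_duration_exact(hc: HalfCenterParams, r_leak: float, u: float) -> float:
    """Exact phase duration of the leaky integrator: ln(1 + r/rate)/r.

    For ``r_leak = 0`` this reduces to :func:`phase_duration_taylor`
    (the API stays continuous at the singular parameter value).  With
    ``r_leak < 0`` the exact duration is always at least the Taylor
    value, since the leak slows the approach to threshold.

    Raises
    ------
    NonPositiveRateError
        Rate at x = 0 not positive (as in the Taylor form).
    SaturationError
        Rate positive but the asymptote rate/|r_leak| does not exceed
        the threshold: the state saturates below 1.
    """
    rate = hc.rate(u)
    if rate <= 0:
        raise NonPositiveRateError(
            f"effective rate x0 + g*u = {rate:.6g} <= 0 at u = {u:.6g}: "
            "state never reaches threshold",
            u_min=_u_min_for_rate(hc, max(0.0, -r_leak)),
        )
    if r_leak == 0:
        return 1.0 / rate
    # crossing requires the asymptote rate/|r| to exceed the threshold,
    # equivalently 1 + r/rate > 0
    if rate + r_leak * THRESHOLD <= 0:
        raise SaturationError(
            f"state saturates at {rate / -r_leak:.6g} < threshold 1 "
            f"(rate {rate:.6g} <= |r_leak| {-r_leak:.6g})",
            u_min=_u_min_for_rate(hc, -r_leak * THRESHOLD),
        )
    return math.log1p(r_leak * THRESHOLD / rate) / r_leak


def cycle_duration(
    params: LimbCPGParams, u: float, method: str = "exact"
) -> CycleSolution:
    """Cycle duration at constant drive ``u`` as the sum of both phases.

    Parameters
    ----------
    params : LimbCPGParams
    u : float
        Constant drive (scaled desired limb speed).
    method : {"exact", "taylor"}
        Closed form used per phase.  The Taylor sum is algebraically
        identical to the rational form from
        :func:`rational_coefficients`.

    Raises
    ------
    ThresholdCrossingError
        Propagated from the inadmissible phase, labelled by phase index.
    """
    if method not in ("exact", "taylor"):
        raise ValueError(f"method must be 'exact' or 'taylor', got {method!r}")
    taus = []
    for index, hc in enumerate(params.half_centers, start=1):
        try:
            if method == "taylor":
                taus.append(phase_duration_taylor(hc, u))
            else:
                taus.append(phase_duration_exact(hc, params.r_leak, u))
        except ThresholdCrossingError as err:
            raise type(err)(
                f"phase {index}: {err.base_message}", u_min=err.u_min
            ) from err
    return CycleSolution.from_phases(*taus)
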