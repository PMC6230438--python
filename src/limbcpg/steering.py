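"""Two-limb steering: heading change from an interlimb speed difference.

With independent left/right limb CPGs sharing the speed-command input,
steering follows differential-drive kinematics: over one step cycle of
duration Tc the heading rotates by

    gamma = Tc * (V_R - V_L) / W

where W is the interlimb step width (≈0.15 m in the cat).  Tc is taken
at the mean of the two limb speeds, mapped to CPG drive through the
printed regression — the symmetric choice matching a surface
parameterised by (mean speed, speed differential).

Sign convention: positive gamma turns toward the slower left limb when
V_R > V_L, i.e. counterclockwise in the simulated plane.

:func:`simulate_walk_path` chains per-step heading changes into a planar
trajectory: each step turns by gamma, then advances one stride
(mean speed × Tc) along the updated heading (order configurable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .empirical import SpeedMaps, input_from_speed
from .model_core import LimbCPGParams, ThresholdCrossingError, cycle_duration

__all__ = [
    "SteeringConfig",
    "StepCommand",
    "WalkPath",
    "heading_change",
    "heading_surface",
    "simulate_walk_path",
    "ramp_schedule",
]


@dataclass(frozen=True)
class SteeringConfig:
    """Configuration of the two-limb steering model.

    ``W`` is the interlimb step width (m); ``method`` selects the closed
    form used for Tc (the rational/Taylor form by default);
    ``angle_unit`` only affects reporting, angles are radians
    internally; ``turn_then_translate`` fixes the per-step update order.
    """

    params: LimbCPGParams
    maps: SpeedMaps
    W: float = 0.15
    angle_unit: str = "rad"
    method: str = "taylor"
    turn_then_translate: bool = True

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError(f"step width W must be positive, got {self.W}")
        if self.angle_unit not in ("rad", "deg"):
            raise ValueError(f"angle_unit must be 'rad' or 'deg', got {self.angle_unit}")

    def report_angle(self, rad: float) -> float:
        return math.degrees(rad) if self.angle_unit == "deg" else rad


@dataclass(frozen=True)
class StepCommand:
    """Left/right limb speeds (m/s) commanded for one step cycle."""

    V_R: float
    V_L: float

    @property
    def mean_speed(self) -> float:
        return 0.5 * (self.V_R + self.V_L)

    @property
    def dV(self) -> float:
        return self.V_R - self.V_L

    def __post_init__(self) -> None:
        if self.mean_speed <= 0:
            raise ValueError(
                f"mean limb speed must be positive, got {self.mean_speed}"
            )


@dataclass
class WalkPath:
    """Per-step headings and planar positions of a simulated walk.

    Arrays are per step; ``x``/``y`` are the positions *after* each
    step, starting from the origin.  Stride k connects the previous
    position to (x[k], y[k]) and has length ``stride[k]``.
    """

    V_R: np.ndarray
    V_L: np.ndarray
    Tc: np.ndarray
    gamma: np.ndarray
    heading: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stride: np.ndarray
    initial_heading: float = 0.0

    @property
    def total_length(self) -> float:
        return float(self.stride.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.Tc) + 1),
                "V_R": self.V_R,
                "V_L": self.V_L,
                "Tc_s": self.Tc,
                "gamma_rad": self.gamma,
                "heading_rad": self.heading,
                "x_m": self.x,
                "y_m": self.y,
                "stride_m": self.stride,
            }
        )


def _cycle_duration_at_mean(cmd: StepCommand, cfg: SteeringConfig) -> float:
    u = float(input_from_speed(cmd.mean_speed, cfg.maps))
    try:
        return cycle_duration(cfg.params, u, method=cfg.method).Tc
    except ThresholdCrossingError as err:
        raise type(err)(
            f"mean speed {cmd.mean_speed:.4g} m/s (drive {u:.4g}): "
            f"{err.base_message}",
            u_min=err.u_min,
        ) from err


def heading_change(cmd: StepCommand, cfg: SteeringConfig) -> float:
    """Per-cycle heading change gamma = Tc * (V_R − V_L) / W (rad).

    Tc is evaluated at the mean limb speed; gamma is exactly zero for
    equal limb speeds and odd in the speed differential.
    """
    Tc = _cycle_duration_at_mean(cmd, cfg)
    return Tc * cmd.dV / cfg.W


def heading_surface(
    mean_speeds, dV, cfg: SteeringConfig
) -> np.ndarray:
    """Heading-change surface over (mean speed, speed differential).

    Returns gamma[i, j] (rad) for ``mean_speeds[i]`` and ``dV[j]``.
    Inadmissible cells (e.g. non-positive limb mean) are recorded as NaN
    with a warning rather than failing the whole surface.
    """
    mean_speeds = np.asarray(mean_speeds, dtype=float)
    dV = np.asarray(dV, dtype=float)
    gamma = np.full((len(mean_speeds), len(dV)), np.nan)
    bad = 0
    for i, V in enumerate(mean_speeds):
        for j, d in enumerate(dV):
            try:
                gamma[i, j] = heading_change(
                    StepCommand(V_R=V + d / 2, V_L=V - d / 2), cfg
                )
            except (ValueError, ThresholdCrossingError):
                bad += 1
    if bad:
        warnings.warn(
            f"{bad} inadmissible (mean speed, dV) cells recorded as NaN",
            stacklevel=2,
        )
    return gamma


def simulate_walk_path(
    steps: list[StepCommand],
    cfg: SteeringConfig,
    initial_heading: float = 0.0,
) -> WalkPath:
    """Chain step commands into a planar walking trajectory.

    Each step turns the heading by its gamma, then translates one
    stride (mean speed × Tc) along the updated heading (or the reverse
    order if configured).  Fails on the first inadmissible step,
    reporting its 1-based index.
    """
    if not steps:
        raise ValueError("need at least one step command")
    n = len(steps)
    V_R = np.empty(n)
    V_L = np.empty(n)
    Tc = np.empty(n)
    gamma = np.empty(n)
    heading = np.empty(n)
    xs = np.empty(n)
    ys = np.empty(n)
    stride = np.empty(n)

    h = initial_heading
    px, py = 0.0, 0.0
    for k, cmd in enumerate(steps):
        try:
            Tc_k = _cycle_duration_at_mean(cmd, cfg)
        except ThresholdCrossingError as err:
            raise type(err)(
                f"step {k + 1}: {err.base_message}", u_min=err.u_min
            ) from err
        except ValueError as err:
            raise ValueError(f"step {k + 1}: {err}") from err
        g_k = Tc_k * cmd.dV / cfg.W
        s_k = cmd.mean_speed * Tc_k
        if cfg.turn_then_translate:
            h += g_k
            px += s_k * math.cos(h)
            py += s_k * math.sin(h)
        else:
            px += s_k * math.cos(h)
            py += s_k * math.sin(h)
            h += g_k
        V_R[k], V_L[k] = cmd.V_R, cmd.V_L
        Tc[k], gamma[k], heading[k] = Tc_k, g_k, h
        xs[k], ys[k], stride[k] = px, py, s_k

    return WalkPath(
        V_R=V_R, V_L=V_L, Tc=Tc, gamma=gamma, heading=heading,
        x=xs, y=ys, stride=stride, initial_heading=initial_heading,
    )


def ramp_schedule(
    mean_speed: float, dV_max: float, n_steps: int = 5
) -> list[StepCommand]:
    """Constant-speed schedule with the speed differential ramping 0 → dV_max.

    The differential increases linearly over the steps (first step
    straight), reproducing the curved-walk scenarios: consecutive steps
    turn progressively harder, and the same schedule at a higher mean
    speed turns less because Tc shrinks.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    dVs = np.linspace(0.0, dV_max, n_steps)
    return [
        StepCommand(V_R=mean_speed + d / 2, V_L=mean_speed - d / 2) for d in dVs
    ]
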