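"""Time-domain simulation of the two-half-center CPG with reset events.

This module is the numerical counterpart (and the in-package brute-force
check) of the closed forms in :mod:`limbcpg.model_core`, and the only
route for time-varying drive.  One half-center integrates

    dx/dt = x0 + g * u(t) + r_leak * x

from 0; when it crosses the threshold 1 it resets to 0 and hands over to
the antagonist.  The inactive state is clamped at 0 — reciprocity is
enforced structurally, never by numerics.

Within every integration step the drive is constant, so the linear ODE
is advanced with its exact exponential update and the threshold-crossing
time is obtained by solving the local closed form.  Event localisation
therefore carries no discretisation error; ``dt`` only sets the sampling
density of the recorded trajectory and the granularity at which
piecewise drive changes are honoured (drive breakpoints additionally
split steps exactly).
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    THRESHOLD,
    CycleSolution,
    LimbCPGParams,
)

__all__ = [
    "InputSignal",
    "PhaseEvent",
    "StateTrajectory",
    "StalledOscillatorError",
    "simulate",
    "measure_cycles",
]


class StalledOscillatorError(RuntimeError):
    """The active half-center can no longer reach the threshold.

    Raised when the active state's derivative is non-positive below
    threshold, or when it saturates below threshold with no upcoming
    drive change that could rescue it.  ``stall_time`` (s) and the
    stalled ``state_index`` are attached.
    """

    def __init__(self, message: str, stall_time: float, state_index: int):
        super().__init__(f"{message} (stalled at t = {stall_time:.6g} s, state {state_index})")
        self.stall_time = stall_time
        self.state_index = state_index


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant drive schedule.

    ``schedule`` is a tuple of ``(start_time_s, u)`` pairs with start
    times strictly increasing from 0; each value holds until the next
    start time.
    """

    schedule: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one (time, u) pair")
        times = [t for t, _ in self.schedule]
        if times[0] != 0.0:
            raise ValueError(f"schedule must start at time 0, got {times[0]}")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule start times must be strictly increasing")

    @classmethod
    def constant(cls, u: float) -> "InputSignal":
        return cls(schedule=((0.0, float(u)),))

    @classmethod
    def steps(cls, pairs) -> "InputSignal":
        return cls(schedule=tuple((float(t), float(u)) for t, u in pairs))

    def value(self, t: float) -> float:
        """Drive at time ``t`` (left-continuous from each breakpoint)."""
        times = [s for s, _ in self.schedule]
        idx = bisect_right(times, t) - 1
        return self.schedule[max(idx, 0)][1]

    def next_breakpoint(self, t: float) -> float | None:
        """First schedule start time strictly after ``t``, if any."""
        for start, _ in self.schedule:
            if start > t:
                return start
        return None


@dataclass(frozen=True)
class PhaseEvent:
    """A threshold crossing: the end of one phase.

    ``cycle_index`` counts completed swing+stance pairs (0-based index
    of the cycle the finished phase belongs to).
    """

    time: float
    ending_state: int
    duration: float
    cycle_index: int


@dataclass
class StateTrajectory:
    """Sampled two-state trajectory with the active-state index.

    The inactive state is identically 0; the active state rises from 0
    to the threshold within each phase.
    """

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    active: np.ndarray

    _rows: list = field(default_factory=list, repr=False)

    @classmethod
    def _empty(cls) -> "StateTrajectory":
        z = np.empty(0)
        return cls(times=z, x1=z.copy(), x2=z.copy(), active=np.empty(0, dtype=int))

    def _append(self, t: float, x: float, active: int) -> None:
        self._rows.append((t, x if active == 1 else 0.0, x if active == 2 else 0.0, active))

    def _finalize(self) -> None:
        arr = np.asarray(self._rows, dtype=float)
        self.times = arr[:, 0]
        self.x1 = arr[:, 1]
        self.x2 = arr[:, 2]
        self.active = arr[:, 3].astype(int)
        self._rows = []


def _propagate(x: float, rate: float, r: float, s: float) -> float:
    """Advance ``dx/dt = rate + r*x`` from ``x`` by time ``s`` exactly."""
    if r == 0.0:
        return x + rate * s
    c = x + rate / r
    return c * math.exp(r * s) - rate / r


def _crossing_time(x: float, rate: float, r: float) -> float | None:
    """Time for the state to rise from ``x`` to the threshold, or None.

    None means the state never reaches the threshold under this
    (rate, r): non-positive derivative or saturation below threshold.
    """
    if x >= THRESHOLD:
        return 0.0
    if r == 0.0:
        return (THRESHOLD - x) / rate if rate > 0 else None
    top = THRESHOLD + rate / r
    bottom = x + rate / r
    # with r < 0 both must be negative (asymptote above threshold)
    if top * bottom <= 0 or top / bottom <= 0:
        return None
    s = math.log(top / bottom) / r
    return s if s >= 0 else None


def simulate(
    params: LimbCPGParams,
    input: InputSignal | float,
    t_end: float,
    initial_active: int = 1,
    dt: float = 1e-4,
) -> tuple[StateTrajectory, list[PhaseEvent]]:
    """Integrate the reciprocal pair with threshold resetting.

    Parameters
    ----------
    params : LimbCPGParams
    input : InputSignal or float
        Piecewise-constant drive schedule; a bare number is treated as
        a constant drive.
    t_end : float
        Simulation horizon (s).
    initial_active : {1, 2}
        Which half-center starts integrating (both states start at 0;
        for constant drive the steady rhythm does not depend on this).
    dt : float
        Trajectory sampling interval (s).  The integrator itself is
        exact per segment; crossings are located analytically.

    Returns
    -------
    (StateTrajectory, list[PhaseEvent])

    Raises
    ------
    StalledOscillatorError
        If the active state's derivative becomes non-positive below
        threshold, or the state saturates below threshold with no
        future drive change.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if initial_active not in (1, 2):
        raise ValueError(f"initial_active must be 1 or 2, got {initial_active}")
    if not isinstance(input, InputSignal):
        input = InputSignal.constant(float(input))

    r = params.r_leak
    t = 0.0
    x = 0.0
    active = initial_active
    phase_start = 0.0
    events: list[PhaseEvent] = []
    traj = StateTrajectory._empty()
    traj._append(t, x, active)
    sample_idx = 1  # next sample at sample_idx * dt

    # (t, x) anchors the current constant-drive segment; samples inside a
    # segment are computed analytically from the anchor, so the trajectory
    # and the event times carry no per-dt rounding accumulation
    while t < t_end:
        u = input.value(t)
        hc = params.half_centers[active - 1]
        rate = hc.rate(u)

        deriv = rate + r * x
        if deriv <= 0.0:
            raise StalledOscillatorError(
                f"active state {active} has non-positive derivative "
                f"{deriv:.6g} below threshold",
                stall_time=t,
                state_index=active,
            )

        brk = input.next_breakpoint(t)
        s_cross = _crossing_time(x, rate, r)
        if s_cross is None and brk is None:
            raise StalledOscillatorError(
                f"active state {active} saturates at {rate / -r:.6g} "
                "below threshold with constant drive",
                stall_time=t,
                state_index=active,
            )

        seg_end = min(t_end, brk) if brk is not None else t_end
        crossing = s_cross is not None and t + s_cross <= seg_end
        t_next = t + s_cross if crossing else seg_end

        while sample_idx * dt <= t_next:
            ts = sample_idx * dt
            sample_idx += 1
            if ts <= t:
                continue
            xs = min(_propagate(x, rate, r, ts - t), THRESHOLD)
            traj._append(ts, xs, active)

        if crossing:
            events.append(
                PhaseEvent(
                    time=t_next,
                    ending_state=active,
                    duration=t_next - phase_start,
                    cycle_index=len(events) // 2,
                )
            )
            x = 0.0
            active = 2 if active == 1 else 1
            phase_start = t_next
        else:
            x = _propagate(x, rate, r, t_next - t)
        t = t_next

    traj._finalize()
    return traj, events


def measure_cycles(events: list[PhaseEvent]) -> list[CycleSolution]:
    """Pair consecutive phase durations into full cycles.

    An unpaired trailing phase is discarded.  Fewer than two events
    yields an empty list with a warning.  Events whose ending states do
    not strictly alternate are rejected.
    """
    if len(events) < 2:
        warnings.warn(
            f"need at least 2 phase events to form a cycle, got {len(events)}",
            stacklevel=2,
        )
        return []
    for prev, nxt in zip(events, events[1:]):
        if nxt.ending_state == prev.ending_state:
            raise ValueError(
                f"phase events must alternate ending states; got state "
                f"{nxt.ending_state} twice around t = {nxt.time:.6g} s"
            )
    cycles = []
    for k in range(0, len(events) - 1, 2):
        cycles.append(
            CycleSolution.from_phases(events[k].duration, events[k + 1].duration)
        )
    return cycles
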