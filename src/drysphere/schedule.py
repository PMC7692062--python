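"""Time-dependent ambient programs for continuous and intermittent drying.

A drying program is a cyclic sequence of stages, each holding the chamber
air temperature T_inf, relative humidity RH_inf and speed U_inf for a fixed
duration.  The canonical intermittent program alternates a convective stage
(C: hot, dry, fast air) with two pause stages (P1: hot-humid "barreling",
P2: cool-humid "night").  Stage switches in a real chamber take ~30 min, so
ambient values are blended at every stage boundary with the smooth step

    theta_delta(t) = (1 - tanh(t/delta)) / 2,   delta = 0.1 h by default,

which makes the ambient forcing C-infinity in time and keeps the stiff
integrator happy.  An optional ``startup`` ambient models the switch-on
transient at t = 0 (the chamber ramping from lab/night conditions up to the
first stage); it uses the same blending width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AmbientConditions",
    "Stage",
    "CycleProgram",
    "smooth_step",
    "ambient_at",
]


@dataclass(frozen=True)
class AmbientConditions:
    """Chamber air state at one time instant."""

    T_inf: float  # K
    RH_inf: float  # [-], in [0, 1]
    U_inf: float  # m/s


@dataclass(frozen=True)
class Stage:
    """One constant-ambient stage of a drying program."""

    duration_h: float
    T_inf: float  # K
    RH_inf: float
    U_inf: float
    label: str = "C"

    def __post_init__(self):
        if not (self.duration_h > 0):
            raise ValueError("stage duration must be > 0")
        if not (0.0 <= self.RH_inf <= 1.0):
            raise ValueError("RH_inf must lie in [0, 1]")
        if self.U_inf < 0:
            raise ValueError("U_inf must be >= 0")


@dataclass(frozen=True)
class CycleProgram:
    """Cyclic repetition of an ordered stage list, with smooth switching.

    ``n_cycles`` full repetitions of ``stages``, optionally followed by
    ``extra_stages`` (a trailing partial cycle).  ``delta_h`` is the
    half-width of the tanh switch.  ``startup``, if given, is the ambient
    state the chamber ramps *from* at t = 0.  A continuous program is a
    single stage (possibly of unbounded duration).
    """

    stages: Sequence[Stage]
    n_cycles: int = 1
    delta_h: float = 0.1
    startup: Optional[AmbientConditions] = None
    extra_stages: Sequence[Stage] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("program needs at least one stage")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")
        if not (self.delta_h > 0):
            raise ValueError("switch half-width delta must be > 0")

    @property
    def occurrences(self) -> list[Stage]:
        """Flat list of stage occurrences over all cycles."""
        return list(self.stages) * self.n_cycles + list(self.extra_stages)

    @property
    def total_duration_h(self) -> float:
        return float(sum(s.duration_h for s in self.occurrences))

    @property
    def switch_times_h(self) -> np.ndarray:
        """Stage-boundary instants, including the t=0 switch-on."""
        durs = [s.duration_h for s in self.occurrences]
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])


def smooth_step(t, delta: float):
    """Smooth switch weight theta_delta(t) = (1 - tanh(t/delta))/2.

    Equals 1 well before t=0, 1/2 at t=0 and 0 well after; satisfies
    theta(t) + theta(-t) = 1.  ``t`` and ``delta`` share units (hours here).
    """
    if not (delta > 0):
        raise ValueError("delta must be > 0")
    out = 0.5 * (1.0 - np.tanh(np.asarray(t, dtype=float) / delta))
    return out if out.ndim else float(out)


def _stage_values(program: CycleProgram):
    occ = program.occurrences
    vals = np.array([[s.T_inf, s.RH_inf, s.U_inf] for s in occ])
    if program.startup is not None:
        s0 = program.startup
        start = np.array([s0.T_inf, s0.RH_inf, s0.U_inf])
        switches = program.switch_times_h.copy()
        # The switch-on ramp is centered 3*delta after t=0 (interior switches
        # are centered on their boundary) so the program actually starts at
        # the startup ambient rather than halfway through the first switch.
        switches[0] = 3.0 * program.delta_h
    else:
        start = vals[0]
        switches = program.switch_times_h[1:]
        vals = vals[1:] if len(occ) > 1 else vals[:0]
    return start, switches, vals


def ambient_at(t_h, program: CycleProgram) -> AmbientConditions:
    """Ambient conditions at time ``t_h`` [h] into the program.

    Piecewise stage values blended at each boundary t_k with
    theta_delta(t - t_k); far from boundaries the exact stage plateau is
    returned.  Raises ``ValueError`` outside [0, total duration].
    """
    total = program.total_duration_h
    slack = 1e-9 * max(1.0, total if math.isfinite(total) else 1.0)
    if t_h < -slack or t_h > total + slack:
        raise ValueError(f"t = {t_h} h outside the program span [0, {total}] h")
    start, switches, vals = _stage_values(program)
    v = start.copy()
    for t_k, v_k in zip(switches, vals):
        w = 0.5 * (1.0 + math.tanh((t_h - t_k) / program.delta_h))
        v = v + (v_k - v) * w
    return AmbientConditions(T_inf=float(v[0]), RH_inf=float(v[1]), U_inf=float(v[2]))


def standard_cycle(
    T_max: float,
    U_max: float,
    T_night: float = 290.15,
    RH_dry: float = 0.15,
    RH_humid: float = 0.80,
    U_pause: float = 0.1,
) -> list[Stage]:
    """The canonical three-stage solar-drying cycle.

    10 h convective drying (C) at ``T_max``/``RH_dry``/``U_max``, then a 7 h
    hot-humid pause (P1) at the same temperature, then a 7 h cool-humid
    night pause (P2) at ``T_night``.  Pause air speed is 0.1 m/s.
    """
    return [
        Stage(10.0, T_max, RH_dry, U_max, "C"),
        Stage(7.0, T_max, RH_humid, U_pause, "P1"),
        Stage(7.0, T_night, RH_humid, U_pause, "P2"),
    ]
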