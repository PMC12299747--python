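"""Air-blown sorting kinematics.

After grading, a timed air jet pushes each mushroom sideways off the
conveyor belt into its grade's collection box.  This module models that
motion in three steps:

1. **Blow-off feasibility.**  The jet force is the pump pressure over the
   tube cross-section, ``F = P * pi * r^2``; it moves the mushroom only
   if it exceeds belt friction ``mu * m * g``.  Equivalently the
   break-even mass ``m* = F / (mu * g)`` must exceed the mushroom's mass
   (tens of kilograms versus ~30 g in practice, so feasibility is never
   in doubt for realistic pumps).
2. **Impulse.**  The blow is short enough that the mushroom does not move
   while it lasts; the lateral speed right after is
   ``Vy1 = (F * dt0 + m * Vy0) / m``.
3. **Crossing.**  The mushroom starts in the middle of the belt and must
   cross ``W/2`` laterally while the belt carries it forward at ``Vx``;
   the horizontal displacement along the belt is ``X = dt1 * Vx`` where
   ``dt1`` is the crossing time under constant friction deceleration
   ``a = mu * g``.

Two crossing modes are provided.  ``friction_decelerates`` (the default)
treats friction as opposing the lateral slide, ``Vy2 = sqrt(Vy1^2 - 2 a
(W/2))``, and detects a stall when the mushroom runs out of speed on the
belt.  ``as_printed`` uses the sign convention with friction *adding*
speed, ``Vy2 = sqrt(Vy1^2 + 2 a (W/2))``; it is retained so published
worked examples using that convention can be reproduced.

``pi_const`` defaults to 3.14: engineering worked examples for this rig
round pi, and matching their arithmetic to the printed digit requires the
same rounding.  Pass ``pi_const="exact"`` for full-precision pi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

PiConst = float | Literal["exact"]
CrossingMode = Literal["as_printed", "friction_decelerates"]

DEFAULT_PI = 3.14


def _pi(pi_const: PiConst) -> float:
    return math.pi if pi_const == "exact" else float(pi_const)


class StallWarning(UserWarning):
    """Friction stops the mushroom before it leaves the belt."""


@dataclass(frozen=True)
class AirBlowParams:
    """Physical parameters of the blow-off rig.

    Units: ``P`` Pa, ``r`` m, ``m`` kg, ``g`` m/s^2, ``dt0`` s,
    ``Vy0``/``Vx`` m/s, ``W`` (belt width) m; ``mu`` unitless.
    """

    P: float = 0.80e6
    r: float = 4e-3
    mu: float = 0.10
    m: float = 0.030
    g: float = 9.80
    dt0: float = 1e-3
    Vy0: float = 0.0
    Vx: float = 0.10
    W: float = 0.20
    pi_const: PiConst = DEFAULT_PI

    def __post_init__(self) -> None:
        for name in ("P", "r", "m", "g", "W"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dt0", "Vx", "Vy0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.mu <= 1:
            raise ValueError("mu must lie in (0, 1]")


@dataclass(frozen=True)
class TrajectoryResult:
    """Derived quantities of one blow-off event (SI units)."""

    S_tube: float       # tube cross-section, m^2
    F: float            # blow force, N
    displaceable: bool
    Vy1: float          # lateral speed just after the blow, m/s
    a: float            # friction deceleration magnitude, m/s^2
    Vy2: float          # lateral speed at the belt edge, m/s
    dt1: float          # crossing time, s
    X: float            # displacement along the belt, m
    stalled: bool = False


def blow_force(P: float, r: float, pi_const: PiConst = DEFAULT_PI) -> tuple[float, float]:
    """Tube cross-section S = pi r^2 and jet force F = P S.

    Inputs in SI (Pa, m); returns (m^2, N).
    """
    if P <= 0 or r <= 0:
        raise ValueError("P and r must be positive")
    S = _pi(pi_const) * r * r
    return S, P * S


def break_even_mass(
    P: float, r: float, mu: float, g: float, pi_const: PiConst = DEFAULT_PI
) -> float:
    """Mass at which the jet force exactly balances belt friction, kg."""
    if mu <= 0 or g <= 0:
        raise ValueError("mu and g must be positive")
    _, F = blow_force(P, r, pi_const)
    return F / (mu * g)


def can_displace(params: AirBlowParams) -> bool:
    """True iff the jet force strictly exceeds belt friction on this mushroom."""
    _, F = blow_force(params.P, params.r, params.pi_const)
    return F > params.mu * params.m * params.g


def post_blow_velocity(F: float, dt0: float, m: float, Vy0: float = 0.0) -> float:
    """Lateral speed after the blow, from the impulse F dt0 = m (Vy1 - Vy0)."""
    if m <= 0:
        raise ValueError("m must be positive")
    return (F * dt0 + m * Vy0) / m


def crossing_kinematics(
    params: AirBlowParams,
    Vy1: float,
    mode: CrossingMode = "friction_decelerates",
) -> tuple[float, float, float, float]:
    """Edge speed, crossing time and along-belt displacement.

    The lateral travel distance is ``W/2`` (belt-center start).  Returns
    ``(a, Vy2, dt1, X)``.  In ``friction_decelerates`` mode a
    :class:`StallWarning` is emitted when ``Vy1^2 < 2 a W/2`` — the
    mushroom stops short of the edge; the reported ``dt1``/``X`` then
    cover the slide up to the stall point.
    """
    if Vy1 <= 0:
        raise ValueError("Vy1 must be positive")
    if params.W <= 0:
        raise ValueError("belt width W must be positive")
    a = params.mu * params.g
    d = params.W / 2.0
    if mode == "as_printed":
        Vy2 = math.sqrt(2 * a * d + Vy1 * Vy1)
        dt1 = (Vy2 - Vy1) / a
    elif mode == "friction_decelerates":
        disc = Vy1 * Vy1 - 2 * a * d
        if disc < 0:
            warnings.warn(
                f"mushroom stalls on the belt: Vy1={Vy1:.3g} m/s cannot cross "
                f"{d:.3g} m against a={a:.3g} m/s^2",
                StallWarning,
                stacklevel=2,
            )
            disc = 0.0
        Vy2 = math.sqrt(disc)
        dt1 = (Vy1 - Vy2) / a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    X = dt1 * params.Vx
    return a, Vy2, dt1, X


def simulate(params: AirBlowParams, mode: CrossingMode = "friction_decelerates") -> TrajectoryResult:
    """Run the full model: feasibility, impulse, crossing."""
    S, F = blow_force(params.P, params.r, params.pi_const)
    displaceable = F > params.mu * params.m * params.g
    Vy1 = post_blow_velocity(F, params.dt0, params.m, params.Vy0)
    stalled = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", StallWarning)
        a, Vy2, dt1, X = crossing_kinematics(params, Vy1, mode)
        stalled = any(issubclass(w.category, StallWarning) for w in caught)
    if stalled:
        warnings.warn("stall detected during crossing", StallWarning, stacklevel=2)
    return TrajectoryResult(
        S_tube=S, F=F, displaceable=displaceable,
        Vy1=Vy1, a=a, Vy2=Vy2, dt1=dt1, X=X, stalled=stalled,
    )


def displacement_envelope(
    params: AirBlowParams,
    m_min: float,
    m_max: float,
    mode: CrossingMode = "friction_decelerates",
) -> tuple[float, float]:
    """Displacement X at the two mass extremes, returned sorted.

    For a fixed impulse, ``Vy1`` falls with mass, so in the default mode
    the heaviest mushroom travels least along the belt before leaving it.
    Stall warnings from either endpoint propagate.
    """
    if not 0 < m_min <= m_max:
        raise ValueError("need 0 < m_min <= m_max")
    xs = []
    for m in (m_min, m_max):
        p = AirBlowParams(
            P=params.P, r=params.r, mu=params.mu, m=m, g=params.g,
            dt0=params.dt0, Vy0=params.Vy0, Vx=params.Vx, W=params.W,
            pi_const=params.pi_const,
        )
        xs.append(simulate(p, mode).X)
    return min(xs), max(xs)
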