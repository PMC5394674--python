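"""Minimum-time bang-bang schooling controller.

A focal fish senses its own speed ``v_F``, its partner's speed ``v_P`` and
the signed along-track distance ``d = x_partner - x_focal``.  Its locomotor
output is binary: burst at the maximal available acceleration
``a_max * (1 - v_F / v_max)`` or glide passively under viscous drag
``-alpha * v_F``.  Minimum-time control with bounded input is bang-bang, and
the switch happens on the surface where pure gliding alone would bring the
pair to maximal cohesion (same position, same speed).

For ``v_F >= v_P`` the glide-matching distance — the relative distance that
a glide closes before the focal's exponentially decaying speed matches the
partner's — has the closed form

    d*(v_F, v_P) = (v_F - v_P)/alpha - (v_P/alpha) * ln(v_F/v_P),

so the decision function is ``T = d - d*``; bursting for ``T > 0``, gliding
otherwise.  A slower focal fish can never be caught by gliding, so there
``T = d``.  A focal fish in front of its partner (``d < 0``) glides: the
rear blind angle makes partner estimates unreliable, and being overtaken is
the passive route back to the controllable half-space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .kinematics import LocomotorParams

__all__ = [
    "DecisionState",
    "ControlAction",
    "SensoryNoise",
    "glide_matching_distance",
    "decision_surface",
    "control_action",
    "integrate_policy",
    "PolicyTrace",
    "acceleration_grid",
]


@dataclass(frozen=True)
class DecisionState:
    """Sensory input triple (v_F, v_P, d); speeds in cm/s, distance in cm."""

    v_f: float
    v_p: float
    d: float

    def __post_init__(self) -> None:
        if self.v_f < 0 or self.v_p < 0:
            raise ValueError("speeds must be non-negative")


@dataclass(frozen=True)
class ControlAction:
    mode: Literal["burst", "glide"]
    acceleration: float  # cm/s^2

    def __post_init__(self) -> None:
        if self.mode == "burst" and self.acceleration < 0:
            raise ValueError("burst acceleration must be non-negative")
        if self.mode == "glide" and self.acceleration > 0:
            raise ValueError("glide acceleration must be non-positive")


@dataclass
class SensoryNoise:
    """Additive Gaussian error on the perceived inter-fish distance.

    With ``tau_s = 0`` (default) each call to :meth:`perceive` draws a
    fresh independent error of standard deviation ``sigma_d``.  A positive
    ``tau_s`` makes the error an Ornstein-Uhlenbeck process with that
    correlation time (updated by ``dt`` per call, stationary s.d. still
    ``sigma_d``): a slowly drifting distance-estimation bias rather than
    frame-rate flicker.  ``sigma_d = 0`` reproduces the noiseless
    controller exactly (no random draws are consumed).
    """

    sigma_d: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    tau_s: float = 0.0
    dt: float = 1.0 / 30.0
    _bias: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be non-negative")
        if self.tau_s < 0 or self.dt <= 0:
            raise ValueError("tau_s must be >= 0 and dt > 0")
        if self.tau_s > 0:
            # start from the stationary distribution
            self._bias = self.sigma_d * self.rng.standard_normal()

    def perceive(self, d: float) -> float:
        if self.sigma_d == 0.0:
            return d
        if self.tau_s == 0.0:
            return d + self.sigma_d * self.rng.standard_normal()
        a = self.dt / self.tau_s
        self._bias += -a * self._bias + self.sigma_d * math.sqrt(2.0 * a) * self.rng.standard_normal()
        return d + self._bias


def glide_matching_distance(v_f: float, v_p: float, alpha: float) -> float:
    """Relative distance closed by gliding until speed matches the partner's.

    Requires ``v_f >= v_p >= 0`` and ``alpha > 0``.  Continuous in both
    speeds; the limit ``v_p -> 0`` is the total glide distance ``v_f/alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if v_p < 0 or v_f < v_p:
        raise ValueError("requires v_f >= v_p >= 0 (no glide-matching time otherwise)")
    if v_p == 0.0:
        return v_f / alpha
    if v_f == v_p:
        return 0.0
    return (v_f - v_p) / alpha - (v_p / alpha) * math.log(v_f / v_p)


def decision_surface(state: DecisionState, params: LocomotorParams) -> float:
    """Signed distance T to the burst/glide switching surface (cm).

    ``T > 0`` means gliding alone cannot reach cohesion (burst); ``T < 0``
    means a glide overshoots (keep gliding).  For a focal fish slower than
    its partner ``T = d``: any positive gap demands a burst.
    """
    if state.v_f >= state.v_p:
        return state.d - glide_matching_distance(state.v_f, state.v_p, params.alpha)
    return state.d


def control_action(
    state: DecisionState,
    params: LocomotorParams,
    noise: Optional[SensoryNoise] = None,
) -> ControlAction:
    """Memoryless bang-bang decision from the (possibly noisy) state.

    The perceived distance is ``d + eps`` with ``eps ~ N(0, sigma_d^2)``
    drawn fresh per call.  In front of the partner (perceived ``d < 0``) the
    fish glides; behind, it bursts iff ``T > 0`` (ties resolve to glide, the
    passive default).
    """
    d_perceived = state.d if noise is None else noise.perceive(state.d)
    if d_perceived >= 0:
        t_val = decision_surface(
            DecisionState(state.v_f, state.v_p, d_perceived), params
        )
        if t_val > 0:
            return ControlAction("burst", params.burst_acceleration(state.v_f))
    return ControlAction("glide", params.glide_acceleration(state.v_f))


@dataclass
class PolicyTrace:
    """Closed-loop trace of the focal fish against a constant-speed partner."""

    times: np.ndarray
    v_f: np.ndarray
    d: np.ndarray
    mode: np.ndarray  # "burst"/"glide" per step
    acceleration: np.ndarray


def integrate_policy(
    initial: DecisionState,
    params: LocomotorParams,
    noise: Optional[SensoryNoise] = None,
    dt: float = 1.0 / 30.0,
    horizon: float = 60.0,
) -> PolicyTrace:
    """Forward-Euler integration of the closed loop (partner at constant v_P).

    Speed is kept in [0, v_max] after each step.  With no sensory noise the
    trace crosses the switching surface at most once from burst to glide and
    then converges: |d| and |v_F - v_P| both shrink below tolerance.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(horizon / dt))
    times = np.arange(n) * dt
    v = np.empty(n)
    dist = np.empty(n)
    modes = np.empty(n, dtype=object)
    accel = np.empty(n)
    v_f, d = initial.v_f, initial.d
    v_p = initial.v_p
    for i in range(n):
        action = control_action(DecisionState(v_f, v_p, d), params, noise)
        v[i], dist[i], modes[i], accel[i] = v_f, d, action.mode, action.acceleration
        d += (v_p - v_f) * dt
        v_f = min(max(v_f + action.acceleration * dt, 0.0), params.v_max)
        if not (math.isfinite(v_f) and math.isfinite(d)):
            raise FloatingPointError(f"non-finite state at step {i}")
    return PolicyTrace(times, v, dist, modes, accel)


def acceleration_grid(
    d_values: np.ndarray,
    vp_values: np.ndarray,
    v_f: float,
    params: LocomotorParams,
    sigma_d: float = 0.0,
    n_noise: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Controller acceleration over a (distance x partner-speed) grid.

    With ``sigma_d > 0`` each cell is the mean action over ``n_noise``
    perceived-distance draws, i.e. the expected acceleration under sensory
    noise (the smoothed decision map); with ``sigma_d = 0`` it is the sharp
    noiseless map.  Shape: ``(len(d_values), len(vp_values))``.
    """
    if sigma_d > 0 and rng is None:
        rng = np.random.default_rng()
    out = np.empty((len(d_values), len(vp_values)))
    for i, d in enumerate(d_values):
        for j, vp in enumerate(vp_values):
            state = DecisionState(v_f, float(vp), float(d))
            if sigma_d == 0.0:
                out[i, j] = control_action(state, params).acceleration
            else:
                noise = SensoryNoise(sigma_d, rng)
                out[i, j] = float(
                    np.mean(
                        [
                            control_action(state, params, noise).acceleration
                            for _ in range(n_noise)
                        ]
                    )
                )
    return out
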