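"""Closed-loop leader-follower simulation on a quasi-1-D ring.

Wall-following fish in a square tank move along essentially one-dimensional
tracks, so the pair is simulated on a ring whose circumference matches the
tank perimeter.  A leader swims non-socially in a hysteresis burst-glide
oscillation between two speed thresholds; the follower obeys the
minimum-time bang-bang controller, except during non-social episodes —
governed by a two-state Markov chain — when it reverts to the same
oscillator.  Roles may alternate at exponentially distributed intervals,
mirroring the alternating leadership seen in real pairs.

Output is a :class:`~pairschool.kinematics.TrajectoryPair` in the same
dialect as tracked experimental data (unwrapped arclength as x, constant
y), so the entire analysis pipeline applies unchanged to simulated and
real trajectories alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .controller import DecisionState, SensoryNoise, control_action
from .kinematics import LocomotorParams, TrajectoryPair, differentiate

__all__ = [
    "SimConfig",
    "AgentState",
    "leader_step",
    "follower_step",
    "mode_switch",
    "simulate_pair",
    "simulate_mode_chain",
    "nonsocial_episode_lengths",
    "summary_stats",
    "ring_distance",
    "unroll_to_perimeter",
    "SimResult",
]


@dataclass
class SimConfig:
    """Study conditions for the pair simulation.

    Defaults reproduce 30-minute recordings at 30 fps: a 140 cm ring
    (perimeter of a 35 x 35 cm tank), non-social occupancy 0.2 with 15 s
    mean episodes, and leadership alternating on a 60 s mean timescale.
    The non-social oscillator swings between ~4 and ~22 cm/s with highly
    variable glide troughs (deep jitter on the lower threshold) and a
    consistent burst ceiling; the follower's perceived distance carries a
    slowly drifting estimation error (6 cm s.d., 1 s correlation).  These
    stand-in parameters are calibrated against the summary statistics the
    closed loop should reproduce: per-fish mean +/- s.d. of speed near
    13.5 +/- 5.8 and 12 +/- 6.5 cm/s, median inter-fish distance near
    4.6 cm, and forcemap peak amplitude near 25 cm/s^2
    (scripts/calibrate_leader.py re-derives them).
    """

    duration: float = 1800.0  # s
    dt: float = 1.0 / 30.0  # s
    track_length: float = 140.0  # cm, ring circumference
    p_nonsocial: float = 0.2
    mean_nonsocial_s: float = 15.0
    v_low: float = 4.0  # cm/s, leader oscillator lower threshold
    v_high: float = 22.0  # cm/s, upper threshold
    jitter_low: float = 0.4  # multiplicative jitter on v_low, redrawn each switch
    jitter_high: float = 0.1  # multiplicative jitter on v_high
    locomotor: LocomotorParams = field(default_factory=LocomotorParams)
    sigma_d: float = 6.0  # cm, s.d. of the perceived-distance error
    noise_tau_s: float = 1.0  # s, correlation time of the error (0 = white)
    latency_s: float = 0.0  # s, follower sensorimotor reaction latency
    role_switch_mean_s: Optional[float] = 60.0  # None = fixed roles
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nonsocial < 1.0:
            raise ValueError("p_nonsocial must be in [0, 1)")
        if not self.v_low < self.v_high <= self.locomotor.v_max:
            raise ValueError("need v_low < v_high <= v_max")
        if self.dt <= 0 or self.duration <= 0 or self.track_length <= 0:
            raise ValueError("dt, duration and track_length must be positive")
        if self.mean_nonsocial_s <= 0:
            raise ValueError("mean_nonsocial_s must be positive")


@dataclass
class AgentState:
    """Mutable per-agent state: ring position, speed, behavioural mode.

    ``phase`` is the burst-glide oscillator phase used whenever the agent
    moves non-socially; ``v_lo``/``v_hi`` are the current (jittered)
    switching thresholds.
    """

    pos: float  # unwrapped arclength, cm
    speed: float  # cm/s
    mode: str = "social"  # "social" | "nonsocial"
    phase: str = "glide"  # "burst" | "glide"
    v_lo: float = 7.0
    v_hi: float = 20.0


def ring_distance(x_from: float, x_to: float, circumference: float) -> float:
    """Signed shortest arc from ``x_from`` to ``x_to``, in [-C/2, C/2)."""
    half = circumference / 2.0
    return (x_to - x_from + half) % circumference - half


def _redraw_thresholds(state: AgentState, config: SimConfig, rng: np.random.Generator) -> None:
    jl, jh = config.jitter_low, config.jitter_high
    state.v_lo = config.v_low * (1.0 + jl * (2.0 * rng.random() - 1.0)) if jl > 0 else config.v_low
    state.v_hi = config.v_high * (1.0 + jh * (2.0 * rng.random() - 1.0)) if jh > 0 else config.v_high
    # a jittered upper threshold at/above v_max would never be crossed
    state.v_hi = min(state.v_hi, 0.98 * config.locomotor.v_max)


def _oscillator_acceleration(state: AgentState, params: LocomotorParams) -> float:
    if state.phase == "burst":
        return params.burst_acceleration(state.speed)
    return -params.alpha * state.speed


def _advance(state: AgentState, accel: float, params: LocomotorParams, dt: float) -> None:
    """One Euler step: position with the pre-step speed, then clipped speed."""
    state.pos += state.speed * dt
    state.speed = min(max(state.speed + accel * dt, 0.0), params.v_max)


def leader_step(
    state: AgentState,
    params: LocomotorParams,
    config: SimConfig,
    dt: float,
    rng: np.random.Generator,
) -> AgentState:
    """Non-social burst-glide oscillator step (state mutated and returned).

    Glide until speed drops below the lower threshold, burst until it
    exceeds the upper one; thresholds are re-jittered at every switch so
    the leader is not perfectly periodic.
    """
    accel = _oscillator_acceleration(state, params)
    _advance(state, accel, params, dt)
    if state.phase == "glide" and state.speed < state.v_lo:
        state.phase = "burst"
        _redraw_thresholds(state, config, rng)
    elif state.phase == "burst" and state.speed > state.v_hi:
        state.phase = "glide"
        _redraw_thresholds(state, config, rng)
    return state


def follower_step(
    state: AgentState,
    leader_state: AgentState,
    params: LocomotorParams,
    config: SimConfig,
    noise: SensoryNoise,
    dt: float,
    rng: np.random.Generator,
) -> AgentState:
    """One follower step: bang-bang control when social, oscillator otherwise."""
    if state.mode == "social":
        d = ring_distance(state.pos, leader_state.pos, config.track_length)
        action = control_action(
            DecisionState(state.speed, leader_state.speed, d), params, noise
        )
        state.phase = action.mode  # keep the oscillator phase continuous
        _advance(state, action.acceleration, params, dt)
        return state
    return leader_step(state, params, config, dt, rng)


def mode_switch(
    mode: str, config: SimConfig, dt: float, rng: np.random.Generator
) -> str:
    """Discretised two-state Markov chain for social/non-social behaviour.

    Exit rate from the non-social state is 1/mean_nonsocial_s; the exit
    rate from social is scaled by p/(1-p) so the stationary non-social
    occupancy equals ``p_nonsocial``.
    """
    rate_exit_ns = 1.0 / config.mean_nonsocial_s
    if mode == "nonsocial":
        return "social" if rng.random() < rate_exit_ns * dt else "nonsocial"
    p = config.p_nonsocial
    rate_exit_s = rate_exit_ns * p / (1.0 - p)
    return "nonsocial" if rng.random() < rate_exit_s * dt else "social"


@dataclass
class SimResult:
    """Full simulation record: trajectory plus per-frame internals."""

    trajectory: TrajectoryPair
    speeds: np.ndarray  # (n, 2)
    nonsocial: np.ndarray  # (n,) bool — follower-of-the-moment non-social
    leader: np.ndarray  # (n,) int — index of the current leader
    signed_distance: np.ndarray  # (n,) follower -> leader ring arc, cm
    config: SimConfig


def simulate_pair(config: SimConfig, full_output: bool = False):
    """Simulate a leader-follower pair; reproducible from ``config.seed``.

    Returns a :class:`TrajectoryPair` with unwrapped ring arclength as the
    x coordinate and a constant y coordinate (quasi-1-D dialect), or a
    :class:`SimResult` when ``full_output`` is requested.
    """
    rng = np.random.default_rng(config.seed)
    params = config.locomotor
    dt = config.dt
    n = int(round(config.duration / dt))
    noise = SensoryNoise(config.sigma_d, rng, tau_s=config.noise_tau_s, dt=dt)
    lag = int(round(config.latency_s / dt))  # follower reacts to a stale percept

    agents = []
    for start_pos in (5.0, 0.0):
        st = AgentState(
            pos=start_pos,
            speed=config.v_low + rng.random() * (config.v_high - config.v_low),
            mode="social",
            phase="glide",
        )
        _redraw_thresholds(st, config, rng)
        agents.append(st)
    leader_idx = 0

    # pre-draw leadership switch times
    switch_steps: list[int] = []
    if config.role_switch_mean_s is not None:
        t = 0.0
        while True:
            t += rng.exponential(config.role_switch_mean_s)
            if t >= config.duration:
                break
            switch_steps.append(int(t / dt))
    switch_ptr = 0

    positions = np.zeros((n, 2, 2))
    speeds = np.empty((n, 2))
    nonsocial = np.empty(n, dtype=bool)
    leader_rec = np.empty(n, dtype=np.int8)
    signed_d = np.empty(n)

    for i in range(n):
        while switch_ptr < len(switch_steps) and switch_steps[switch_ptr] == i:
            leader_idx = 1 - leader_idx
            switch_ptr += 1
        lead = agents[leader_idx]
        foll = agents[1 - leader_idx]
        foll.mode = mode_switch(foll.mode, config, dt, rng)

        positions[i, 0, 0] = agents[0].pos
        positions[i, 1, 0] = agents[1].pos
        speeds[i, 0] = agents[0].speed
        speeds[i, 1] = agents[1].speed
        nonsocial[i] = foll.mode == "nonsocial"
        leader_rec[i] = leader_idx
        signed_d[i] = ring_distance(foll.pos, lead.pos, config.track_length)

        if lag > 0:
            j = max(0, i - lag)
            perceived = AgentState(
                pos=positions[j, leader_idx, 0], speed=speeds[j, leader_idx]
            )
        else:
            perceived = lead
        leader_step(lead, params, config, dt, rng)
        follower_step(foll, perceived, params, config, noise, dt, rng)
        if not (math.isfinite(lead.pos) and math.isfinite(foll.pos)):
            raise FloatingPointError(f"non-finite agent state at frame {i}")

    traj = TrajectoryPair(
        times=np.arange(n) * dt, positions=positions, frame_rate=1.0 / dt
    )
    if not full_output:
        return traj
    return SimResult(traj, speeds, nonsocial, leader_rec, signed_d, config)


def simulate_mode_chain(
    duration: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run the social/non-social Markov chain alone; returns a non-social mask."""
    n = int(round(duration / config.dt))
    out = np.empty(n, dtype=bool)
    mode = "social"
    for i in range(n):
        mode = mode_switch(mode, config, config.dt, rng)
        out[i] = mode == "nonsocial"
    return out


def nonsocial_episode_lengths(mask: np.ndarray, dt: float) -> np.ndarray:
    """Durations (s) of completed non-social episodes in a boolean mask.

    Episodes touching either end of the series are censored and excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = (ends - starts) * dt
    keep = np.ones(lengths.size, dtype=bool)
    if lengths.size and mask[0]:
        keep[0] = False
    if lengths.size and mask[-1]:
        keep[-1] = False
    return lengths[keep]


def summary_stats(traj: TrajectoryPair) -> dict:
    """Per-fish speed statistics and median inter-fish distance.

    Speeds come from the same backward-difference kinematics applied to
    experimental data, scaled to cm/s; the distance is the per-frame
    Euclidean distance between the two position records.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    kin = differentiate(traj, scale="per_second")
    dist = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=-1)
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return {
        "mean_speed": tuple(float(m) for m in kin.speed.mean(axis=0)),
        "std_speed": tuple(float(s) for s in kin.speed.std(axis=0)),
        "median_distance": float(np.median(dist)),
        "speed_quantiles": {
            q: tuple(float(v) for v in np.quantile(kin.speed, q, axis=0)) for q in qs
        },
    }


def unroll_to_perimeter(traj: TrajectoryPair, side: float = 35.0) -> TrajectoryPair:
    """Map unwrapped ring arclength onto the perimeter of a square tank.

    Produces genuinely 2-D wall-following coordinates (with corner turns)
    from the quasi-1-D simulator output, for file interchange with tools
    expecting tank coordinates.
    """
    perim = 4.0 * side
    s = traj.positions[..., 0] % perim  # (n, 2)
    x = np.empty_like(s)
    y = np.empty_like(s)
    for k, lo in enumerate((0.0, side, 2 * side, 3 * side)):
        m = (s >= lo) & (s < lo + side)
        u = s[m] - lo
        if k == 0:
            x[m], y[m] = u, 0.0
        elif k == 1:
            x[m], y[m] = side, u
        elif k == 2:
            x[m], y[m] = side - u, side
        else:
            x[m], y[m] = 0.0, side - u
    positions = np.stack([x, y], axis=-1)
    return TrajectoryPair(traj.times.copy(), positions, traj.frame_rate)
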