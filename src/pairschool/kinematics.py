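"""Trajectory kinematics for burst-and-glide swimmers.

Raw tracker output is a per-frame position table for a pair of fish.  This
module turns it into smoothed velocity/acceleration series, segments the
saw-tooth speed profile into glide (decay) phases, and fits the drag model
that governs passive deceleration: ``dv/dt = -alpha * v`` (viscous) or
``dv/dt = -alpha_q * v**2`` (quadratic), with a single drag constant shared
across all glide segments of all fish.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "TrajectoryPair",
    "KinematicSeries",
    "DecaySegment",
    "LocomotorParams",
    "smooth_positions",
    "differentiate",
    "extract_decay_segments",
    "fit_shared_drag",
    "estimate_vmax",
    "DragFitResult",
]

DEFAULT_FRAME_RATE = 30.0  # Hz


@dataclass(frozen=True)
class LocomotorParams:
    """Locomotor constants defining burst-and-glide physics of one fish.

    Attributes
    ----------
    alpha : float
        Viscous drag constant in 1/s; glide deceleration is ``-alpha * v``.
    a_max : float
        Peak burst acceleration in cm/s^2, produced at stand-still.
    v_max : float
        Aerobic speed ceiling in cm/s; burst acceleration falls off linearly
        as ``a_max * (1 - v / v_max)`` and vanishes at the ceiling.
    """

    alpha: float = 2.7
    a_max: float = 60.0
    v_max: float = 30.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.a_max > 0 and self.v_max > 0):
            raise ValueError("alpha, a_max and v_max must all be strictly positive")

    def burst_acceleration(self, v: float) -> float:
        """Active acceleration available at speed ``v`` (>= 0, cm/s^2)."""
        return max(0.0, self.a_max * (1.0 - v / self.v_max))

    def glide_acceleration(self, v: float) -> float:
        """Passive drag deceleration at speed ``v`` (<= 0, cm/s^2)."""
        return -self.alpha * v


@dataclass
class TrajectoryPair:
    """Per-frame 2-D positions of exactly two agents on a uniform time grid.

    ``positions`` has shape ``(n_frames, 2, 2)``: frame x agent x (x, y), in
    centimetres.  Frame times must be strictly increasing and uniformly
    spaced; gaps are rejected at construction so every downstream finite
    difference is well defined.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        n = self.times.size
        if self.positions.shape != (n, 2, 2):
            raise ValueError(
                f"positions must have shape (n_frames, 2, 2); got {self.positions.shape}"
            )
        if n >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                bad = int(np.argmax(dts <= 0))
                raise ValueError(f"frame times not strictly increasing at frame {bad + 1}")
            dt = 1.0 / self.frame_rate
            if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9 * max(1.0, dt)):
                bad = int(np.argmax(~np.isclose(dts, dt, rtol=1e-6, atol=1e-9)))
                raise ValueError(
                    f"non-uniform frame spacing (gap?) at frame {bad + 1}: "
                    f"dt={dts[bad]:.6g}, expected {dt:.6g}"
                )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the on-disk dialect ``time,x1,y1,x2,y2``."""
        return pd.DataFrame(
            {
                "time": self.times,
                "x1": self.positions[:, 0, 0],
                "y1": self.positions[:, 0, 1],
                "x2": self.positions[:, 1, 0],
                "y2": self.positions[:, 1, 1],
            }
        )


@dataclass
class KinematicSeries:
    """Finite-difference velocity and acceleration for a TrajectoryPair.

    Velocity at frame i is the backward difference x(t_i) - x(t_{i-1})
    (defined for frames 1..n-1); acceleration at frame i is the forward
    difference of velocity v(t_{i+1}) - v(t_i) (frames 1..n-2).  ``scale``
    records whether values are per-frame displacements or have been scaled
    by the frame rate to cm/s and cm/s^2 — the caller chooses explicitly.
    """

    velocity: np.ndarray  # (n-1, 2 agents, 2 components)
    acceleration: np.ndarray  # (n-2, 2, 2)
    speed: np.ndarray  # (n-1, 2)
    frame_rate: float
    scale: Literal["per_frame", "per_second"]

    def __post_init__(self) -> None:
        if self.velocity.shape[0] != self.acceleration.shape[0] + 1:
            raise ValueError("acceleration must be one sample shorter than velocity")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")

    @property
    def v_x(self) -> np.ndarray:
        return self.velocity[..., 0]

    @property
    def v_y(self) -> np.ndarray:
        return self.velocity[..., 1]

    @property
    def a_x(self) -> np.ndarray:
        return self.acceleration[..., 0]

    @property
    def a_y(self) -> np.ndarray:
        return self.acceleration[..., 1]


@dataclass
class DecaySegment:
    """One glide phase: speed samples from a local maximum to the next minimum.

    ``amplitude`` is the value at the opening local maximum (the burst peak
    A_i); ``dt`` is the sampling interval so the fitter can reconstruct
    within-segment times without a back-reference to the trajectory.
    """

    start: int
    end: int  # inclusive index into the source speed series
    values: np.ndarray
    dt: float = 1.0 / DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("decay segment speeds must be non-negative")

    @property
    def amplitude(self) -> float:
        return float(self.values[0])

    @property
    def rel_times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def smooth_positions(traj: TrajectoryPair, window_ms: float = 170.0) -> TrajectoryPair:
    """Centred moving-average filter applied per coordinate.

    The window is specified as a duration; at 30 fps the 170 ms default is a
    5-frame window.  Edges use a shrink-to-valid window so the output keeps
    frame-for-frame alignment with the input.
    """
    window = int(round(window_ms / 1000.0 * traj.frame_rate))
    if window % 2 == 0:
        raise ValueError(
            f"window of {window_ms} ms is {window} frames at {traj.frame_rate} fps; "
            "an odd number of frames is required for a centred filter"
        )
    if window > traj.n_frames:
        raise ValueError("smoothing window longer than the trajectory")
    if window == 1:
        return replace(traj, positions=traj.positions.copy())
    flat = traj.positions.reshape(traj.n_frames, 4)
    smoothed = (
        pd.DataFrame(flat).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return replace(traj, positions=smoothed.reshape(traj.n_frames, 2, 2))


def differentiate(
    traj: TrajectoryPair, scale: Literal["per_frame", "per_second"] = "per_frame"
) -> KinematicSeries:
    """First differences for velocity, forward differences for acceleration.

    With ``scale="per_second"`` velocities are multiplied by the frame rate
    and accelerations by its square, giving cm/s and cm/s^2.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate twice")
    vel = np.diff(traj.positions, axis=0)
    acc = np.diff(vel, axis=0)
    if scale == "per_second":
        vel = vel * traj.frame_rate
        acc = acc * traj.frame_rate**2
    elif scale != "per_frame":
        raise ValueError(f"unknown scale {scale!r}")
    speed = np.linalg.norm(vel, axis=-1)
    return KinematicSeries(
        velocity=vel,
        acceleration=acc,
        speed=speed,
        frame_rate=traj.frame_rate,
        scale=scale,
    )


def _extrema_signs(speed: np.ndarray) -> np.ndarray:
    """Backward-filled sign of the first difference.

    Plateaus inherit the sign of the following move, so a local extremum on a
    plateau is attributed to the plateau's first index (deterministic
    tie-break).
    """
    d = np.sign(np.diff(speed))
    out = d.copy()
    # backward fill zeros with the next non-zero sign
    nxt = 0.0
    for i in range(out.size - 1, -1, -1):
        if out[i] == 0.0:
            out[i] = nxt
        else:
            nxt = out[i]
    return out


def extract_decay_segments(
    speed: Sequence[float] | np.ndarray,
    min_length: int = 3,
    dt: float = 1.0 / DEFAULT_FRAME_RATE,
) -> list[DecaySegment]:
    """Segment a speed series into descending (glide) phases.

    Each maximal run from a local speed maximum down to the following local
    minimum becomes one segment; a decreasing run into the end of the series
    terminates there.  Segments shorter than ``min_length`` samples are
    treated as noise and discarded.  A monotone series yields no segments.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.ndim != 1:
        raise ValueError("speed must be a one-dimensional series")
    if speed.size < 2:
        return []
    s = _extrema_signs(speed)
    segments: list[DecaySegment] = []
    n = speed.size
    maxima = [i for i in range(1, s.size) if s[i - 1] > 0 and s[i] < 0]
    for m in maxima:
        # walk forward to the next local minimum (or series end on a decay tail)
        end = n - 1
        for j in range(m + 1, s.size):
            if s[j - 1] < 0 and s[j] > 0:
                end = j
                break
        if end - m + 1 >= min_length:
            segments.append(DecaySegment(start=m, end=end, values=speed[m : end + 1], dt=dt))
    return segments


class DragFitResult(NamedTuple):
    alpha: float
    fraction_explained: float
    model: str
    n_segments: int


def _predict_decay(model: str, amplitude: float, alpha: float, t: np.ndarray) -> np.ndarray:
    if model == "viscous":
        return amplitude * np.exp(-alpha * t)
    if model == "quadratic":
        return amplitude / (1.0 + amplitude * alpha * t)
    raise ValueError(f"unknown drag model {model!r}")


def fit_shared_drag(
    segments: Sequence[DecaySegment],
    model: Literal["viscous", "quadratic"] = "viscous",
    bracket: tuple[float, float] = (0.01, 50.0),
) -> DragFitResult:
    """Fit one drag constant jointly to all glide segments.

    The per-segment amplitude A_i is pinned to the observed peak speed; the
    only free parameter is the shared decay constant, chosen to minimise the
    total absolute deviation between predicted and observed speeds across
    all segments (scalar bounded minimisation).  The returned
    ``fraction_explained`` is the fraction of explained linear variation f
    of the fitted curves, with per-segment median speeds as the reference
    predictor.
    """
    if len(segments) == 0:
        raise ValueError("need at least one decay segment")
    if all(seg.amplitude == 0 for seg in segments):
        raise ValueError("all segments have zero amplitude; nothing to fit")

    times = [seg.rel_times for seg in segments]
    obs = [seg.values for seg in segments]

    def objective(alpha: float) -> float:
        return sum(
            float(np.abs(_predict_decay(model, o[0], alpha, t) - o).sum())
            for t, o in zip(times, obs)
        )

    res = minimize_scalar(
        objective, bounds=bracket, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(
            f"shared-drag fit did not converge on bracket {bracket}: {res.message}"
        )
    alpha_hat = float(res.x)
    # fraction of explained linear variation, deferred import to avoid a cycle
    from .predictability import explained_linear_variation

    preds = [_predict_decay(model, o[0], alpha_hat, t) for t, o in zip(times, obs)]
    decomp = explained_linear_variation(preds, obs)
    return DragFitResult(alpha_hat, decomp.f, model, len(segments))


def estimate_vmax(speed: Sequence[float] | np.ndarray, quantile: float = 0.95) -> float:
    """Empirical speed ceiling: the given quantile of observed speeds."""
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed series")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(speed, quantile))
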