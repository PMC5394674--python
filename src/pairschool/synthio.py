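"""Synthetic data generation and trajectory file I/O.

A single file dialect (``time,x1,y1,x2,y2``; seconds and centimetres, one
row per frame) serves both "experimental-style" and simulated data, so
every pipeline stage can be exercised end-to-end without any recordings.
Fixture factories emit data with known ground truth — drag constants,
imposed lags, noise scales — stored in a metadata sidecar so recovery
tests read the truth from metadata rather than hard-coding it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kinematics import DEFAULT_FRAME_RATE, DecaySegment, TrajectoryPair
from .simulator import SimConfig, simulate_pair

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "make_decay_fixtures",
    "make_ring_pair",
    "make_independent_walkers",
    "make_shifted_pair",
    "add_observation_noise",
    "write_fixture",
]

_COLUMNS = ["time", "x1", "y1", "x2", "y2"]


def write_trajectory(path, traj: TrajectoryPair) -> None:
    """Write the delimited trajectory table (round-trip lossless to 1e-9)."""
    traj.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> TrajectoryPair:
    """Read a trajectory table, rejecting malformed rows with line numbers.

    Validates column names, numeric content, and the uniform-time-grid
    invariant (gaps and non-monotone times are rejected).
    """
    df = pd.read_csv(path)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric values on line(s) {lines}")
    times = df["time"].to_numpy(float)
    dts = np.diff(times)
    if times.size >= 2:
        dt = np.median(dts)
        off = ~np.isclose(dts, dt, rtol=1e-6, atol=1e-9)
        if off.any():
            line = int(np.argmax(off)) + 3
            raise ValueError(
                f"{path}: time gap or irregular spacing at line {line} "
                f"(dt={dts[np.argmax(off)]:.6g}, expected {dt:.6g})"
            )
        frame_rate = 1.0 / dt
    else:
        frame_rate = DEFAULT_FRAME_RATE
    positions = np.stack(
        [
            df[["x1", "y1"]].to_numpy(float),
            df[["x2", "y2"]].to_numpy(float),
        ],
        axis=1,
    )
    return TrajectoryPair(times=times, positions=positions, frame_rate=frame_rate)


def make_decay_fixtures(
    n: int = 200,
    alpha: float = 2.7,
    amp_range: tuple[float, float] = (5.0, 30.0),
    noise: float = 0.05,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
    model: str = "viscous",
) -> tuple[list[DecaySegment], dict]:
    """Glide segments with known drag constant, for fit-recovery tests.

    Amplitudes are uniform on ``amp_range`` (cm/s), sampled at 30 Hz for a
    uniform random duration, with multiplicative Gaussian observation
    noise of relative scale ``noise``.  Returns (segments, ground_truth).
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    segments = []
    for _ in range(n):
        amp = rng.uniform(*amp_range)
        dur = rng.uniform(*duration_range)
        t = np.arange(0.0, dur, dt)
        if t.size < 3:
            t = np.arange(3) * dt
        if model == "viscous":
            v = amp * np.exp(-alpha * t)
        elif model == "quadratic":
            v = amp / (1.0 + amp * alpha * t)
        else:
            raise ValueError(f"unknown model {model!r}")
        if noise > 0:
            v = v * (1.0 + noise * rng.standard_normal(t.size))
        v = np.clip(v, 0.0, None)
        segments.append(DecaySegment(start=0, end=t.size - 1, values=v, dt=dt))
    truth = {
        "kind": "decay_segments",
        "alpha": alpha,
        "model": model,
        "noise": noise,
        "amp_range": list(amp_range),
        "n": n,
        "seed": seed,
    }
    return segments, truth


def make_ring_pair(seed: int = 0, **overrides) -> tuple[TrajectoryPair, dict]:
    """Closed-loop simulated pair with its generating config as ground truth."""
    config = SimConfig(seed=seed, **overrides)
    traj = simulate_pair(config)
    truth = {"kind": "ring_pair", **_config_dict(config)}
    return traj, truth


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["locomotor"] = asdict(config.locomotor)
    return d


def _ou_walk(n: int, dt: float, rng: np.random.Generator, tau: float = 1.0,
             sigma_v: float = 8.0, start: np.ndarray | None = None,
             box: float | None = 35.0) -> np.ndarray:
    """Smooth 2-D random walk (Ornstein-Uhlenbeck velocity), positions in cm.

    With ``box`` set, the walk reflects off the walls of a square arena of
    that side length (tank-like bounded fixture); ``box=None`` is free.
    """
    v = np.zeros((n, 2))
    for i in range(1, n):
        v[i] = v[i - 1] * (1 - dt / tau) + sigma_v * np.sqrt(2 * dt / tau) * rng.standard_normal(2)
    pos = np.empty((n, 2))
    pos[0] = start if start is not None else np.zeros(2)
    for i in range(1, n):
        p = pos[i - 1] + v[i] * dt
        if box is not None:
            for c in range(2):
                if p[c] < 0:
                    p[c] = -p[c]
                    v[i:, c] *= -1.0
                elif p[c] > box:
                    p[c] = 2 * box - p[c]
                    v[i:, c] *= -1.0
        pos[i] = p
    return pos


def make_independent_walkers(
    n: int = 9000, seed: int = 0, frame_rate: float = DEFAULT_FRAME_RATE
) -> tuple[TrajectoryPair, dict]:
    """Two independent smooth random walkers (no social coupling at all)."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    p1 = _ou_walk(n, dt, rng, start=np.array([10.0, 10.0]))
    p2 = _ou_walk(n, dt, rng, start=np.array([25.0, 25.0]))
    traj = TrajectoryPair(
        times=np.arange(n) * dt,
        positions=np.stack([p1, p2], axis=1),
        frame_rate=frame_rate,
    )
    return traj, {"kind": "independent_walkers", "n": n, "seed": seed}


def make_shifted_pair(
    lag_frames: int = 10,
    n: int = 3000,
    seed: int = 0,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> tuple[TrajectoryPair, dict]:
    """Fish 2 replays fish 1 delayed by a known number of frames."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    p1 = _ou_walk(n + lag_frames, dt, rng)
    traj = TrajectoryPair(
        times=np.arange(n) * dt,
        positions=np.stack([p1[lag_frames:], p1[:n]], axis=1),
        frame_rate=frame_rate,
    )
    return traj, {"kind": "shifted_pair", "lag_frames": lag_frames, "n": n, "seed": seed}


def add_observation_noise(
    traj: TrajectoryPair,
    sigma_pos: float,
    rng: Optional[np.random.Generator] = None,
) -> TrajectoryPair:
    """i.i.d. Gaussian jitter on positions (tracking noise); times untouched."""
    if sigma_pos < 0:
        raise ValueError("sigma_pos must be non-negative")
    if sigma_pos == 0:
        return TrajectoryPair(traj.times.copy(), traj.positions.copy(), traj.frame_rate)
    if rng is None:
        rng = np.random.default_rng()
    jitter = sigma_pos * rng.standard_normal(traj.positions.shape)
    return TrajectoryPair(traj.times.copy(), traj.positions + jitter, traj.frame_rate)


def write_fixture(outdir, name: str, traj: TrajectoryPair, truth: dict) -> tuple[Path, Path]:
    """Write a trajectory fixture plus its ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_path = outdir / f"{name}.csv"
    meta_path = outdir / f"{name}.json"
    write_trajectory(data_path, traj)
    meta_path.write_text(json.dumps(truth, indent=2))
    return data_path, meta_path
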