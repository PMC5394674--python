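"""Social forcemaps: binned focal acceleration in the focal frame.

The empirical picture of a social interaction rule is the mean of the focal
fish's acceleration component parallel to its own velocity, binned over the
partner's relative position (projected on the focal heading) and the
partner's projected speed, stratified into three focal-speed groups.
Samples are first restricted to quasi-one-dimensional episodes (headings
within 45 degrees, small perpendicular separation), and amplitudes are
corrected for chance-level co-occurrence by the temporal-shuffle factor
1/(1 - k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .kinematics import TrajectoryPair, differentiate

__all__ = [
    "Forcemap",
    "project_to_focal_frame",
    "project_both",
    "filter_quasi_1d",
    "bin_forcemap",
    "estimate_chance_fraction",
    "shuffle_correction",
    "distance_profile",
    "quadrant_analysis",
    "peak_force",
    "DEFAULT_D_EDGES",
    "DEFAULT_VP_EDGES",
    "DEFAULT_VF_EDGES",
]

# Axis ranges follow the published map extents: distances +/-20 cm, partner
# projected speed 0-32.5 cm/s, focal-speed groups 0-10.5, 10.5-21, 21-32.5.
DEFAULT_D_EDGES = np.linspace(-20.0, 20.0, 11)
DEFAULT_VP_EDGES = np.linspace(0.0, 32.5, 7)
DEFAULT_VF_EDGES = np.array([0.0, 10.5, 21.0, 32.5])

SAMPLE_COLUMNS = [
    "frame",
    "focal",
    "d_par",
    "d_perp",
    "v_p_proj",
    "v_f",
    "a_par",
    "heading_diff",
]


def project_to_focal_frame(traj: TrajectoryPair, focal: int) -> pd.DataFrame:
    """One sample per usable frame, expressed in the focal fish's frame.

    For each frame where the focal fish has a defined heading (speed > 0),
    the partner's relative position and velocity are projected onto the
    focal velocity direction, and the focal acceleration component parallel
    to it is recorded.  Velocities and accelerations are scaled to cm/s and
    cm/s^2.  Frames with zero focal speed are skipped.
    """
    if focal not in (0, 1):
        raise ValueError("focal must be 0 or 1")
    partner = 1 - focal
    kin = differentiate(traj, scale="per_second")
    n_acc = kin.acceleration.shape[0]
    # velocity index i covers frames 1..n-1; acceleration 1..n-2: use 0..n_acc-1
    v_f_vec = kin.velocity[:n_acc, focal]  # (m, 2)
    v_p_vec = kin.velocity[:n_acc, partner]
    a_f_vec = kin.acceleration[:, focal]
    frames = np.arange(1, n_acc + 1)
    pos = traj.positions[frames]
    rel = pos[:, partner] - pos[:, focal]

    speed_f = np.linalg.norm(v_f_vec, axis=-1)
    usable = speed_f > 0
    u = np.zeros_like(v_f_vec)
    u[usable] = v_f_vec[usable] / speed_f[usable, None]
    perp = np.stack([-u[:, 1], u[:, 0]], axis=-1)

    d_par = np.einsum("ij,ij->i", rel, u)
    d_perp = np.einsum("ij,ij->i", rel, perp)
    v_p_proj = np.einsum("ij,ij->i", v_p_vec, u)
    a_par = np.einsum("ij,ij->i", a_f_vec, u)

    speed_p = np.linalg.norm(v_p_vec, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(
            speed_p > 0, v_p_proj / np.where(speed_p > 0, speed_p, 1.0), np.nan
        )
    heading_diff = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    df = pd.DataFrame(
        {
            "frame": frames,
            "focal": focal,
            "d_par": d_par,
            "d_perp": d_perp,
            "v_p_proj": v_p_proj,
            "v_f": speed_f,
            "a_par": a_par,
            "heading_diff": heading_diff,
        }
    )
    return df.loc[usable].reset_index(drop=True)


def project_both(traj: TrajectoryPair) -> pd.DataFrame:
    """Pooled samples with each fish serving as focal in turn."""
    return pd.concat(
        [project_to_focal_frame(traj, 0), project_to_focal_frame(traj, 1)],
        ignore_index=True,
    )


def filter_quasi_1d(
    samples: pd.DataFrame,
    max_heading_deg: float = 45.0,
    max_perp: float = 7.0,
    max_par: float = 20.0,
) -> pd.DataFrame:
    """Keep near-parallel, nearby samples (the quasi-1-D episodes).

    A sample survives iff the heading difference is below 45 degrees, the
    perpendicular separation below 7 cm and the parallel separation below
    20 cm in magnitude.  The retained fraction is stored in
    ``result.attrs["retained_fraction"]``.
    """
    keep = (
        (samples["heading_diff"] < max_heading_deg)
        & (samples["d_perp"].abs() < max_perp)
        & (samples["d_par"].abs() < max_par)
    )
    out = samples.loc[keep.fillna(False)].reset_index(drop=True)
    out.attrs["retained_fraction"] = float(keep.sum() / len(samples)) if len(samples) else 0.0
    return out


@dataclass
class Forcemap:
    """Occupancy and summed parallel acceleration over (vf-group, d, vp) bins.

    The mean-force grid is summed force / occupancy where occupancy is
    positive, masked elsewhere, and scaled by the shuffle-correction factor
    1/(1 - k); ``k = 0`` leaves values untouched.  Corrections touch values
    only, never occupancies.
    """

    d_edges: np.ndarray
    vp_edges: np.ndarray
    vf_edges: np.ndarray
    occupancy: np.ndarray  # (n_vf, n_d, n_vp) int
    force_sum: np.ndarray
    force_sumsq: np.ndarray
    k: float = 0.0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.k < 1.0:
            raise ValueError("shuffle fraction k must be in [0, 1)")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy must be non-negative")

    @property
    def correction(self) -> float:
        return 1.0 / (1.0 - self.k)

    @property
    def mean_force(self) -> np.ma.MaskedArray:
        occ = self.occupancy
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(occ > 0, self.force_sum / np.maximum(occ, 1), np.nan)
        return np.ma.masked_invalid(raw * self.correction)

    @property
    def sem(self) -> np.ma.MaskedArray:
        occ = self.occupancy
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.force_sum / np.maximum(occ, 1)
            var = self.force_sumsq / np.maximum(occ, 1) - mean**2
            var = np.clip(var, 0.0, None)
            s = np.where(occ > 0, np.sqrt(var / np.maximum(occ, 1)), np.nan)
        return np.ma.masked_invalid(s * self.correction)

    @property
    def total_occupancy(self) -> int:
        return int(self.occupancy.sum())

    def to_table(self) -> pd.DataFrame:
        """Tidy serialization: one row per bin."""
        rows = []
        for g in range(self.occupancy.shape[0]):
            for i in range(self.occupancy.shape[1]):
                for j in range(self.occupancy.shape[2]):
                    occ = int(self.occupancy[g, i, j])
                    mean = self.mean_force[g, i, j]
                    sem = self.sem[g, i, j]
                    rows.append(
                        {
                            "d_lo": self.d_edges[i],
                            "d_hi": self.d_edges[i + 1],
                            "vp_lo": self.vp_edges[j],
                            "vp_hi": self.vp_edges[j + 1],
                            "vf_group": g,
                            "occupancy": occ,
                            "mean_force": float(mean) if occ > 0 else np.nan,
                            "sem": float(sem) if occ > 0 else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


def bin_forcemap(
    samples: pd.DataFrame,
    d_edges: Optional[np.ndarray] = None,
    vp_edges: Optional[np.ndarray] = None,
    vf_edges: Optional[np.ndarray] = None,
) -> Forcemap:
    """Accumulate filtered samples into an occupancy/force grid.

    Bins are half-open [lo, hi).  Samples outside every bin (including
    negative projected partner speeds, which lie outside the published
    velocity range) are excluded and counted in ``n_excluded``.
    """
    d_edges = DEFAULT_D_EDGES if d_edges is None else np.asarray(d_edges, float)
    vp_edges = DEFAULT_VP_EDGES if vp_edges is None else np.asarray(vp_edges, float)
    vf_edges = DEFAULT_VF_EDGES if vf_edges is None else np.asarray(vf_edges, float)

    d = samples["d_par"].to_numpy()
    vp = samples["v_p_proj"].to_numpy()
    vf = samples["v_f"].to_numpy()
    a = samples["a_par"].to_numpy()

    di = np.digitize(d, d_edges) - 1
    vpi = np.digitize(vp, vp_edges) - 1
    vfi = np.digitize(vf, vf_edges) - 1
    ok = (
        (di >= 0)
        & (di < len(d_edges) - 1)
        & (vpi >= 0)
        & (vpi < len(vp_edges) - 1)
        & (vfi >= 0)
        & (vfi < len(vf_edges) - 1)
    )
    shape = (len(vf_edges) - 1, len(d_edges) - 1, len(vp_edges) - 1)
    occupancy = np.zeros(shape, dtype=np.int64)
    force_sum = np.zeros(shape)
    force_sumsq = np.zeros(shape)
    np.add.at(occupancy, (vfi[ok], di[ok], vpi[ok]), 1)
    np.add.at(force_sum, (vfi[ok], di[ok], vpi[ok]), a[ok])
    np.add.at(force_sumsq, (vfi[ok], di[ok], vpi[ok]), a[ok] ** 2)
    return Forcemap(
        d_edges=d_edges,
        vp_edges=vp_edges,
        vf_edges=vf_edges,
        occupancy=occupancy,
        force_sum=force_sum,
        force_sumsq=force_sumsq,
        n_excluded=int((~ok).sum()),
    )


def _rewrap_partner(
    positions: np.ndarray, partner: np.ndarray, wrap_length: Optional[float]
) -> np.ndarray:
    """Re-express a (rolled) partner series relative to fish 1 on a ring.

    Unwrapped ring coordinates grow without bound, so a plain temporal
    shift would place the decoupled partner arbitrarily far away.  With a
    known circumference the partner is mapped to the shortest signed arc
    from fish 1, preserving its local autostructure.
    """
    if wrap_length is None:
        return partner
    x1 = positions[:, 0]
    arc = (partner[:, 0] - x1 + wrap_length / 2.0) % wrap_length - wrap_length / 2.0
    out = partner.copy()
    out[:, 0] = x1 + arc
    return out


def _shuffled_occupancy(
    traj: TrajectoryPair,
    offset_frames: int,
    filter_kwargs: dict,
    edges: tuple,
    wrap_length: Optional[float],
) -> int:
    rolled = np.roll(traj.positions[:, 1], offset_frames, axis=0)
    rolled = _rewrap_partner(traj.positions[:, 0], rolled, wrap_length)
    shifted = TrajectoryPair(
        traj.times.copy(),
        np.stack([traj.positions[:, 0], rolled], axis=1),
        traj.frame_rate,
    )
    samples = filter_quasi_1d(project_both(shifted), **filter_kwargs)
    return bin_forcemap(samples, *edges).total_occupancy


def estimate_chance_fraction(
    fmap: Forcemap,
    traj: TrajectoryPair,
    n_shuffles: int = 10,
    rng: Optional[np.random.Generator] = None,
    min_shift_s: float = 60.0,
    method: str = "circular",
    wrap_length: Optional[float] = None,
    **filter_kwargs,
) -> float:
    """Chance-level co-occurrence fraction k from temporal shuffles.

    One fish's series is circularly shifted by a random large offset
    (preserving its autostructure) and the forcemap pipeline is re-run; k
    is the mean ratio of shuffled to observed total occupancy.  Frame
    permutation is available behind ``method="permute"``.  For trajectories
    in unwrapped ring coordinates pass the ring circumference as
    ``wrap_length`` so the decoupled partner stays on the track.
    """
    if rng is None:
        rng = np.random.default_rng()
    duration = traj.n_frames / traj.frame_rate
    if duration <= 2 * min_shift_s:
        raise ValueError("trajectory too short for the requested minimum shift")
    edges = (fmap.d_edges, fmap.vp_edges, fmap.vf_edges)
    total = fmap.total_occupancy
    if total == 0:
        raise ValueError("observed forcemap is empty")
    ks = []
    lo = int(min_shift_s * traj.frame_rate)
    hi = traj.n_frames - lo
    for _ in range(n_shuffles):
        if method == "circular":
            offset = int(rng.integers(lo, hi))
            shuffled_total = _shuffled_occupancy(
                traj, offset, filter_kwargs, edges, wrap_length
            )
        elif method == "permute":
            perm = rng.permutation(traj.n_frames)
            permuted = _rewrap_partner(
                traj.positions[:, 0], traj.positions[perm, 1], wrap_length
            )
            shuffled = TrajectoryPair(
                traj.times.copy(),
                np.stack([traj.positions[:, 0], permuted], axis=1),
                traj.frame_rate,
            )
            samples = filter_quasi_1d(project_both(shuffled), **filter_kwargs)
            shuffled_total = bin_forcemap(samples, *edges).total_occupancy
        else:
            raise ValueError(f"unknown shuffle method {method!r}")
        ks.append(shuffled_total / total)
    return float(np.mean(ks))


def shuffle_correction(
    fmap: Forcemap,
    traj: TrajectoryPair,
    n_shuffles: int = 10,
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> Forcemap:
    """Return a copy of the map with the 1/(1-k) amplitude correction set.

    Occupancies are untouched; only the derived mean-force values scale.
    ``k >= 1`` (shuffled occupancy at or above observed) indicates broken
    filters and raises.
    """
    k = estimate_chance_fraction(fmap, traj, n_shuffles=n_shuffles, rng=rng, **kwargs)
    if k >= 1.0:
        raise ValueError(
            f"shuffled occupancy fraction k={k:.3f} >= 1; filters admit chance-level "
            "co-occurrence at or above the observed rate"
        )
    return replace(fmap, k=k)


def distance_profile(fmap: Forcemap) -> pd.DataFrame:
    """1-D social force vs parallel distance (occupancy-weighted marginal).

    Marginalises over partner-speed bins and focal-speed groups; empty
    distance bins are masked (NaN), never reported as zero force.
    """
    occ = fmap.occupancy.sum(axis=(0, 2))
    fsum = fmap.force_sum.sum(axis=(0, 2))
    fsumsq = fmap.force_sumsq.sum(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(occ > 0, fsum / np.maximum(occ, 1), np.nan)
        var = np.clip(fsumsq / np.maximum(occ, 1) - mean**2, 0.0, None)
        sem = np.where(occ > 0, np.sqrt(var / np.maximum(occ, 1)), np.nan)
    return pd.DataFrame(
        {
            "d_lo": fmap.d_edges[:-1],
            "d_hi": fmap.d_edges[1:],
            "d_center": 0.5 * (fmap.d_edges[:-1] + fmap.d_edges[1:]),
            "occupancy": occ,
            "mean_force": mean * fmap.correction,
            "sem": sem * fmap.correction,
        }
    )


def quadrant_analysis(
    fmap: Forcemap, vp_split: Optional[float] = None
) -> pd.DataFrame:
    """Occupancy-weighted mean force per quadrant per focal-speed group.

    Quadrants partition the (d, v_P) plane: Q1 partner behind & slow, Q2
    ahead & slow, Q3 behind & fast, Q4 ahead & fast, with "fast" meaning a
    projected partner speed above the split (midpoint of the binned range
    by default).  Empty quadrants are masked.
    """
    if vp_split is None:
        vp_split = 0.5 * (fmap.vp_edges[0] + fmap.vp_edges[-1])
    d_centers = 0.5 * (fmap.d_edges[:-1] + fmap.d_edges[1:])
    vp_centers = 0.5 * (fmap.vp_edges[:-1] + fmap.vp_edges[1:])
    ahead = d_centers >= 0
    fast = vp_centers >= vp_split
    quadrants = {
        "Q1": (~ahead, ~fast),
        "Q2": (ahead, ~fast),
        "Q3": (~ahead, fast),
        "Q4": (ahead, fast),
    }
    n_groups = fmap.occupancy.shape[0]
    rows = []
    for name, (dmask, vmask) in quadrants.items():
        sel = np.outer(dmask, vmask)
        for g in range(n_groups):
            occ = fmap.occupancy[g][sel].sum()
            fsum = fmap.force_sum[g][sel].sum()
            rows.append(
                {
                    "quadrant": name,
                    "vf_group": g,
                    "occupancy": int(occ),
                    "mean_force": (fsum / occ * fmap.correction) if occ > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def peak_force(fmap: Forcemap, min_occupancy: int = 20,
               side: str = "abs") -> float:
    """Peak mean-force amplitude over bins with sufficient occupancy (cm/s^2).

    ``side="abs"`` takes the maximum of |mean force| over qualifying bins;
    ``side="positive"`` restricts to the acceleration zones (the amplitude
    a burst-and-glide rule dilutes down from its burst maximum), which is
    the more robust summary because the deceleration extreme sits in
    sparsely occupied bins.
    """
    mask = fmap.occupancy >= min_occupancy
    if not mask.any():
        raise ValueError(f"no bin reaches occupancy {min_occupancy}")
    values = fmap.mean_force.filled(0.0)[mask]
    if side == "abs":
        return float(np.abs(values).max())
    if side == "positive":
        return float(values.max())
    raise ValueError(f"unknown side {side!r}")
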