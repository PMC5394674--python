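"""Predictability measures for pair kinematics.

The common currency is the fraction of explained linear variation

    f = (T - U) / T,

where U is the summed absolute prediction error and T the summed absolute
deviation of the observations from their per-episode medians.  It is used
both to score the drag fits on glide waveforms and to compare how well a
fish's next acceleration is predicted by (a) its own current acceleration
(ordinary linear regression — the non-social locomotor cycle) versus (b)
the full social state (a one-hidden-layer neural-network regressor on the
positions and velocities of both fish).  A lagged velocity
cross-correlation provides the leadership signature.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .kinematics import TrajectoryPair, differentiate

__all__ = [
    "VariationDecomposition",
    "explained_linear_variation",
    "autoregressive_predictability",
    "social_predictability",
    "SocialPredictabilityResult",
    "velocity_cross_correlation",
    "CrossCorrelation",
]


class VariationDecomposition(NamedTuple):
    """U: unexplained, T_total: total linear variation, f = (T-U)/T."""

    U: float
    T_total: float
    f: float


def _as_episodes(x) -> list[np.ndarray]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return [x.astype(float)]
    return [np.asarray(e, dtype=float) for e in x]


def explained_linear_variation(pred, obs) -> VariationDecomposition:
    """Fraction of explained linear variation over one or more episodes.

    ``pred`` and ``obs`` are aligned 1-D arrays or sequences of per-episode
    arrays; the reference predictor for T is each episode's median
    observation.  Constant observations (T = 0) leave f undefined and
    raise.
    """
    preds, obss = _as_episodes(pred), _as_episodes(obs)
    if len(preds) != len(obss):
        raise ValueError("pred and obs must contain the same number of episodes")
    U = 0.0
    T = 0.0
    for p, o in zip(preds, obss):
        if p.shape != o.shape:
            raise ValueError("each episode's prediction must align with its observation")
        U += float(np.abs(p - o).sum())
        T += float(np.abs(o - np.median(o)).sum())
    if T == 0.0:
        raise ValueError("total linear variation is zero (constant observations); f undefined")
    return VariationDecomposition(U, T, (T - U) / T)


def autoregressive_predictability(acceleration: np.ndarray, min_samples: int = 10) -> float:
    """f for predicting a(t+1) from a(t) by ordinary linear regression.

    ``acceleration`` is (n,) or (n, c); components are fitted and scored
    separately (one episode each, global median reference) and pooled into
    a single f.
    """
    a = np.asarray(acceleration, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    preds, obss = [], []
    for c in range(a.shape[1]):
        x, y = a[:-1, c], a[1:, c]
        if x.std() == 0.0:
            continue  # a constant component carries no linear variation
        beta1, beta0 = np.polyfit(x, y, 1)
        preds.append(beta0 + beta1 * x)
        obss.append(y)
    if not preds:
        raise ValueError("all acceleration components are constant")
    return explained_linear_variation(preds, obss).f


class SocialPredictabilityResult(NamedTuple):
    f_test: float
    f_val: float
    f_train: float
    n_train: int
    n_test: int


def _social_design(traj: TrajectoryPair, focal: int) -> tuple[np.ndarray, np.ndarray]:
    """Eight inputs at t (positions + velocities of both fish, cm & cm/s)
    and the focal acceleration components at t+1."""
    kin = differentiate(traj, scale="per_second")
    partner = 1 - focal
    n_acc = kin.acceleration.shape[0]
    # velocity index j <-> frame j+1; acceleration index j <-> frame j+1.
    # Inputs at frame j+1 predict acceleration at frame j+2 (index j+1).
    m = n_acc - 1
    frames = np.arange(1, m + 1)
    X = np.column_stack(
        [
            traj.positions[frames, focal, 0],
            traj.positions[frames, focal, 1],
            traj.positions[frames, partner, 0],
            traj.positions[frames, partner, 1],
            kin.velocity[:m, focal, 0],
            kin.velocity[:m, focal, 1],
            kin.velocity[:m, partner, 0],
            kin.velocity[:m, partner, 1],
        ]
    )
    y = kin.acceleration[1 : m + 1, focal, :]
    return X, y


def social_predictability(
    traj_or_xy,
    focal: int = 0,
    hidden_units: int = 40,
    seed: int = 0,
    max_iter_grid: Sequence[int] = (100, 500),
) -> SocialPredictabilityResult:
    """f of a one-hidden-layer network predicting acceleration from social state.

    Inputs are the x/y positions and velocity components of both fish at
    time t (8 units), standardized to zero mean and unit variance on the
    training split; outputs are the focal acceleration components at t+1.
    Data are split at random into 70% training, 15% validation and 15%
    test; the validation split selects the optimisation budget and f is
    reported on the held-out test split.
    """
    if isinstance(traj_or_xy, TrajectoryPair):
        X, y = _social_design(traj_or_xy, focal)
    else:
        X, y = traj_or_xy
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
    col_sd = X.std(axis=0)
    if np.all(col_sd == 0):
        raise ValueError("degenerate (constant) inputs; cannot standardize")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_train = int(0.70 * n)
    n_val = int(0.15 * n)
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :]

    mu, sd = X[idx_train].mean(axis=0), X[idx_train].std(axis=0)
    # constant columns (e.g. the unused coordinate of quasi-1-D data) carry
    # no information: centre them and leave them at zero
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)

    def score(model, idx) -> float:
        p = model.predict(Z[idx])
        if p.ndim == 1:
            p = p[:, None]
        return explained_linear_variation(list(p.T), list(y[idx].T)).f

    best = None
    for max_iter in max_iter_grid:
        model = MLPRegressor(
            hidden_layer_sizes=(hidden_units,),
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
        model.fit(Z[idx_train], y[idx_train] if y.shape[1] > 1 else y[idx_train, 0])
        f_val = score(model, idx_val)
        if best is None or f_val > best[0]:
            best = (f_val, model)
    f_val, model = best
    return SocialPredictabilityResult(
        f_test=score(model, idx_test),
        f_val=f_val,
        f_train=score(model, idx_train),
        n_train=len(idx_train),
        n_test=len(idx_test),
    )


class CrossCorrelation(NamedTuple):
    lags: np.ndarray  # frames; positive lag = fish 2 trails fish 1
    correlation: np.ndarray
    peak_lag: int


def velocity_cross_correlation(
    traj: TrajectoryPair, max_lag: int = 150
) -> CrossCorrelation:
    """Normalized velocity-vector cross-correlation over lags (leadership).

    At lag L the velocity of fish 1 at time t is correlated with that of
    fish 2 at time t+L (components pooled, demeaned over the overlap).  If
    fish 2 replays fish 1 with a delay, the peak sits at that positive lag;
    swapping the fish negates the peak lag.
    """
    kin = differentiate(traj, scale="per_second")
    v1 = kin.velocity[:, 0, :]
    v2 = kin.velocity[:, 1, :]
    n = v1.shape[0]
    if max_lag >= n:
        raise ValueError("max_lag must be shorter than the velocity series")
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = v1[: n - lag], v2[lag:]
        else:
            a, b = v1[-lag:], v2[: n + lag]
        da = a - a.mean(axis=0)
        db = b - b.mean(axis=0)
        denom = np.sqrt((da**2).sum() * (db**2).sum())
        corr[i] = (da * db).sum() / denom if denom > 0 else 0.0
    peak = int(lags[int(np.argmax(corr))])
    return CrossCorrelation(lags, corr, peak)
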