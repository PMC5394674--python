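"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form expressions under test: the glide
closure is obtained by brute-force RK4 integration of the glide ODE, and
policy comparisons run a generic closed-loop simulator parameterised by an
arbitrary decision function.
"""

from __future__ import annotations

import numpy as np


def glide_closure_rk4(v_f, v_p, alpha: float, dt: float = 1e-4) -> np.ndarray:
    """Relative distance closed by gliding from v_f until speed reaches v_p.

    Vectorised brute-force integration of dv/dt = -alpha v and
    dr/dt = v - v_p with classical RK4, linearly interpolating the crossing
    v = v_p within the final step.  Inputs may be arrays (v_f >= v_p > 0).
    """
    v = np.atleast_1d(np.asarray(v_f, dtype=float)).copy()
    vp = np.broadcast_to(np.asarray(v_p, dtype=float), v.shape).copy()
    r = np.zeros_like(v)
    prev_v = v.copy()
    prev_r = r.copy()
    active = v > vp
    while active.any():
        prev_v[active] = v[active]
        prev_r[active] = r[active]
        va = v[active]
        k1v = -alpha * va
        k1r = va - vp[active]
        v2 = va + 0.5 * dt * k1v
        k2v = -alpha * v2
        k2r = v2 - vp[active]
        v3 = va + 0.5 * dt * k2v
        k3v = -alpha * v3
        k3r = v3 - vp[active]
        v4 = va + dt * k3v
        k4v = -alpha * v4
        k4r = v4 - vp[active]
        v[active] = va + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        r[active] = r[active] + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        active = v > vp
    # refine the final step at dt/100 before interpolating the crossing
    fine = dt / 100.0
    v = prev_v.copy()
    r = prev_r.copy()
    active = v > vp
    while active.any():
        prev_v[active] = v[active]
        prev_r[active] = r[active]
        va = v[active]
        k1v = -alpha * va
        k1r = va - vp[active]
        v2 = va + 0.5 * fine * k1v
        k2v = -alpha * v2
        k2r = v2 - vp[active]
        v3 = va + 0.5 * fine * k2v
        k3v = -alpha * v3
        k3r = v3 - vp[active]
        v4 = va + fine * k3v
        k4v = -alpha * v4
        k4r = v4 - vp[active]
        v[active] = va + fine / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        r[active] = r[active] + fine / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        active = v > vp
    denom = prev_v - v
    frac = np.where(denom > 0, (prev_v - vp) / np.where(denom > 0, denom, 1.0), 0.0)
    out = prev_r + frac * (r - prev_r)
    return out if out.size > 1 else float(out[0])


def time_to_cohesion(
    decide,
    v_f: float,
    v_p: float,
    d: float,
    params,
    dt: float = 0.005,
    horizon: float = 200.0,
    tol_d: float = 0.5,
    tol_v: float = 0.5,
) -> float:
    """Time for a generic policy to reach cohesion against a constant-speed partner.

    ``decide(v_f, v_p, d) -> acceleration`` is an arbitrary feedback law.
    Returns np.inf if cohesion (|d| < tol_d and |v_f - v_p| < tol_v) is not
    reached within the horizon.
    """
    n = int(horizon / dt)
    for i in range(n):
        if abs(d) < tol_d and abs(v_f - v_p) < tol_v:
            return i * dt
        a = decide(v_f, v_p, d)
        d += (v_p - v_f) * dt
        v_f = min(max(v_f + a * dt, 0.0), params.v_max)
    return np.inf
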