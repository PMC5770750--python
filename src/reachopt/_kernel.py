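"""Compiled closed-loop rollout kernel.

The control loop (state estimation with a delayed-feedback forward model,
policy evaluation, noisy plant step, wall-crossing detection) is executed
thousands of times per policy-search iteration, and the closed-loop
estimator alone costs ``delay`` forward-model iterations per control step.
This module holds a numba-compiled implementation of exactly the same
computation as the pure-NumPy operations in :mod:`reachopt.arm`,
:mod:`reachopt.estimator` and :mod:`reachopt.controller`; the test suite
asserts step-for-step agreement between the two on shared noise draws.

Parameter packing (``par`` vector) — see :func:`pack_params`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector
_K1, _K2, _K3 = 0, 1, 2
_B11, _B12, _B21, _B22 = 3, 4, 5, 6
_DT, _KAPPA = 7, 8
_Q1MIN, _Q1MAX, _Q2MIN, _Q2MAX = 9, 10, 11, 12
_L1, _L2, _WALLY = 13, 14, 15
_KE1, _KE2, _QDSCALE = 16, 17, 18
PAR_LEN = 19


def pack_params(params, estimator_cfg, wall_y: float, velocity_scale: float) -> np.ndarray:
    """Flatten arm and estimator parameters for the compiled kernel."""
    par = np.empty(PAR_LEN)
    par[_K1], par[_K2], par[_K3] = params.k1, params.k2, params.k3
    par[_B11], par[_B12] = params.B[0, 0], params.B[0, 1]
    par[_B21], par[_B22] = params.B[1, 0], params.B[1, 1]
    par[_DT], par[_KAPPA] = params.dt, params.kappa
    par[_Q1MIN], par[_Q1MAX] = params.q_min[0], params.q_max[0]
    par[_Q2MIN], par[_Q2MAX] = params.q_min[1], params.q_max[1]
    par[_L1], par[_L2], par[_WALLY] = params.l1, params.l2, wall_y
    par[_KE1], par[_KE2] = estimator_cfg.k1, estimator_cfg.k2
    par[_QDSCALE] = velocity_scale
    return par


@njit(cache=True)
def _dyn_step(x, tau1, tau2, par):
    """Semi-implicit Euler step of the rigid-body dynamics, with clamping."""
    q1, q2, qd1, qd2 = x[0], x[1], x[2], x[3]
    c = np.cos(q2)
    m11 = par[_K1] + 2.0 * par[_K2] * c
    m12 = par[_K3] + par[_K2] * c
    m22 = par[_K3]
    s = par[_K2] * np.sin(q2)
    cor1 = -qd2 * (2.0 * qd1 + qd2) * s
    cor2 = qd1 * qd1 * s
    r1 = tau1 - cor1 - (par[_B11] * qd1 + par[_B12] * qd2)
    r2 = tau2 - cor2 - (par[_B21] * qd1 + par[_B22] * qd2)
    det = m11 * m22 - m12 * m12
    a1 = (m22 * r1 - m12 * r2) / det
    a2 = (-m12 * r1 + m11 * r2) / det
    dt = par[_DT]
    qd1 += a1 * dt
    qd2 += a2 * dt
    q1 += qd1 * dt
    q2 += qd2 * dt
    if q1 < par[_Q1MIN]:
        q1 = par[_Q1MIN]
        qd1 = 0.0
    elif q1 > par[_Q1MAX]:
        q1 = par[_Q1MAX]
        qd1 = 0.0
    if q2 < par[_Q2MIN]:
        q2 = par[_Q2MIN]
        qd2 = 0.0
    elif q2 > par[_Q2MAX]:
        q2 = par[_Q2MAX]
        qd2 = 0.0
    out = np.empty(4)
    out[0], out[1], out[2], out[3] = q1, q2, qd1, qd2
    return out


@njit(cache=True)
def _fm_step(x, u, AT, fmax, par):
    """Noise-free forward-model step (deterministic torque from raw u)."""
    tau1 = 0.0
    tau2 = 0.0
    for i in range(6):
        f = fmax[i] * u[i]
        tau1 += AT[0, i] * f
        tau2 += AT[1, i] * f
    return _dyn_step(x, tau1, tau2, par)


@njit(cache=True)
def _policy_eval(x, w1, b1, w2, b2, par):
    """4 -> n_hidden (tanh) -> 6 (logistic) policy on the normalized state."""
    inp = np.empty(4)
    inp[0] = 2.0 * (x[0] - par[_Q1MIN]) / (par[_Q1MAX] - par[_Q1MIN]) - 1.0
    inp[1] = 2.0 * (x[1] - par[_Q2MIN]) / (par[_Q2MAX] - par[_Q2MIN]) - 1.0
    inp[2] = x[2] / par[_QDSCALE]
    inp[3] = x[3] / par[_QDSCALE]
    h = np.tanh(w1 @ inp + b1)
    z = w2 @ h + b2
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _endpoint(x, par):
    """Hand position and Cartesian velocity from the joint state."""
    q1 = x[0]
    q12 = x[0] + x[1]
    c1, s1 = np.cos(q1), np.sin(q1)
    c12, s12 = np.cos(q12), np.sin(q12)
    l1, l2 = par[_L1], par[_L2]
    px = l1 * c1 + l2 * c12
    py = l1 * s1 + l2 * s12
    vx = (-l1 * s1 - l2 * s12) * x[2] + (-l2 * s12) * x[3]
    vy = (l1 * c1 + l2 * c12) * x[2] + (l2 * c12) * x[3]
    return px, py, vx, vy


@njit(cache=True)
def simulate(x0, w1, b1, w2, b2, AT, fmax, par, delay, max_steps, noise):
    """Closed-loop rollout until wall crossing or ``max_steps``.

    Parameters
    ----------
    x0 : (4,) initial joint state (zero velocity for a reaching trial).
    w1, b1, w2, b2 : policy arrays.
    AT : (2, 6) transposed moment-arm matrix; fmax : (6,) max tensions.
    par : packed parameter vector from :func:`pack_params`.
    delay : sensory delay in steps.
    noise : (max_steps, 6) standard-normal draws for the motor noise.

    Returns
    -------
    (n_steps, states, us, u_noisys, xy, crossed, hit_x, mt, end_vx, end_vy,
    effort): arrays are allocated at full length; rows beyond ``n_steps``
    (``n_steps + 1`` for states/xy) are unspecified.
    """
    dt = par[_DT]
    kappa = par[_KAPPA]
    wall_y = par[_WALLY]
    ke1, ke2 = par[_KE1], par[_KE2]

    states = np.empty((max_steps + 1, 4))
    us = np.empty((max_steps, 6))
    uns = np.empty((max_steps, 6))
    xy = np.empty((max_steps + 1, 2))

    states[0] = x0
    px, py, vx, vy = _endpoint(x0, par)
    xy[0, 0], xy[0, 1] = px, py

    open_est = x0.copy()
    effort = 0.0
    crossed = False
    hit_x = np.nan
    mt = np.nan
    end_vx = np.nan
    end_vy = np.nan
    n_steps = 0

    for t in range(max_steps):
        # closed-loop term: delayed truth rolled forward through efference copies
        t0 = t - delay
        if t0 < 0:
            t0 = 0
        closed = states[t0].copy()
        for j in range(t0, t):
            closed = _fm_step(closed, us[j], AT, fmax, par)
        est = (ke1 * open_est + ke2 * closed) / (ke1 + ke2)

        u = _policy_eval(est, w1, b1, w2, b2, par)
        us[t] = u
        tau1 = 0.0
        tau2 = 0.0
        for i in range(6):
            un = u[i] * (1.0 + kappa * noise[t, i])
            if un < 0.0:
                un = 0.0
            elif un > 1.0:
                un = 1.0
            uns[t, i] = un
            f = fmax[i] * un
            tau1 += AT[0, i] * f
            tau2 += AT[1, i] * f
        states[t + 1] = _dyn_step(states[t], tau1, tau2, par)
        effort += (u @ u) * dt
        open_est = _fm_step(open_est, u, AT, fmax, par)

        px2, py2, vx2, vy2 = _endpoint(states[t + 1], par)
        xy[t + 1, 0], xy[t + 1, 1] = px2, py2
        n_steps = t + 1
        if py < wall_y and py2 >= wall_y:
            frac = (wall_y - py) / (py2 - py)
            hit_x = px + frac * (px2 - px)
            mt = (t + frac) * dt
            end_vx = vx + frac * (vx2 - vx)
            end_vy = vy + frac * (vy2 - vy)
            crossed = True
            break
        px, py, vx, vy = px2, py2, vx2, vy2

    return n_steps, states, us, uns, xy, crossed, hit_x, mt, end_vx, end_vy, effort
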