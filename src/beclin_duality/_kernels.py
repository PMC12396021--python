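"""Compiled numerical kernels shared by the model and the ensemble pipeline.

Everything here operates on a flat parameter vector laid out in Table-1
order (see :data:`PARAM_NAMES` in :mod:`beclin_duality.model_core`):

    0  S        7  phi_A     14 gamma_C
    1  alpha_B  8  alpha_M   15 phi_C
    2  beta_B   9  sigma_M   16 sigma_J
    3  gamma_B  10 gamma_M   17 u_B
    4  gamma_BC 11 alpha_C   18 u_M
    5  alpha_A  12 sigma_C
    6  beta_A   13 mu_C

State layout: y = (B, Bc, A, M, C).

Status codes returned by the steady-state / batch routines:

    0  resting steady state found (survival or apoptotic branch)
    1  degenerate: autophagosome production exceeds the flux capacity
       (alpha_A * B >= beta_A * phi_A), so no resting A balance exists
    2  degenerate: zero resting autophagic flux (alpha_A * alpha_B == 0),
       so damaged mitochondria have no resting balance
    3  integrator failure (step-size collapse / step budget exhausted)
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_PARAMS = 19
N_STATES = 5


@njit(cache=True)
def rhs(y, s, p):
    """Time derivative of (B, Bc, A, M, C) at stress level ``s``."""
    B, Bc, A, M, C = y[0], y[1], y[2], y[3], y[4]
    J = p[6] * A / (1.0 + A / p[7])
    dB = p[1] * (1.0 + p[17] * s) - p[2] * C * B - p[3] * B
    dBc = p[2] * C * B - p[4] * Bc
    dA = p[5] * B - J
    dM = p[8] * (1.0 + p[18] * s) + p[9] * Bc - p[10] * J * M
    dC = (p[11] * M + p[12] * A + p[13] * C / (p[15] + 1.0 - C)) * (1.0 - C) \
        - p[14] * C / (p[15] + p[16] * J + C)
    out = np.empty(5)
    out[0] = dB
    out[1] = dBc
    out[2] = dA
    out[3] = dM
    out[4] = dC
    return out


@njit(cache=True)
def caspase_net(C, alpha1, alpha2, mu, gamma, phi):
    """Activation minus inactivation rate of the isolated Caspase switch."""
    return (alpha1 + mu * C / (phi + 1.0 - C)) * (1.0 - C) \
        - gamma * C / (phi + C + alpha2)


@njit(cache=True)
def lowest_stable_root(alpha1, alpha2, mu, gamma, phi):
    """Smallest stable fixed point of the Caspase balance on [0, 1].

    The net rate is alpha1 >= 0 at C=0 and strictly negative at C=1, so a
    (+ -> -) crossing always exists; the first one is the smallest stable
    root.  When alpha1 == 0, C = 0 itself is a root and is stable iff the
    net rate is negative just above zero.
    """
    n = 400
    dc = 1.0 / n
    c_prev = 0.0
    f_prev = caspase_net(0.0, alpha1, alpha2, mu, gamma, phi)
    if alpha1 == 0.0:
        # C = 0 is an exact root; stable iff flow points back towards it.
        if caspase_net(0.5 * dc, alpha1, alpha2, mu, gamma, phi) < 0.0:
            return 0.0
        f_prev = 0.0
    for i in range(1, n + 1):
        c = i * dc
        f = caspase_net(c, alpha1, alpha2, mu, gamma, phi)
        if f_prev > 0.0 and f <= 0.0:
            lo = c_prev
            hi = c
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if caspase_net(mid, alpha1, alpha2, mu, gamma, phi) > 0.0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)
        c_prev = c
        f_prev = f
    # Not reachable for valid parameters; return the absorbing end point.
    return 1.0


@njit(cache=True)
def steady_state(p):
    """Unstressed (S = 0) steady state with C on its lowest stable branch.

    Fixed-point iteration: given C, the remaining balances are algebraic
    (resting flux J equals autophagosome production alpha_A * B); the
    Caspase level is then re-solved from the frozen drives.  Returns
    (state, status) with status as documented in the module docstring.
    """
    y = np.zeros(5)
    if p[5] * p[1] <= 0.0:
        return y, 2
    C = 0.0
    status = 0
    for _ in range(200):
        B = p[1] / (p[2] * C + p[3])
        prod = p[5] * B
        denom = p[6] - prod / p[7]
        if denom <= 0.0:
            return y, 1
        A = prod / denom
        J = prod
        Bc = p[2] * C * B / p[4]
        M = (p[8] + p[9] * Bc) / (p[10] * J)
        alpha1 = p[11] * M + p[12] * A
        alpha2 = p[16] * J
        C_new = lowest_stable_root(alpha1, alpha2, p[13], p[14], p[15])
        y[0] = B
        y[1] = Bc
        y[2] = A
        y[3] = M
        y[4] = C_new
        if abs(C_new - C) < 1e-13:
            break
        C = C_new
    # Near the resting saddle-node the fixed-point map is ill-conditioned;
    # polish by relaxation integration at S = 0 until the residual
    # certifies a steady state.
    for _ in range(60):
        dy = rhs(y, 0.0, p)
        resid = 0.0
        for j in range(5):
            if abs(dy[j]) > resid:
                resid = abs(dy[j])
        if resid < 1e-9:
            break
        y, st = integrate_final(y, 0.0, 200.0, 0.0, p, 1e-10, 1e-12)
        if st != 0:
            return y, 3
    return y, status


# Dormand-Prince 5(4) coefficients.
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, \
    64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = 9017.0 / 3168.0, -355.0 / 33.0, \
    46732.0 / 5247.0, 49.0 / 176.0, -5103.0 / 18656.0
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, \
    -2187.0 / 6784.0, 11.0 / 84.0
# y5 - y4 error weights (incl. the FSAL stage k7).
_E1, _E3, _E4, _E5, _E6, _E7 = 71.0 / 57600.0, -71.0 / 16695.0, \
    71.0 / 1920.0, -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0


@njit(cache=True)
def _clip_state(y):
    for j in range(4):
        if y[j] < 0.0:
            y[j] = 0.0
    if y[4] < 0.0:
        y[4] = 0.0
    elif y[4] > 1.0:
        y[4] = 1.0


@njit(cache=True)
def integrate_final(y0, t0, t1, s, p, rtol, atol):
    """Adaptive Dormand-Prince 5(4) integration; returns (y(t1), status).

    The system is only mildly stiff (fastest decay ~ gamma_M * J, a few
    hundred per hour in extreme variants), so an explicit embedded pair
    with step rejection is adequate and keeps the whole ensemble sweep in
    compiled code.  Status 3 flags step-size collapse.
    """
    y = y0.copy()
    if t1 <= t0:
        return y, 0
    t = t0
    h = min(1e-2, t1 - t0)
    max_steps = 5_000_000
    k1 = rhs(y, s, p)
    for _ in range(max_steps):
        if t + h > t1:
            h = t1 - t
        y2 = y + h * _A21 * k1
        k2 = rhs(y2, s, p)
        y3 = y + h * (_A31 * k1 + _A32 * k2)
        k3 = rhs(y3, s, p)
        y4 = y + h * (_A41 * k1 + _A42 * k2 + _A43 * k3)
        k4 = rhs(y4, s, p)
        y5 = y + h * (_A51 * k1 + _A52 * k2 + _A53 * k3 + _A54 * k4)
        k5 = rhs(y5, s, p)
        y6 = y + h * (_A61 * k1 + _A62 * k2 + _A63 * k3 + _A64 * k4
                      + _A65 * k5)
        k6 = rhs(y6, s, p)
        ynew = y + h * (_B1 * k1 + _B3 * k3 + _B4 * k4 + _B5 * k5 + _B6 * k6)
        k7 = rhs(ynew, s, p)
        errnorm = 0.0
        for j in range(5):
            e = h * (_E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j] + _E5 * k5[j]
                     + _E6 * k6[j] + _E7 * k7[j])
            sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
            r = e / sc
            errnorm += r * r
        errnorm = np.sqrt(errnorm / 5.0)
        if errnorm <= 1.0:
            t += h
            y = ynew
            _clip_state(y)
            k1 = rhs(y, s, p)
            if t >= t1:
                return y, 0
        if errnorm > 1e-300:
            fac = 0.9 * errnorm ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-12:
            return y, 3
    return y, 3


@njit(cache=True)
def rk4_fixed(y0, t0, t1, s, p, dt):
    """Fixed-step classical RK4; brute-force reference integrator."""
    y = y0.copy()
    n = int(np.ceil((t1 - t0) / dt))
    if n == 0:
        return y
    h = (t1 - t0) / n
    for _ in range(n):
        k1 = rhs(y, s, p)
        k2 = rhs(y + 0.5 * h * k1, s, p)
        k3 = rhs(y + 0.5 * h * k2, s, p)
        k4 = rhs(y + h * k3, s, p)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        _clip_state(y)
    return y


@njit(cache=True)
def protocol_final(y0, level, t_on, t_off, horizon, p, rtol, atol):
    """Integrate a piecewise-constant stress protocol, restarting at the
    stress discontinuities, and return (state at horizon, status)."""
    y = y0.copy()
    status = 0
    if t_on > 0.0:
        y, status = integrate_final(y, 0.0, t_on, 0.0, p, rtol, atol)
        if status != 0:
            return y, status
    if t_off > t_on:
        y, status = integrate_final(y, t_on, t_off, level, p, rtol, atol)
        if status != 0:
            return y, status
    if horizon > t_off:
        y, status = integrate_final(y, t_off, horizon, 0.0, p, rtol, atol)
    return y, status


@njit(cache=True)
def batch_protocol_final(P, levels, t_on, t_off, horizon, rtol, atol):
    """Simulate every variant (row of P) from its own unstressed steady
    state under the shared stress protocol.

    Returns (Y, status): final states (n, 5) and per-variant status codes.
    Degenerate variants (status 1 or 2) are not integrated; their rows in
    Y hold NaN.
    """
    n = P.shape[0]
    Y = np.full((n, 5), np.nan)
    status = np.zeros(n, dtype=np.int64)
    for i in range(n):
        p = P[i]
        y0, st = steady_state(p)
        if st != 0:
            status[i] = st
            continue
        y, st = protocol_final(y0, levels[i], t_on, t_off, horizon, p,
                               rtol, atol)
        status[i] = st
        Y[i] = y
    return Y, status
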