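"""Compiled RK4 inner loop.

The public :func:`thalcor.model.rhs` is the reference right-hand side; this
module holds a numba translation of the same equations specialised for the
fixed-step integrator, looping over a batch of grid cells with per-cell
(h7, h8).  A unit test asserts that one compiled RK4 step agrees with the
reference composition to machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_integrate"]


@njit(cache=True, inline="always")
def _sigmoid(z):
    # numerically stable logistic
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


@njit(cache=True)
def _deriv(y, d, h, h7, h8, eps, tau, a, b, ln_eps, s,
           c1, c2, cross_in_tau, stim_in_tau, u1, u2):
    """Derivative of one 8-component state row into ``d``.

    ``h`` holds (h1..h6, h9); ``eps`` the four background inputs;
    ``tau`` the four rate constants; ``c1``/``c2`` gate the cross-module
    inputs received by module I / module II.
    """
    h1, h2, h3, h4, h5, h6, h9 = h[0], h[1], h[2], h[3], h[4], h[5], h[6]

    q0 = _sigmoid(ln_eps * y[0]); q1 = _sigmoid(ln_eps * y[1])
    q2 = _sigmoid(ln_eps * y[2]); q4 = _sigmoid(ln_eps * y[4])
    q5 = _sigmoid(ln_eps * y[5]); q6 = _sigmoid(ln_eps * y[6])
    k2 = a * y[2] + b; k3 = a * y[3] + b
    k6 = a * y[6] + b; k7 = a * y[7] + b

    b_py1 = eps[0] - y[0] + h1 * q0 - h2 * q1 + h3 * q2
    b_py2 = eps[0] - y[4] + h1 * q4 - h2 * q5 + h3 * q6
    b_in1 = eps[1] - y[1] + h4 * q0
    b_in2 = eps[1] - y[5] + h4 * q4
    b_srn1 = eps[2] - y[2] + h5 * q0 - h6 * k3
    b_srn2 = eps[2] - y[6] + h5 * q4 - h6 * k7
    b_trn1 = eps[3] - y[3] + h7 * q0 + h8 * k2 - h9 * k3
    b_trn2 = eps[3] - y[7] + h7 * q4 + h8 * k6 - h9 * k7

    x_py1 = c1 * ((h1 / s) * q4 - (h2 / s) * q5)
    x_py2 = c2 * ((h1 / s) * q0 - (h2 / s) * q1)
    x_in1 = c1 * (h4 / s) * q4
    x_in2 = c2 * (h4 / s) * q0
    x_srn1 = -c1 * (h6 / s) * k7
    x_srn2 = -c2 * (h6 / s) * k3
    x_trn1 = c1 * ((h8 / s) * k6 - (h9 / s) * k7)
    x_trn2 = c2 * ((h8 / s) * k2 - (h9 / s) * k3)

    a1 = 0.0; a2 = 0.0
    if stim_in_tau:
        b_trn1 += u1
        b_trn2 += u2
    else:
        a1 = u1; a2 = u2

    if cross_in_tau:
        d[0] = tau[0] * (b_py1 + x_py1)
        d[4] = tau[0] * (b_py2 + x_py2)
        d[1] = tau[1] * (b_in1 + x_in1)
        d[5] = tau[1] * (b_in2 + x_in2)
        d[2] = tau[2] * (b_srn1 + x_srn1)
        d[6] = tau[2] * (b_srn2 + x_srn2)
        d[3] = tau[3] * (b_trn1 + x_trn1) + a1
        d[7] = tau[3] * (b_trn2 + x_trn2) + a2
    else:
        d[0] = tau[0] * b_py1 + x_py1
        d[4] = tau[0] * b_py2 + x_py2
        d[1] = tau[1] * b_in1 + x_in1
        d[5] = tau[1] * b_in2 + x_in2
        d[2] = tau[2] * b_srn1 + x_srn1
        d[6] = tau[2] * b_srn2 + x_srn2
        d[3] = tau[3] * b_trn1 + x_trn1 + a1
        d[7] = tau[3] * b_trn2 + x_trn2 + a2


@njit(cache=True)
def rk4_integrate(y, h7v, h8v, h, eps, tau, a, b, ln_eps, s,
                  c1, c2, cross_in_tau, stim_in_tau,
                  u1, u2, dt, n_steps, store_stride,
                  mf_out, states_out, store_full, guard, diverged_step):
    """Classic RK4 over ``n_steps`` for a batch of state rows ``y``.

    Stimulus arrays ``u1``/``u2`` are sampled on the half-step grid
    (``2 * n_steps + 1`` points).  The module-I mean field is written to
    ``mf_out`` every ``store_stride`` steps; rows breaching ``guard`` are
    frozen, their divergence step recorded, and NaN stored thereafter.
    """
    nb = y.shape[0]
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    yt = np.empty(8)

    for bi in range(nb):
        mf_out[bi, 0] = 0.5 * (y[bi, 0] + y[bi, 1])
    if store_full:
        for bi in range(nb):
            for j in range(8):
                states_out[0, bi, j] = y[bi, j]

    for i in range(n_steps):
        ua = u1[2 * i]; um = u1[2 * i + 1]; uc = u1[2 * i + 2]
        va = u2[2 * i]; vm = u2[2 * i + 1]; vc = u2[2 * i + 2]
        for bi in range(nb):
            if diverged_step[bi] >= 0:
                continue
            h7 = h7v[bi]; h8 = h8v[bi]
            yb = y[bi]
            _deriv(yb, k1, h, h7, h8, eps, tau, a, b, ln_eps, s,
                   c1, c2, cross_in_tau, stim_in_tau, ua, va)
            for j in range(8):
                yt[j] = yb[j] + 0.5 * dt * k1[j]
            _deriv(yt, k2, h, h7, h8, eps, tau, a, b, ln_eps, s,
                   c1, c2, cross_in_tau, stim_in_tau, um, vm)
            for j in range(8):
                yt[j] = yb[j] + 0.5 * dt * k2[j]
            _deriv(yt, k3, h, h7, h8, eps, tau, a, b, ln_eps, s,
                   c1, c2, cross_in_tau, stim_in_tau, um, vm)
            for j in range(8):
                yt[j] = yb[j] + dt * k3[j]
            _deriv(yt, k4, h, h7, h8, eps, tau, a, b, ln_eps, s,
                   c1, c2, cross_in_tau, stim_in_tau, uc, vc)
            ok = True
            for j in range(8):
                yb[j] = yb[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                if not (np.isfinite(yb[j]) and abs(yb[j]) <= guard):
                    ok = False
            if not ok:
                diverged_step[bi] = i + 1
                for j in range(8):
                    yb[j] = np.nan

        if (i + 1) % store_stride == 0:
            jdx = (i + 1) // store_stride
            for bi in range(nb):
                mf_out[bi, jdx] = 0.5 * (y[bi, 0] + y[bi, 1])
            if store_full:
                for bi in range(nb):
                    for j in range(8):
                        states_out[jdx, bi, j] = y[bi, j]
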