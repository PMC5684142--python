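"""Compiled Dormand-Prince 5(4) stepper for the plant-resource system.

The experiment drivers assemble thousands of communities to equilibrium, so
the inner loop is JIT-compiled. The scheme is the classic embedded
Runge-Kutta pair with FSAL (the same family as MATLAB's ode45 / scipy's
RK45); step-size control follows the standard PI-free elementary controller
with safety factor 0.9 and growth clamped to [0.2, 10].

Termination: after every accepted step the derivative at the new state is
available for free (FSAL); integration stops as soon as its max-norm falls
below ``tol`` (converged) or ``t`` reaches ``t_max``. Biomasses and resource
are clipped at zero both inside the right-hand side and after each accepted
step, since explicit solvers can overshoot into negative abundances.

Status codes: 0 converged, 1 hit t_max, 2 non-finite state encountered.
"""

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
# b5 - b4: error estimator weights
_E = np.array([
    35 / 384 - 5179 / 57600,
    0.0,
    500 / 1113 - 7571 / 16695,
    125 / 192 - 393 / 640,
    -2187 / 6784 + 92097 / 339200,
    11 / 84 - 187 / 2100,
    -1 / 40,
])


@njit(cache=True)
def _rhs(y, out, a, S, f, m, l, c):
    """dy/dt for y = [R, P_1..P_N]; negative entries treated as zero."""
    n = f.shape[0]
    R = y[0] if y[0] > 0.0 else 0.0
    tot = 0.0
    uptake = 0.0
    for i in range(n):
        p = y[i + 1] if y[i + 1] > 0.0 else 0.0
        tot += p
        uptake += f[i] * p
    out[0] = a * (S - R) - uptake * R
    for i in range(n):
        p = y[i + 1] if y[i + 1] > 0.0 else 0.0
        out[i + 1] = p * (f[i] * R - m[i] - c * p - l[i] * tot)


@njit(cache=True)
def _maxabs(v):
    r = 0.0
    for i in range(v.shape[0]):
        x = abs(v[i])
        if x > r:
            r = x
    return r


@njit(cache=True)
def integrate(y0, a, S, f, m, l, c, tol, t_max, rtol, atol):
    """Integrate to steady state. Returns (y, t, residual, status)."""
    d = y0.shape[0]
    y = y0.copy()
    k = np.empty((7, d))
    ytmp = np.empty(d)
    ynew = np.empty(d)

    _rhs(y, k[0], a, S, f, m, l, c)
    res = _maxabs(k[0])
    if res < tol:
        return y, 0.0, res, 0

    t = 0.0
    h = 1e-3
    while t < t_max:
        if h > t_max - t:
            h = t_max - t
        # stages 2..7 (stage 1 reuses FSAL derivative in k[0])
        for s in range(1, 6):
            for i in range(d):
                acc = 0.0
                for j in range(s):
                    acc += _A[s, j] * k[j, i]
                ytmp[i] = y[i] + h * acc
            _rhs(ytmp, k[s], a, S, f, m, l, c)
        for i in range(d):
            acc = 0.0
            for j in range(6):
                acc += _B5[j] * k[j, i]
            ynew[i] = y[i] + h * acc
        _rhs(ynew, k[6], a, S, f, m, l, c)

        # scaled error norm of the embedded 4th-order difference
        err = 0.0
        for i in range(d):
            e = 0.0
            for j in range(7):
                e += _E[j] * k[j, i]
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = abs(h * e) / sc
            if e > err:
                err = e

        if not np.isfinite(err):
            return y, t, _maxabs(k[0]), 2

        if err <= 1.0:
            t += h
            for i in range(d):
                y[i] = ynew[i] if ynew[i] > 0.0 else 0.0
            # FSAL: derivative at the (clipped) new state
            _rhs(y, k[0], a, S, f, m, l, c)
            res = _maxabs(k[0])
            if res < tol:
                return y, t, res, 0
        # step-size update
        if err == 0.0:
            fac = 10.0
        else:
            fac = 0.9 * err ** (-0.2)
            if fac > 10.0:
                fac = 10.0
            elif fac < 0.2:
                fac = 0.2
        h *= fac
        if h < 1e-12:
            h = 1e-12

    return y, t, res, 1
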