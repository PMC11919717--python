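"""Compiled inner loops of the probe-trajectory solvers.

Two time-stepping schemes for the overdamped motion of a trapped bead in a
linear viscoelastic medium, both driven by a prescribed trap trajectory
``xl`` sampled on a uniform grid with step ``dt``:

* ``gl_solve`` -- stress-additive materials (parallel springpots): the
  material operator is a sum of Grunwald-Letnikov fractional derivatives,
  ``sum_i c_i D^{a_i} x = k (xl - x)`` with ``c_i = 6 pi a C_i``.
* ``volterra_solve`` / ``volterra_linear_solve`` -- compliance-additive
  materials (series springpots): the hereditary creep integral
  ``x(t) = (1/6 pi a) \\int J(t - s) dF(s)`` with ``F = k (xl - x)``,
  discretized with midpoint kernel samples and piecewise-constant force
  increments.  The linear variant exploits a kernel of the form
  ``J(t) = J0 + t/eta`` (newtonian, Maxwell) for an O(N) recursion.

Both schemes resolve the implicit dependence of the current step on the
current force algebraically, so no inner iteration is required.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gl_weights(alpha, n):
    """Grunwald-Letnikov binomial weights w_j = (-1)^j C(alpha, j), j=0..n."""
    w = np.empty(n + 1)
    w[0] = 1.0
    for j in range(1, n + 1):
        w[j] = w[j - 1] * (1.0 - (alpha + 1.0) / j)
    return w


@njit(cache=True)
def gl_solve(xl, dt, k, coeffs, alphas, window):
    """March sum_i c_i D^{a_i} x = k (xl - x) from rest (x = 0 for t <= 0).

    ``window`` truncates each fractional memory sum (short-memory
    principle); pass ``len(xl)`` for full memory.  Weights that vanish
    exactly (integer orders) shrink the effective window automatically.
    """
    n = xl.shape[0]
    nterms = coeffs.shape[0]
    x = np.zeros(n)
    scale = np.empty(nterms)
    for i in range(nterms):
        scale[i] = coeffs[i] * dt ** (-alphas[i])
    wts = np.zeros((nterms, window + 1))
    mlen = np.empty(nterms, dtype=np.int64)
    for i in range(nterms):
        w = gl_weights(alphas[i], window)
        m = window
        while m > 0 and w[m] == 0.0:
            m -= 1
        wts[i, : window + 1] = w
        mlen[i] = m
    denom = k
    for i in range(nterms):
        denom += scale[i] * wts[i, 0]
    for t in range(1, n):
        hist = 0.0
        for i in range(nterms):
            m = mlen[i]
            if m > t:
                m = t
            s = 0.0
            for j in range(1, m + 1):
                s += wts[i, j] * x[t - j]
            hist += scale[i] * s
        x[t] = (k * xl[t] - hist) / denom
    return x


@njit(cache=True)
def volterra_solve(xl, dt, k, six_pi_a, jmid):
    """March the hereditary creep integral; jmid[q] = J((q + 1/2) dt)."""
    n = xl.shape[0]
    x = np.zeros(n)
    f = np.zeros(n)
    j0 = jmid[0] / six_pi_a
    for t in range(1, n):
        b = 0.0
        for m in range(1, t):
            b += jmid[t - m] * (f[m] - f[m - 1])
        b /= six_pi_a
        # x_t = b + j0 (F_t - F_{t-1}),  F_t = k (xl_t - x_t)
        x[t] = (b + j0 * (k * xl[t] - f[t - 1])) / (1.0 + j0 * k)
        f[t] = k * (xl[t] - x[t])
    return x


@njit(cache=True)
def volterra_linear_solve(xl, dt, k, six_pi_a, j_el, inv_eta):
    """O(N) hereditary march for the linear kernel J(t) = j_el + t/eta.

    The memory sum splits as j_el (F_{t-1} - F_0) + (t_n S0 - S1)/eta with
    S0 = sum dF, S1 = sum t_mid dF, both updated incrementally.
    """
    n = xl.shape[0]
    x = np.zeros(n)
    f = np.zeros(n)
    s0 = 0.0
    s1 = 0.0
    j0 = (j_el + 0.5 * dt * inv_eta) / six_pi_a
    for t in range(1, n):
        tn = t * dt
        b = (j_el * (f[t - 1] - f[0]) + inv_eta * (tn * s0 - s1)) / six_pi_a
        x[t] = (b + j0 * (k * xl[t] - f[t - 1])) / (1.0 + j0 * k)
        f[t] = k * (xl[t] - x[t])
        df = f[t] - f[t - 1]
        s0 += df
        s1 += (tn - 0.5 * dt) * df
    return x
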