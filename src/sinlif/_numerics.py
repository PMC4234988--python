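"""Compiled numerical kernels (Euler-Maruyama scan, Crank-Nicolson march).

These are internal: the public surfaces live in :mod:`sinlif.simulate` and
:mod:`sinlif.fokker_planck`.  Kernels are written for numba's nopython mode;
all randomness is supplied from outside so the RNG contract stays with
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def euler_scan(
    x: float,
    s: float,
    alpha: float,
    beta: float,
    gamma: float,
    Omega: float,
    dt: float,
    z: np.ndarray,
    out: np.ndarray,
    n_found: int,
):
    """Advance the threshold-reset SDE through one chunk of normal draws.

    Continues an ongoing trajectory from state ``(x, s)``, appending spike
    times into ``out`` starting at slot ``n_found``.  A spike is recorded at
    the first time-grid point where X >= 1, after which X resets to 0; the
    global clock keeps running across resets.

    Returns ``(n_found, k_used, x, s)`` so the caller can resume with a fresh
    noise chunk.
    """
    sqdt = math.sqrt(dt)
    cap = out.shape[0]
    k = 0
    n = z.shape[0]
    while k < n:
        drift = (alpha - x + gamma * math.sin(Omega * s)) * dt
        x = x + drift + beta * sqdt * z[k]
        s = s + dt
        k += 1
        if x >= 1.0:
            out[n_found] = s
            n_found += 1
            x = 0.0
            if n_found == cap:
                break
    return n_found, k, x, s


@njit(cache=True)
def cn_march(
    alpha: float,
    beta: float,
    gamma: float,
    Omega: float,
    phi: float,
    x_lo: float,
    nx: int,
    dt: float,
    nt: int,
    stop_tol: float,
    t_stop_min: float,
    F_full: np.ndarray,
    store_full: bool,
):
    """Crank-Nicolson march of the distribution-form forward equation.

    Solves  dF/dt = (beta^2/2) F_xx - (alpha - x + gamma sin(Omega(t+phi))) F_x
    on [x_lo, 1] with F(x,0) = Heaviside(x), F(x_lo,t) = 0 (the mass below the
    truncation boundary is negligible) and F_x(1,t) = 0 (absorption at the
    threshold).  Central differences in space; the sinusoidal drift is
    evaluated at the half-time level so the scheme stays second order in time.

    Parameters
    ----------
    stop_tol, t_stop_min : the march stops early once the surviving mass
        F(1,t) falls below ``stop_tol`` *and* t >= ``t_stop_min``.
    F_full : (nt+1, nx) array, written only when ``store_full`` is True.

    Returns
    -------
    trace : (nt+1,) array of F(1, t_j); entries beyond the stopping step are
        filled with the last computed value (effectively zero).
    n_done : index of the last computed step.
    """
    dx = (1.0 - x_lo) / (nx - 1)
    D = 0.5 * beta * beta
    r = D * dt / (2.0 * dx * dx)
    cc = dt / (4.0 * dx)

    F = np.empty(nx)
    for i in range(nx):
        xi = x_lo + i * dx
        F[i] = 1.0 if xi >= 0.0 else 0.0
    F[0] = 0.0

    trace = np.empty(nt + 1)
    trace[0] = F[nx - 1]
    if store_full:
        for i in range(nx):
            F_full[0, i] = F[i]

    # Thomas-algorithm work arrays
    cp = np.empty(nx)
    dp = np.empty(nx)
    rhs = np.empty(nx)
    Fn = np.empty(nx)

    # drift base (alpha - x_i); the sinusoidal part is a scalar per step
    abase = np.empty(nx)
    for i in range(nx):
        abase[i] = alpha - (x_lo + i * dx)

    n_done = nt
    for j in range(nt):
        if j < 2:
            # Rannacher startup: the Heaviside initial condition excites
            # undamped Crank-Nicolson modes; replace each of the first two
            # steps by two backward-Euler half-steps, which damp them while
            # keeping second-order accuracy globally.
            h = 0.5 * dt
            for sub in range(2):
                t_end = j * dt + h * (sub + 1)
                ssub = gamma * math.sin(Omega * (t_end + phi))
                rdx = D * h / (dx * dx)
                chh = h / (2.0 * dx)
                cp[0] = 0.0
                dp[0] = 0.0
                for i in range(1, nx - 1):
                    ai = abase[i] + ssub
                    a_l = -(rdx + chh * ai)
                    a_d = 1.0 + 2.0 * rdx
                    a_u = -(rdx - chh * ai)
                    denom = a_d - a_l * cp[i - 1]
                    cp[i] = a_u / denom
                    dp[i] = (F[i] - a_l * dp[i - 1]) / denom
                a_l = -2.0 * rdx
                a_d = 1.0 + 2.0 * rdx
                denom = a_d - a_l * cp[nx - 2]
                dlast = (F[nx - 1] - a_l * dp[nx - 2]) / denom
                Fn[nx - 1] = dlast
                for i in range(nx - 2, -1, -1):
                    Fn[i] = dp[i] - cp[i] * Fn[i + 1]
                for i in range(nx):
                    F[i] = Fn[i]
            top = F[nx - 1]
            trace[j + 1] = top
            if store_full:
                for i in range(nx):
                    F_full[j + 1, i] = F[i]
            continue
        t_mid = (j + 0.5) * dt
        sterm = gamma * math.sin(Omega * (t_mid + phi))
        # explicit half step -> rhs
        rhs[0] = 0.0
        for i in range(1, nx - 1):
            ci = cc * (abase[i] + sterm)
            lo = r + ci
            up = r - ci
            rhs[i] = (1.0 - 2.0 * r) * F[i] + lo * F[i - 1] + up * F[i + 1]
        rhs[nx - 1] = (1.0 - 2.0 * r) * F[nx - 1] + 2.0 * r * F[nx - 2]

        # implicit half step: tridiagonal solve (forward sweep)
        # row 0: F=0 Dirichlet
        cp[0] = 0.0
        dp[0] = 0.0
        for i in range(1, nx - 1):
            ci = cc * (abase[i] + sterm)
            a_l = -(r + ci)
            a_d = 1.0 + 2.0 * r
            a_u = -(r - ci)
            denom = a_d - a_l * cp[i - 1]
            cp[i] = a_u / denom
            dp[i] = (rhs[i] - a_l * dp[i - 1]) / denom
        # last row: (1+2r) F_{n-1} - 2r F_{n-2} = rhs
        a_l = -2.0 * r
        a_d = 1.0 + 2.0 * r
        denom = a_d - a_l * cp[nx - 2]
        dlast = (rhs[nx - 1] - a_l * dp[nx - 2]) / denom

        Fn[nx - 1] = dlast
        for i in range(nx - 2, -1, -1):
            Fn[i] = dp[i] - cp[i] * Fn[i + 1]

        for i in range(nx):
            F[i] = Fn[i]
        top = F[nx - 1]
        trace[j + 1] = top
        if store_full:
            for i in range(nx):
                F_full[j + 1, i] = F[i]
        if not math.isfinite(top):
            n_done = j + 1
            break
        if top < stop_tol and (j + 1) * dt >= t_stop_min:
            n_done = j + 1
            for jj in range(j + 2, nt + 1):
                trace[jj] = top
            break

    return trace, n_done
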