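"""Numerical kernels for the simulator.

The beat-by-beat RR recursion and the per-second bout chain are inherently
sequential; they are JIT-compiled with numba when available and fall back to
identical pure-Python loops otherwise.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def rr_beat_loop(t0, t1, base, asleep_sec, lf_amp, hf_amp, ph1, ph2, phi, noise,
                 beat_t, beat_rr):
    """Sequential beat generation; writes into preallocated arrays and
    returns the number of beats produced.

    asleep_sec[k] is the sleep flag for second ``t0 + k``.
    """
    two_pi = 2.0 * math.pi
    t = t0
    ar = 0.0
    n = 0
    nmax = beat_t.shape[0]
    nsec = asleep_sec.shape[0]
    while t < t1 and n < nmax:
        k = int(t - t0)
        if k < 0:
            k = 0
        if k >= nsec:
            k = nsec - 1
        mult = 1.10 if asleep_sec[k] else 1.0
        rr = (base * mult
              + lf_amp * math.sin(two_pi * 0.10 * t + ph1)
              + hf_amp * math.sin(two_pi * 0.25 * t + ph2)
              + ar)
        if rr < 350.0:
            rr = 350.0
        elif rr > 1900.0:
            rr = 1900.0
        beat_t[n] = t
        beat_rr[n] = rr
        ar = phi * ar + noise[n]
        t += rr / 1000.0
        n += 1
    return n


@njit(cache=False)
def sampen_counts(x, m, tol):
    """Template-match pair counts (B at length m, A at length m+1) with
    Chebyshev distance and self-matches excluded."""
    n = x.shape[0]
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= tol:
                b += 1
                # Chebyshev distance at length m+1 is max(d, last-point diff)
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    return b, a


@njit(cache=False)
def lomb_scargle_kernel(t, x, freqs_rad):
    """Unnormalized Lomb-Scargle periodogram with the phase-origin shift tau.

    Evaluates, for every angular frequency on a (not necessarily uniform)
    grid,

        P(w) = 1/2 [ (sum x cos w(t-tau))^2 / sum cos^2 w(t-tau)
                   + (sum x sin w(t-tau))^2 / sum sin^2 w(t-tau) ],
        tan(2 w tau) = sum sin 2wt / sum cos 2wt.

    The per-sample phasors exp(i w t_n) are advanced across the frequency
    grid by complex rotation (no trigonometric calls in the inner loop),
    which is exact up to rounding; per-frequency sums of zr^2, zi^2, zr*zi,
    x*zr and x*zi yield all the terms above.
    """
    n = t.shape[0]
    nf = freqs_rad.shape[0]
    power = np.empty(nf)
    zr = np.empty(n)
    zi = np.empty(n)
    dr = np.empty(n)
    di = np.empty(n)
    w0 = freqs_rad[0]
    dw = freqs_rad[1] - freqs_rad[0] if nf > 1 else 0.0
    for k in range(n):
        zr[k] = math.cos(w0 * t[k])
        zi[k] = math.sin(w0 * t[k])
        dr[k] = math.cos(dw * t[k])
        di[k] = math.sin(dw * t[k])
    for j in range(nf):
        w = freqs_rad[j]
        if j > 0:
            for k in range(n):
                r = zr[k] * dr[k] - zi[k] * di[k]
                zi[k] = zr[k] * di[k] + zi[k] * dr[k]
                zr[k] = r
        s_rr = 0.0
        s_ii = 0.0
        s_ri = 0.0
        s_xr = 0.0
        s_xi = 0.0
        for k in range(n):
            s_rr += zr[k] * zr[k]
            s_ii += zi[k] * zi[k]
            s_ri += zr[k] * zi[k]
            s_xr += x[k] * zr[k]
            s_xi += x[k] * zi[k]
        c2 = s_rr - s_ii
        s2 = 2.0 * s_ri
        wtau = 0.5 * math.atan2(s2, c2)
        ct = math.cos(wtau)
        st = math.sin(wtau)
        xc = ct * s_xr + st * s_xi
        xs = ct * s_xi - st * s_xr
        cc = ct * ct * s_rr + 2.0 * ct * st * s_ri + st * st * s_ii
        ss = st * st * s_rr - 2.0 * ct * st * s_ri + ct * ct * s_ii
        p = 0.0
        if cc > 0.0:
            p += xc * xc / cc
        if ss > 0.0:
            p += xs * xs / ss
        power[j] = 0.5 * p
    return power


@njit(cache=False)
def bout_chain(u, awake, p_on, p_off):
    """Two-state rest/active chain driven by pre-drawn uniforms."""
    n = u.shape[0]
    states = np.zeros(n, dtype=np.int8)
    s = 0
    for t in range(n):
        if not awake[t]:
            s = 0
        elif s == 0:
            if u[t] < p_on:
                s = 1
        else:
            if u[t] < p_off:
                s = 0
        states[t] = s
    return states
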