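"""Independent brute-force reference implementations used only by tests.

The Ting oracle evaluates the hereditary integral by a midpoint rule on
a densely refined grid (linear interpolation of the indentation
history) and locates the retraction bound t1 by plain bisection on the
dense unloading integral.  It shares no code with the package solver.
"""

from __future__ import annotations

import numpy as np

_NM = 1e-9
_NN = 1e9


def _dense_history(t, delta_nm, refine):
    td = np.linspace(t[0], t[-1], (t.size - 1) * refine + 1)
    dd = np.interp(td, t, delta_nm)
    return td, dd


def _kernel(alpha):
    a = min(alpha, 0.999)
    return lambda gap: gap ** (-a)


def oracle_ting_force(t, delta_nm, tm_index, E1, alpha, eta, radius_nm,
                      poisson_nu=0.5, thickness_nm=np.inf, bec_coeffs=None,
                      refine=15):
    """Midpoint-rule hereditary integral on a refined grid, nN.

    Returns the force at every sample of the original grid.
    """
    t = np.asarray(t, float)
    delta_nm = np.asarray(delta_nm, float)
    r_m = radius_nm * _NM
    c = 4.0 * np.sqrt(r_m) / (3.0 * (1.0 - poisson_nu**2)) * _NN
    ker = _kernel(alpha)
    tm = t[tm_index]

    td, dd = _dense_history(t, delta_nm, refine)
    ud = (dd * _NM) ** 1.5
    mid_t = 0.5 * (td[:-1] + td[1:])
    du = np.diff(ud)
    ddelta = np.diff(dd * _NM)
    if bec_coeffs is not None and np.isfinite(thickness_nm):
        chi = np.sqrt(radius_nm * 0.5 * (dd[:-1] + dd[1:])) / thickness_nm
        g_mid = np.ones_like(chi)
        for p, cf in enumerate(bec_coeffs, start=1):
            g_mid += cf * chi**p
    else:
        g_mid = np.ones_like(mid_t)

    def loading_integral(t_now, upper):
        sel = mid_t < upper
        if not sel.any():
            return 0.0
        return float(np.sum(g_mid[sel] * ker(t_now - mid_t[sel]) * du[sel]))

    def unloading_residual(t_now, t1):
        sel = (mid_t > t1) & (mid_t < t_now)
        if not sel.any():
            return 0.0
        return float(np.sum(ker(t_now - mid_t[sel]) * ddelta[sel]))

    # eta term: per-phase centred derivative of u on the original grid
    u = (delta_nm * _NM) ** 1.5
    du_dt = np.empty_like(u)
    du_dt[: tm_index + 1] = np.gradient(u[: tm_index + 1], t[: tm_index + 1])
    if t.size - tm_index >= 3:
        du_dt[tm_index + 1:] = np.gradient(u[tm_index:], t[tm_index:])[1:]
    elif t.size - tm_index == 2:
        du_dt[-1] = (u[-1] - u[-2]) / (t[-1] - t[-2])

    force = np.zeros_like(t)
    for k in range(1, t.size):
        t_now = t[k]
        if k <= tm_index:
            upper = t_now
        else:
            lo, hi = 0.0, tm
            if unloading_residual(t_now, lo) <= 0.0:
                force[k] = 0.0
                continue
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if unloading_residual(t_now, mid) > 0.0:
                    lo = mid
                else:
                    hi = mid
            upper = 0.5 * (lo + hi)
        f = c * E1 * loading_integral(t_now, upper)
        if k <= tm_index or upper > 0.0:
            f += c * eta * du_dt[k]
        force[k] = f
    return force
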