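"""Forward viscoelastic indentation model (Ting's solution) for power-law rheology.

For an arbitrary indentation history delta(t) of a spherical tip into a
viscoelastic half-space the contact force is the hereditary integral

    F(t) = 4*sqrt(R)/(3*(1-nu^2)) * int_0^{t1(t)} f_BEC(delta(xi)) *
           E(t - xi) * d(delta^{3/2})/dxi  dxi

where t is time from first contact and the upper limit t1(t) equals t
during the approach (t <= tm) and, after the turnaround at tm, is the
earlier time bounding the effective contact history, defined by

    int_{t1}^{t} E(t - xi) * d(delta)/dxi  dxi = 0 .

With the power-law relaxation modulus E(t) = E1 * t^(-alpha) the kernel
has a weak (t - xi)^(-alpha) singularity at xi -> t.  The solver treats
the rates as piecewise constant on the sampling grid and integrates the
kernel analytically on every subinterval, which handles the singular
endpoint exactly; t1 is located by a node scan plus a closed-form solve
inside the bracketing subinterval (the same piecewise-analytic integral
is monotone in t1 there).  The Dirac viscous term eta * delta_D(t) of the
rheology model contributes eta * d(delta^{3/2})/dt pointwise while the tip
is in contact and is excluded from the t1 equation (its endpoint weight
under the convolution is ambiguous; the PLR term dominates t1).

The force is linear in (E1, eta) at fixed alpha; ``ting_basis`` exposes
the two unit-coefficient components, which the fitters exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import BEC_NONE, BECModel, Indenter, PLRParams, bec_factor
from .errors import DomainError

__all__ = ["TingSolution", "force_last", "ting_basis", "ting_force", "ting_solve"]

_NM = 1e-9
_NN = 1e9

# kernel exponent clip: the convolution is non-integrable against a
# non-vanishing rate exactly at alpha = 1 (fluid limit)
_ALPHA_MAX = 0.999


@dataclass
class TingSolution:
    """Forward-model evaluation on one indentation history."""

    t_s: np.ndarray          # time from contact, s
    delta_nm: np.ndarray     # indentation history, nm
    tm_s: float              # approach duration (turnaround time), s
    t1_s: np.ndarray         # auxiliary retraction time bound, s (= t on approach)
    force_nN: np.ndarray     # predicted contact force, nN


def _kernel_integrals(t_now: float, nodes: np.ndarray, one_m_alpha: float) -> np.ndarray:
    """int_{xi_i}^{xi_{i+1}} (t_now - xi)^(-alpha) dxi for all subintervals below t_now."""
    gaps = np.clip(t_now - nodes, 0.0, None) ** one_m_alpha
    return (gaps[:-1] - gaps[1:]) / one_m_alpha


def _centered_rate(u: np.ndarray, t: np.ndarray, tm_index: int) -> np.ndarray:
    """d u / d t by centered differences, computed per phase.

    The rate flips sign at the turnaround; differencing across it would
    smear the discontinuity, so approach and retract are differenced
    separately (one-sided at segment ends, the turnaround sample taking
    the approach-side value).
    """
    rate = np.empty_like(u)
    stop = min(tm_index + 1, u.size)
    if stop >= 2:
        rate[:stop] = np.gradient(u[:stop], t[:stop], edge_order=1)
    else:
        rate[:stop] = 0.0
    if u.size - tm_index >= 3:
        rate[tm_index + 1:] = np.gradient(u[tm_index:], t[tm_index:],
                                          edge_order=1)[1:]
    elif u.size - tm_index == 2:
        rate[tm_index + 1] = (u[tm_index + 1] - u[tm_index]) / \
            (t[tm_index + 1] - t[tm_index])
    return rate


def ting_basis(t_s, delta_nm, tm_index: int, alpha: float, indenter: Indenter,
               thickness_nm: float = np.inf, bec: BECModel = BEC_NONE):
    """Unit-coefficient force components of the PLR Ting model.

    Parameters
    ----------
    t_s, delta_nm : arrays
        Time from contact (t[0] = 0, strictly increasing) and the
        indentation history (>= 0, delta[0] = 0).
    tm_index : int
        Index of the approach/retract turnaround (maximum indentation).
    alpha : float
        Power-law exponent in [0, 1].

    Returns
    -------
    b_plr : array
        Force per unit E1 (nN per Pa).
    b_visc : array
        Force per unit eta (nN per Pa*s): C * f_BEC * d(delta^{3/2})/dt,
        zeroed once contact is lost (t1 = 0).
    t1_s : array
        Auxiliary function t1(t); equals t on the approach.
    """
    t = np.asarray(t_s, dtype=float)
    delta = np.asarray(delta_nm, dtype=float)
    if not (0.0 <= alpha <= 1.0):
        raise DomainError(f"alpha must be in [0, 1], got {alpha}")
    if t.shape != delta.shape or t.ndim != 1:
        raise DomainError("t and delta must be matching 1-d arrays")
    if np.any(np.diff(t) <= 0):
        raise DomainError("time samples must be strictly increasing")
    if np.any(delta < 0):
        raise DomainError("indentation history must be >= 0")
    n = t.size
    if not (0 < tm_index < n or (tm_index == n - 1)):
        raise DomainError("tm_index out of range")

    one_m_alpha = 1.0 - min(alpha, _ALPHA_MAX)
    r_m = indenter.radius_nm * _NM
    c_pref = 4.0 * np.sqrt(r_m) / (3.0 * (1.0 - indenter.poisson_nu**2)) * _NN

    u = (delta * _NM) ** 1.5                    # m^{3/2}
    g = np.atleast_1d(bec_factor(delta, thickness_nm, indenter, bec))
    dxi = np.diff(t)
    rate_u = np.diff(u) / dxi                   # per-subinterval d(u)/dxi
    rate_d = np.diff(delta * _NM) / dxi         # per-subinterval d(delta)/dxi
    g_mid = 0.5 * (g[:-1] + g[1:])
    wu = g_mid * rate_u                         # PLR integrand weights

    b_plr = np.zeros(n)
    t1 = t.copy()

    # --- approach: upper limit is t itself
    for k in range(1, min(tm_index, n - 1) + 1):
        ker = _kernel_integrals(t[k], t[: k + 1], one_m_alpha)
        b_plr[k] = np.dot(wu[:k], ker)

    # --- retraction: solve the t1 equation, then integrate up to t1
    in_contact_until = n
    for k in range(tm_index + 1, n):
        ker = _kernel_integrals(t[k], t[: k + 1], one_m_alpha)
        contrib = rate_d[:k] * ker
        # Phi(xi_j) = int_{xi_j}^{t_k} E(t_k - xi) ddelta/dxi dxi   (per unit E1)
        phi = np.concatenate((np.cumsum(contrib[::-1])[::-1], [0.0]))
        if phi[0] <= 0.0:
            # even the full history cannot balance the unloading: contact lost
            t1[k:] = 0.0
            b_plr[k:] = 0.0
            in_contact_until = k
            break
        m = min(tm_index, k - 1)
        # largest node j <= tm with phi[j] >= 0 > phi[j+1]
        neg = np.nonzero(phi[: m + 2] <= 0.0)[0]
        if neg.size == 0:
            # noisy sample right after the turnaround: unloading has not
            # yet overcome the history; pin t1 to the turnaround
            j, t1_k = m + 1, t[m + 1]
        else:
            j = int(neg[0]) - 1
            rj = rate_d[j]
            if rj <= 0:
                t1_k = t[j]      # stagnant approach subinterval: pin to node
            else:
                target = (t[k] - t[j + 1]) ** one_m_alpha \
                    - phi[j + 1] * one_m_alpha / rj
                t1_k = t[k] - target ** (1.0 / one_m_alpha)
                t1_k = min(max(t1_k, t[j]), t[j + 1])
        t1[k] = t1_k
        full = np.dot(wu[:j], ker[:j])
        partial = wu[j] * ((t[k] - t[j]) ** one_m_alpha
                           - (t[k] - t1_k) ** one_m_alpha) / one_m_alpha \
            if t1_k > t[j] else 0.0
        b_plr[k] = full + partial

    b_plr *= c_pref

    b_visc = c_pref * g * _centered_rate(u, t, tm_index)
    b_visc[in_contact_until:] = 0.0
    return b_plr, b_visc, t1


def force_last(t_s, delta_nm, tm_index: int, params: PLRParams, indenter: Indenter,
               thickness_nm: float = np.inf, bec: BECModel = BEC_NONE) -> float:
    """Contact force (nN) at the final sample of a history, in O(n).

    Used by the quasi-static force-balance simulator, which grows the
    history one sample at a time.  Returns 0.0 once contact is lost
    (t1 = 0 on the retract).  Same discretisation as :func:`ting_basis`.
    """
    t = np.asarray(t_s, dtype=float)
    delta = np.asarray(delta_nm, dtype=float)
    n = t.size
    k = n - 1
    if k == 0:
        return 0.0
    one_m_alpha = 1.0 - min(params.alpha, _ALPHA_MAX)
    r_m = indenter.radius_nm * _NM
    c_pref = 4.0 * np.sqrt(r_m) / (3.0 * (1.0 - indenter.poisson_nu**2)) * _NN

    u = (delta * _NM) ** 1.5
    g = np.atleast_1d(bec_factor(delta, thickness_nm, indenter, bec))
    dxi = np.diff(t)
    rate_u = np.diff(u) / dxi
    g_mid = 0.5 * (g[:-1] + g[1:])
    wu = g_mid * rate_u
    ker = _kernel_integrals(t[k], t, one_m_alpha)

    if k <= tm_index:
        f_plr = np.dot(wu, ker)
        visc = params.eta * c_pref * g[k] * rate_u[k - 1]
        return float(params.E1 * c_pref * f_plr + visc)

    rate_d = np.diff(delta * _NM) / dxi
    contrib = rate_d * ker
    phi = np.concatenate((np.cumsum(contrib[::-1])[::-1], [0.0]))
    if phi[0] <= 0.0:
        return 0.0
    m = min(tm_index, k - 1)
    neg = np.nonzero(phi[: m + 2] <= 0.0)[0]
    if neg.size == 0:
        j, t1_k = m + 1, t[m + 1]
    else:
        j = int(neg[0]) - 1
        rj = rate_d[j]
        if rj <= 0:
            t1_k = t[j]
        else:
            target = (t[k] - t[j + 1]) ** one_m_alpha - phi[j + 1] * one_m_alpha / rj
            t1_k = t[k] - target ** (1.0 / one_m_alpha)
            t1_k = min(max(t1_k, t[j]), t[j + 1])
    full = np.dot(wu[:j], ker[:j])
    partial = wu[j] * ((t[k] - t[j]) ** one_m_alpha
                       - (t[k] - t1_k) ** one_m_alpha) / one_m_alpha \
        if t1_k > t[j] else 0.0
    visc = params.eta * c_pref * g[k] * rate_u[k - 1]
    return float(params.E1 * c_pref * (full + partial) + visc)


def ting_force(t_s, delta_nm, tm_index: int, params: PLRParams, indenter: Indenter,
               thickness_nm: float = np.inf, bec: BECModel = BEC_NONE) -> np.ndarray:
    """Predicted contact force (nN) for a PLR material along one history."""
    b_plr, b_visc, _ = ting_basis(t_s, delta_nm, tm_index, params.alpha,
                                  indenter, thickness_nm, bec)
    return params.E1 * b_plr + params.eta * b_visc


def ting_solve(t_s, delta_nm, tm_index: int, params: PLRParams, indenter: Indenter,
               thickness_nm: float = np.inf, bec: BECModel = BEC_NONE) -> TingSolution:
    """Forward evaluation returning the full solution record (incl. t1)."""
    b_plr, b_visc, t1 = ting_basis(t_s, delta_nm, tm_index, params.alpha,
                                   indenter, thickness_nm, bec)
    force = params.E1 * b_plr + params.eta * b_visc
    t = np.asarray(t_s, dtype=float)
    return TingSolution(t_s=t, delta_nm=np.asarray(delta_nm, dtype=float),
                        tm_s=float(t[tm_index]), t1_s=t1, force_nN=force)
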