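"""Closed-form contact mechanics and rheology.

Spherical (parabolic) indentation of an incompressible soft sample:

    F(delta) = 4*sqrt(R) / (3*(1 - nu**2)) * f_BEC(delta) * E * delta**1.5

with a multiplicative bottom-effect correction ``f_BEC`` for samples of
finite thickness bonded to a rigid support, and a power-law rheology (PLR)
relaxation modulus

    E(t) = E1 * t**(-alpha)        (+ eta * dirac(t), handled by the Ting solver)

Unit contract (uniform across the package): lengths in nm, forces in nN,
moduli in Pa, viscosity in Pa*s, time in s.  Conversion to SI happens
inside these functions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "Indenter",
    "PLRParams",
    "BECModel",
    "hertz_force",
    "relaxation_modulus",
    "bec_factor",
    "hertz_prefactor",
]

#: Dimitriadis-style series coefficients for a spherical indenter on a
#: finite sample bonded to a rigid substrate, incompressible limit
#: (powers 1..4 of chi = sqrt(R*delta)/h).
BONDED_SPHERE_COEFFS = (1.133, 1.497, 1.469, 0.755)

_NM = 1e-9  # nm -> m
_NN = 1e9   # N -> nN


@dataclass(frozen=True)
class Indenter:
    """Spherical probe tip plus the sample's Poisson ratio.

    Parameters
    ----------
    radius_nm : float
        Tip radius R in nm.  Must be positive.  The probe family used for
        live-cell fast force volume has a nominal apex radius near 70 nm,
        which is the package default elsewhere; it is configuration, not
        a constant.
    poisson_nu : float
        Poisson's ratio of the sample, assumed time-independent.
        Default 0.5 (incompressible).
    """

    radius_nm: float = 70.0
    poisson_nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise DomainError(f"tip radius must be > 0, got {self.radius_nm}")
        if not (0.0 <= self.poisson_nu <= 0.5 + 1e-9):
            raise DomainError(f"Poisson ratio must be in [0, 0.5], got {self.poisson_nu}")


@dataclass(frozen=True)
class PLRParams:
    """Power-law rheology material state.

    E1 is the relaxation modulus at t = 1 s (Pa); alpha the power-law
    exponent (0 = solid-like, 1 = fluid-like); eta a Newtonian viscous
    term (Pa*s) entering E(t) as an instantaneous Dirac contribution.
    """

    E1: float
    alpha: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if not self.E1 > 0:
            raise DomainError(f"E1 must be > 0, got {self.E1}")
        if not (0.0 <= self.alpha <= 1.0):
            raise DomainError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.eta < 0:
            raise DomainError(f"eta must be >= 0, got {self.eta}")


@dataclass(frozen=True)
class BECModel:
    """Bottom-effect correction model.

    kind='none' is the semi-infinite sample (factor identically 1);
    kind='bonded_sphere_polynomial' is the polynomial series in
    chi = sqrt(R*delta)/h for a sample bonded to a rigid support.
    """

    kind: str = "bonded_sphere_polynomial"
    coefficients: tuple = field(default=BONDED_SPHERE_COEFFS)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "bonded_sphere_polynomial"):
            raise DomainError(f"unknown BEC kind {self.kind!r}")


#: Semi-infinite sample: no correction.
BEC_NONE = BECModel(kind="none")


def hertz_prefactor(indenter: Indenter) -> float:
    """Prefactor 4*sqrt(R)/(3*(1-nu^2)) such that F[nN] = pref * E[Pa] * delta[nm]^1.5.

    Includes the nm/nN unit conversion.
    """
    r_m = indenter.radius_nm * _NM
    c_si = 4.0 * np.sqrt(r_m) / (3.0 * (1.0 - indenter.poisson_nu**2))
    # delta^1.5 supplied in nm^1.5 -> multiply by _NM^1.5; N -> nN multiply by _NN
    return c_si * _NM**1.5 * _NN


def bec_factor(delta_nm, thickness_nm, indenter: Indenter, bec: BECModel = BEC_NONE):
    """Dimensionless bottom-effect correction factor f_BEC(delta).

    >= 1 everywhere, -> 1 as thickness -> infinity, grows as the
    indentation approaches the sample thickness.  Raises DomainError on
    negative indentation, non-positive thickness, or full penetration
    (delta >= thickness).
    """
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation depth must be >= 0")
    thickness = np.asarray(thickness_nm, dtype=float)
    if np.any(thickness <= 0):
        raise DomainError("sample thickness must be > 0")
    if bec.kind == "none":
        return np.ones_like(delta) if delta.ndim else 1.0
    finite = np.isfinite(thickness)
    if np.any(finite & (delta >= thickness)):
        raise DomainError("indentation >= sample thickness (full penetration)")
    with np.errstate(divide="ignore"):
        chi = np.sqrt(indenter.radius_nm * delta) / thickness
    chi = np.where(finite, chi, 0.0)
    factor = np.ones_like(chi)
    for power, coef in enumerate(bec.coefficients, start=1):
        factor = factor + coef * chi**power
    return factor if factor.ndim else float(factor)


def hertz_force(delta_nm, E_pa, indenter: Indenter,
                thickness_nm=np.inf, bec: BECModel = BEC_NONE):
    """Spherical-indenter contact force, nN.

    F = 4*sqrt(R)/(3*(1-nu^2)) * f_BEC(delta) * E * delta^(3/2),
    with delta in nm, E in Pa.  Strictly increasing in delta, linear in E.
    """
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation depth must be >= 0")
    if not E_pa > 0:
        raise DomainError(f"modulus must be > 0, got {E_pa}")
    factor = bec_factor(delta, thickness_nm, indenter, bec)
    out = hertz_prefactor(indenter) * E_pa * factor * delta**1.5
    return out if out.ndim else float(out)


def relaxation_modulus(t_s, params: PLRParams):
    """Pointwise PLR relaxation modulus E(t) = E1 * t^(-alpha), Pa.

    The Dirac viscous term is excluded from pointwise evaluation; the Ting
    solver applies it as eta * d(delta^{3/2})/dt.  Requires t > 0.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t <= 0):
        raise DomainError("relaxation modulus requires t > 0")
    out = params.E1 * t ** (-params.alpha)
    return out if out.ndim else float(out)
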