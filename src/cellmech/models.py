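"""Model/Results classes for per-curve elastic and viscoelastic fitting.

`HertzModel` fits the apparent Young's modulus to the approach phase;
`TingModel` fits power-law-rheology parameters (E1, alpha, eta) to the
full approach-retract record through the hereditary-integral forward
model.  Both follow the model-object convention: build from data, call
``.fit()``, get a Results object with estimates, standard errors,
diagnostics and ``summary()``.

The Ting force is linear in (E1, eta) at fixed alpha, so the fit is a
1-d search over alpha (coarse grid plus bounded refinement) with a
non-negative linear least-squares inner solve — deterministic, no
starting-point sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .contact import BEC_NONE, BECModel, Indenter, PLRParams, bec_factor, hertz_prefactor
from .curve import (ContactEstimate, ForceCurve, IndentationHistory,
                    compute_indentation_history, decimate_curve,
                    detect_contact_point)
from .errors import MissingRetract, NoContact
from .ting import ting_basis

#: large finite objective for inadmissible trials (inf would make
#: scipy's bounded minimiser emit arithmetic warnings)
_PENALTY = 1e250

__all__ = ["FitConfig", "HertzModel", "HertzResults", "TingModel", "TingResults",
           "fit_hertz", "fit_ting"]


@dataclass
class FitConfig:
    """Shared fitting options.

    fit_range: indentation window as fractions of max delta; samples
    outside are excluded from the residual (contact-region noise below,
    deep-indentation model error above).  refine_contact optimises a
    continuous contact-position offset (in z) around the detected sample.
    """

    fit_range: tuple = (0.10, 0.90)
    refine_contact: bool = True
    refine_span_steps: float = 4.0     # +/- z-grid steps searched
    #: eta is nearly degenerate with (E1, alpha) on trigger-limited
    #: ramps; by default the Newtonian term is held at 0 (standard
    #: practice) and only fitted on request
    fit_eta: bool = False
    alpha_grid: int = 21
    thickness_nm: float = np.inf
    bec: BECModel = field(default_factory=lambda: BEC_NONE)
    #: long curves are block-averaged down to this many samples before
    #: fitting (0 disables); see curve.decimate_curve
    max_curve_samples: int = 600


def _approach_window(delta: np.ndarray, tm_index: int, fit_range) -> np.ndarray:
    lo, hi = fit_range
    dmax = delta[: tm_index + 1].max()
    mask = np.zeros(delta.size, dtype=bool)
    mask[: tm_index + 1] = (delta[: tm_index + 1] >= lo * dmax) & \
                           (delta[: tm_index + 1] <= hi * dmax)
    return mask


def _full_window(delta: np.ndarray, tm_index: int, fit_range) -> np.ndarray:
    lo, _ = fit_range
    dmax = delta.max()
    mask = delta >= lo * dmax
    mask[tm_index] = True
    return mask


class _ResultsBase:
    """Shared diagnostics for curve-fit results."""

    model_tag: str = ""

    @property
    def resid(self) -> np.ndarray:
        return self.measured_nN - self.fitted_nN

    @property
    def rms_nN(self) -> float:
        r = self.resid
        return float(np.sqrt(np.mean(r * r))) if r.size else np.nan

    def summary(self) -> str:
        lines = [f"{self.model_tag} fit: n={self.nobs}, "
                 f"rms={self.rms_nN:.4g} nN, converged={self.converged}"]
        for name, val, se in self._param_rows():
            se_s = f" +/- {se:.4g}" if np.isfinite(se) else ""
            lines.append(f"  {name:>10s} = {val:.6g}{se_s}")
        lines.append(f"  contact z0 = {self.contact.z0_nm + self.contact_shift_nm:.1f} nm "
                     f"(refined by {self.contact_shift_nm:+.2f} nm)")
        return "\n".join(lines)


@dataclass
class HertzResults(_ResultsBase):
    """Apparent Young's modulus from the approach phase."""

    E_pa: float
    E_stderr_pa: float
    contact: ContactEstimate
    contact_shift_nm: float
    history: IndentationHistory
    measured_nN: np.ndarray
    fitted_nN: np.ndarray
    nobs: int
    converged: bool
    model_tag: str = "hertz"

    def _param_rows(self):
        return [("YM (Pa)", self.E_pa, self.E_stderr_pa)]

    @property
    def params_dict(self) -> dict:
        return {"YM_pa": self.E_pa}


@dataclass
class TingResults(_ResultsBase):
    """Power-law rheology parameters from the full approach-retract record."""

    params: PLRParams
    E1_stderr_pa: float
    alpha_stderr: float
    eta_stderr: float
    contact: ContactEstimate
    contact_shift_nm: float
    history: IndentationHistory
    measured_nN: np.ndarray
    fitted_nN: np.ndarray
    t1_s: np.ndarray
    nobs: int
    converged: bool
    model_tag: str = "ting_plr"

    def _param_rows(self):
        return [("E1 (Pa)", self.params.E1, self.E1_stderr_pa),
                ("alpha", self.params.alpha, self.alpha_stderr),
                ("eta (Pa s)", self.params.eta, self.eta_stderr)]

    @property
    def params_dict(self) -> dict:
        return {"E1_pa": self.params.E1, "alpha": self.params.alpha,
                "eta_pa_s": self.params.eta}


class HertzModel:
    """Elastic spherical-indentation model for one force curve.

    Fits F = pref * f_BEC(delta) * E * delta^{3/2} to the approach by
    linear least squares in E, optionally refining the contact position.
    """

    def __init__(self, curve: ForceCurve, config: Optional[FitConfig] = None,
                 contact: Optional[ContactEstimate] = None):
        self.config = config or FitConfig()
        if contact is None:
            curve = decimate_curve(curve, self.config.max_curve_samples)
        self.curve = curve
        self.contact = contact

    def _deltas(self, contact: ContactEstimate):
        hist = compute_indentation_history(self.curve, contact)
        if hist.max_delta_nm <= 0:
            raise NoContact("zero indentation over the whole record")
        return hist

    def _solve_E(self, delta: np.ndarray, force: np.ndarray, tm_index: int):
        cfg = self.config
        mask = _approach_window(delta, tm_index, cfg.fit_range)
        if mask.sum() < 4:
            mask = np.zeros_like(mask)
            mask[: tm_index + 1] = delta[: tm_index + 1] > 0
        d = delta[mask]
        g = np.atleast_1d(bec_factor(d, cfg.thickness_nm, self.curve.probe, cfg.bec))
        x = hertz_prefactor(self.curve.probe) * g * d**1.5
        y = force[mask]
        xx = float(np.dot(x, x))
        e_hat = max(float(np.dot(x, y)) / xx, 1e-12) if xx > 0 else np.nan
        resid = y - e_hat * x
        sse = float(np.dot(resid, resid))
        return e_hat, sse, xx, mask

    def fit(self) -> HertzResults:
        contact = self.contact or detect_contact_point(self.curve)
        hist = self._deltas(contact)
        cfg = self.config
        delta0 = hist.delta_nm
        shift = 0.0
        converged = True

        def sse_at(sh: float):
            d = np.clip(delta0 - sh, 0.0, None)
            if d[: hist.tm_index + 1].max() <= 0:
                return _PENALTY, np.nan, 0.0, None
            e, sse, xx, mask = self._solve_E(d, hist.force_nN, hist.tm_index)
            return sse, e, xx, mask

        if cfg.refine_contact:
            z_app = self.curve.z_nm[: self.curve.turn_index + 1]
            step = float(np.median(np.abs(np.diff(z_app)))) or 1.0
            span = cfg.refine_span_steps * step
            res = optimize.minimize_scalar(lambda s: sse_at(s)[0],
                                           bounds=(-span, span), method="bounded",
                                           options={"xatol": step * 1e-3})
            shift = float(res.x)
            converged = bool(res.success)
        sse, e_hat, xx, mask = sse_at(shift)
        if not np.isfinite(e_hat):
            raise NoContact("no usable indentation window")
        nobs = int(mask.sum())
        sigma2 = sse / max(nobs - 1, 1)
        stderr = float(np.sqrt(sigma2 / xx)) if xx > 0 else np.nan
        d = np.clip(delta0 - shift, 0.0, None)
        g = np.atleast_1d(bec_factor(d, cfg.thickness_nm, self.curve.probe, cfg.bec))
        fitted = hertz_prefactor(self.curve.probe) * g * d**1.5 * e_hat
        return HertzResults(E_pa=e_hat, E_stderr_pa=stderr, contact=contact,
                            contact_shift_nm=shift, history=hist,
                            measured_nN=hist.force_nN[mask], fitted_nN=fitted[mask],
                            nobs=nobs, converged=converged)


class TingModel:
    """PLR viscoelastic indentation model for one approach-retract curve.

    The contact position is taken from a preliminary Hertz fit (shared
    refinement); alpha is profiled on a grid and refined, with (E1, eta)
    solved by non-negative linear least squares at each alpha.
    """

    def __init__(self, curve: ForceCurve, config: Optional[FitConfig] = None,
                 contact: Optional[ContactEstimate] = None):
        if not curve.has_retract:
            raise MissingRetract("viscoelastic fitting needs a retract phase")
        self.config = config or FitConfig()
        if contact is None:
            curve = decimate_curve(curve, self.config.max_curve_samples)
        self.curve = curve
        self.contact = contact

    def fit(self) -> TingResults:
        cfg = self.config
        hertz = HertzModel(self.curve, cfg, contact=self.contact).fit()
        contact = hertz.contact
        hist = hertz.history
        probe = self.curve.probe
        delta0 = hist.delta_nm
        z_app = self.curve.z_nm[: self.curve.turn_index + 1]
        step = float(np.median(np.abs(np.diff(z_app)))) or 1.0
        span = cfg.refine_span_steps * step

        cache: dict = {}

        def solve(alpha: float, shift: float):
            key = (round(float(alpha), 6), round(float(shift), 4))
            if key in cache:
                return cache[key]
            delta = np.clip(delta0 - shift, 0.0, None)
            if delta.max() <= 0:
                return (_PENALTY, np.nan, np.nan, None, None, None, None, None)
            tm = hist.tm_index
            mask = _full_window(delta, tm, cfg.fit_range)
            if mask.sum() < 4:
                return (_PENALTY, np.nan, np.nan, None, None, None, None, None)
            y = hist.force_nN[mask]
            b1, b2, t1 = ting_basis(hist.t_s, delta, tm, alpha, probe,
                                    cfg.thickness_nm, cfg.bec)
            if cfg.fit_eta:
                A = np.column_stack((b1[mask], b2[mask]))
                coef, _ = optimize.nnls(A, y)
                e1, eta = float(coef[0]), float(coef[1])
            else:
                x = b1[mask]
                e1 = max(float(np.dot(x, y)) / float(np.dot(x, x)), 1e-12)
                eta = 0.0
            pred = e1 * b1 + eta * b2
            r = y - pred[mask]
            # compare SSE across shifts on a per-sample basis (mask size varies)
            out = (float(np.mean(r * r)), e1, eta, b1, b2, t1, pred, mask)
            cache[key] = out
            return out

        def refine_alpha(a0: float, shift: float, width: float):
            lo, hi = max(a0 - width, 0.0), min(a0 + width, 1.0)
            if hi <= lo:
                return a0, True
            res = optimize.minimize_scalar(lambda a: solve(a, shift)[0],
                                           bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-4})
            a_new = float(res.x)
            if solve(a_new, shift)[0] > solve(a0, shift)[0]:
                a_new = a0
            return a_new, bool(res.success)

        # stage 1: alpha profile on a coarse grid at the Hertz-refined contact
        shift_hat = hertz.contact_shift_nm if cfg.refine_contact else 0.0
        grid = np.linspace(0.0, 1.0, cfg.alpha_grid)
        sse_grid = [solve(a, shift_hat)[0] for a in grid]
        alpha_hat = float(grid[int(np.argmin(sse_grid))])
        alpha_hat, converged = refine_alpha(alpha_hat, shift_hat,
                                            width=1.05 / (cfg.alpha_grid - 1))
        # stage 2: alternate contact-shift and alpha refinement (the Hertz
        # contact is biased on viscoelastic curves; E1 is very sensitive
        # to a contact error)
        if cfg.refine_contact:
            for _ in range(2):
                res = optimize.minimize_scalar(
                    lambda s: solve(alpha_hat, s)[0],
                    bounds=(shift_hat - span, shift_hat + span),
                    method="bounded", options={"xatol": step * 1e-3})
                if solve(alpha_hat, float(res.x))[0] <= solve(alpha_hat, shift_hat)[0]:
                    shift_hat = float(res.x)
                alpha_hat, ok = refine_alpha(alpha_hat, shift_hat, width=0.06)
                converged = converged and ok
        msse, e1, eta, b1, b2, t1, pred, mask = solve(alpha_hat, shift_hat)
        if not np.isfinite(msse):
            raise NoContact("no usable indentation window")
        y = hist.force_nN[mask]
        sse = msse * int(mask.sum())
        e1 = max(e1, 1e-12)

        nobs = int(mask.sum())
        sigma2 = sse / max(nobs - 3, 1)
        # linear covariance of (E1, eta) at alpha_hat
        A = np.column_stack((b1[mask], b2[mask]))
        ata = A.T @ A
        try:
            cov = sigma2 * np.linalg.inv(ata)
            se_e1, se_eta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            se_e1 = se_eta = np.nan
        # alpha stderr from the profile-SSE curvature
        h = 0.01
        a_lo, a_hi = max(alpha_hat - h, 0.0), min(alpha_hat + h, 1.0)
        curv = (solve(a_lo, shift_hat)[0] + solve(a_hi, shift_hat)[0]
                - 2.0 * msse) * nobs / ((0.5 * (a_hi - a_lo)) ** 2)
        se_alpha = float(np.sqrt(2.0 * sigma2 / curv)) if curv > 0 else np.nan

        return TingResults(params=PLRParams(E1=e1, alpha=min(max(alpha_hat, 0.0), 1.0),
                                            eta=eta),
                           E1_stderr_pa=se_e1, alpha_stderr=se_alpha, eta_stderr=se_eta,
                           contact=contact, contact_shift_nm=shift_hat,
                           history=hist, measured_nN=y, fitted_nN=pred[mask],
                           t1_s=t1, nobs=nobs, converged=converged)


def fit_hertz(curve: ForceCurve, config: Optional[FitConfig] = None) -> HertzResults:
    """Functional wrapper: apparent-YM fit of the approach phase."""
    return HertzModel(curve, config).fit()


def fit_ting(curve: ForceCurve, config: Optional[FitConfig] = None) -> TingResults:
    """Functional wrapper: PLR viscoelastic fit of the full record."""
    return TingModel(curve, config).fit()
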