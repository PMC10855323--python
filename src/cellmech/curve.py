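"""Force-curve containers, calibration, contact detection and indentation history.

A force curve is one approach-retract ramp: time t (s), piezo extension
z (nm, increasing toward the sample during approach) and either raw
photodiode deflection (V) or calibrated force (nN).  Calibration follows
force = k * sensitivity * deflection with the cantilever spring constant
k (N/m) and the optical-lever deflection sensitivity (nm/V).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .contact import Indenter
from .errors import ConfigurationError, DomainError, NoContact

__all__ = [
    "ForceCurve",
    "ContactEstimate",
    "IndentationHistory",
    "calibrate_curve",
    "decimate_curve",
    "detect_contact_point",
    "compute_indentation_history",
]

#: absolute noise floor used when a curve is (numerically) noise-free, nN
NOISE_FLOOR_NN = 1e-6


@dataclass
class ForceCurve:
    """One calibrated (or raw) F-Z record.

    t_s must be strictly increasing; z_nm is piezo extension toward the
    sample.  Exactly one of force_nN / deflection_V must be present for a
    raw curve; after :func:`calibrate_curve` force_nN is filled.
    turn_index is the last approach sample (maximum extension); if None
    it is derived from argmax(z).
    """

    t_s: np.ndarray
    z_nm: np.ndarray
    force_nN: Optional[np.ndarray] = None
    deflection_V: Optional[np.ndarray] = None
    spring_constant_N_per_m: float = 0.1
    sensitivity_nm_per_V: Optional[float] = None
    turn_index: Optional[int] = None
    probe: Indenter = field(default_factory=Indenter)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.shape != self.z_nm.shape:
            raise DomainError("t and z must be matching 1-d arrays")
        if np.any(np.diff(self.t_s) <= 0):
            raise DomainError("time samples must be strictly increasing")
        if not self.spring_constant_N_per_m > 0:
            raise ConfigurationError("spring constant must be > 0")
        if self.force_nN is None and self.deflection_V is None:
            raise ConfigurationError("curve needs force_nN or deflection_V")
        if self.force_nN is not None:
            self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.deflection_V is not None:
            self.deflection_V = np.asarray(self.deflection_V, dtype=float)
        if self.turn_index is None:
            self.turn_index = int(np.argmax(self.z_nm))

    @property
    def n_samples(self) -> int:
        return self.t_s.size

    @property
    def has_retract(self) -> bool:
        return self.turn_index < self.n_samples - 1


def _block_mean(a: np.ndarray, block: int) -> np.ndarray:
    nb = a.size // block
    out = a[: nb * block].reshape(nb, block).mean(axis=1)
    if a.size % block:
        out = np.append(out, a[nb * block:].mean())
    return out


def decimate_curve(curve: ForceCurve, target_n: int) -> ForceCurve:
    """Block-average a long curve down to about target_n samples.

    Averaging (rather than striding) keeps the noise-reduction benefit
    of fast sampling while bounding the hereditary-integral cost, which
    grows quadratically with curve length.  Approach and retract are
    averaged separately so the turnaround is not smeared.  Curves at or
    below the target are returned unchanged.
    """
    n = curve.n_samples
    if target_n <= 0 or n <= target_n:
        return curve
    block = int(np.ceil(n / target_n))

    def condense(a: Optional[np.ndarray]):
        if a is None:
            return None
        app = _block_mean(a[: curve.turn_index + 1], block)
        ret = _block_mean(a[curve.turn_index + 1:], block)
        return np.concatenate((app, ret))

    t = condense(curve.t_s)
    n_app = _block_mean(curve.z_nm[: curve.turn_index + 1], block).size
    return replace(curve, t_s=t, z_nm=condense(curve.z_nm),
                   force_nN=condense(curve.force_nN),
                   deflection_V=condense(curve.deflection_V),
                   turn_index=n_app - 1)


def calibrate_curve(curve: ForceCurve) -> ForceCurve:
    """Convert raw deflection (V) to force (nN); idempotent on calibrated curves.

    force[nN] = k[N/m] * sensitivity[nm/V] * deflection[V].
    """
    if curve.force_nN is not None:
        return curve
    if curve.sensitivity_nm_per_V is None or not curve.sensitivity_nm_per_V > 0:
        raise ConfigurationError("deflection sensitivity (nm/V) required for calibration")
    force = (curve.spring_constant_N_per_m * curve.sensitivity_nm_per_V
             * curve.deflection_V)
    return replace(curve, force_nN=force)


@dataclass
class ContactEstimate:
    """Contact point plus the pre-contact baseline model (offset + slope*z)."""

    index: int                     # sample index of contact, within approach
    z0_nm: float                   # piezo extension at contact
    baseline_offset_nN: float
    baseline_slope_nN_per_nm: float
    noise_rms_nN: float
    quality: float                 # 1 - SSE/SST of the piecewise fit

    def corrected_force(self, curve: ForceCurve) -> np.ndarray:
        """Baseline-subtracted force over the whole curve."""
        return (curve.force_nN - self.baseline_offset_nN
                - self.baseline_slope_nN_per_nm * curve.z_nm)


def _line_fit(z: np.ndarray, f: np.ndarray):
    slope, offset = np.polyfit(z, f, 1)
    resid = f - (offset + slope * z)
    return offset, slope, float(np.dot(resid, resid))


def detect_contact_point(curve: ForceCurve, window: int = 60,
                         noise_floor_nN: float = NOISE_FLOOR_NN) -> ContactEstimate:
    """Locate tip-sample contact on the approach phase.

    A linear baseline is estimated from the early approach; candidate
    contact positions around the first sustained excursion above the noise
    are scored by a piecewise model (line up to the candidate, line plus
    A*(z - z_c)^{3/2} beyond it) and the residual minimiser is returned.

    Raises NoContact when no segment exceeds the noise floor.
    """
    if curve.force_nN is None:
        raise ConfigurationError("curve must be calibrated first")
    n_app = curve.turn_index + 1
    if n_app < 50:
        raise DomainError(f"approach phase too short ({n_app} samples)")
    z = curve.z_nm[:n_app]
    f = curve.force_nN[:n_app]

    base_n = max(10, n_app // 3)
    offset0, slope0, sse0 = _line_fit(z[:base_n], f[:base_n])
    noise = max(float(np.sqrt(sse0 / base_n)), noise_floor_nN)
    fc = f - (offset0 + slope0 * z)

    thresh = 5.0 * noise
    above = fc > thresh
    # first index from which the signal stays above threshold to the end
    stays = np.flip(np.logical_and.accumulate(np.flip(above)))
    cross = np.nonzero(stays)[0]
    if cross.size == 0 or float(np.max(fc)) < 3.0 * noise:
        raise NoContact("no approach segment exceeds the noise floor")
    i_cross = int(cross[0])

    lo = max(5, i_cross - window)
    hi = min(n_app - 5, i_cross + max(5, window // 4))
    best = None
    sst = float(np.dot(f - f.mean(), f - f.mean())) or 1.0
    for j in range(lo, hi):
        off_j, slp_j, sse_pre = _line_fit(z[: j + 1], f[: j + 1])
        resid_post = f[j:] - (off_j + slp_j * z[j:])
        x = (z[j:] - z[j]) ** 1.5
        xx = float(np.dot(x, x))
        amp = max(float(np.dot(x, resid_post)) / xx, 0.0) if xx > 0 else 0.0
        r = resid_post - amp * x
        sse = sse_pre + float(np.dot(r, r))
        if best is None or sse < best[0]:
            best = (sse, j, off_j, slp_j)
    sse, j, off_j, slp_j = best

    # continuous sub-sample refinement of the contact position: slide z0
    # between grid nodes with the baseline held fixed.  Both a Hertzian
    # (power 3/2) and a linear contact shape are tried -- the latter is
    # exact for (near-)rigid samples, whose kink the 3/2 model biases.
    resid_all = f - (off_j + slp_j * z)

    def sse_at(z0: float, power: float) -> float:
        x = np.clip(z - z0, 0.0, None) ** power
        xx = float(np.dot(x, x))
        amp = max(float(np.dot(x, resid_all)) / xx, 0.0) if xx > 0 else 0.0
        r = resid_all - amp * x
        return float(np.dot(r, r))

    step = float(np.median(np.abs(np.diff(z)))) or 1.0
    from scipy.optimize import minimize_scalar
    z0 = float(z[j])
    for power in (1.5, 1.0):
        res = minimize_scalar(sse_at, args=(power,),
                              bounds=(z[j] - 2 * step, z[j] + 2 * step),
                              method="bounded", options={"xatol": step * 1e-3})
        if res.fun < sse:
            sse, z0 = float(res.fun), float(res.x)
    return ContactEstimate(index=j, z0_nm=z0,
                           baseline_offset_nN=off_j, baseline_slope_nN_per_nm=slp_j,
                           noise_rms_nN=noise, quality=1.0 - sse / sst)


@dataclass
class IndentationHistory:
    """Indentation vs time from contact, ready for the Ting solver.

    Covers contact onset through the retract sample where contact is
    lost (indentation returns to zero); delta is clipped at 0.
    """

    t_s: np.ndarray          # origin at contact
    delta_nm: np.ndarray
    force_nN: np.ndarray     # baseline-corrected measured force, same samples
    tm_index: int            # turnaround (maximum indentation) sample
    start_index: int         # index of the first sample in the parent curve

    @property
    def tm_s(self) -> float:
        return float(self.t_s[self.tm_index])

    @property
    def max_delta_nm(self) -> float:
        return float(np.max(self.delta_nm))


def compute_indentation_history(curve: ForceCurve,
                                contact: ContactEstimate) -> IndentationHistory:
    """delta(t) = (z - z_contact) - deflection, from contact to contact loss.

    Deflection (nm) is baseline-corrected force divided by the spring
    constant.  The time origin is shifted to the contact sample and tm is
    the sample of maximum indentation.  A perfectly rigid sample yields
    delta identically zero; a history whose raw indentation never reaches
    zero from below raises NoContact.
    """
    fc = contact.corrected_force(curve)
    defl_nm = fc / curve.spring_constant_N_per_m
    j = contact.index
    delta_raw = (curve.z_nm[j:] - contact.z0_nm) - defl_nm[j:]
    if np.max(delta_raw) < -1e-9:
        raise NoContact("indentation never exceeds zero")
    turn = curve.turn_index - j
    # cut where contact is lost on the retract: either the indentation
    # returns to zero or the force does (a viscoelastic sample can stay
    # geometrically overlapped after the contact force vanishes)
    end = delta_raw.size
    floor = max(2.0 * contact.noise_rms_nN, 1e-9)
    lost = (delta_raw[turn + 1:] <= 0.0) | (fc[j + turn + 1:] <= floor)
    post = np.nonzero(lost)[0]
    if post.size:
        end = turn + 1 + int(post[0]) + 1   # include the crossing sample
    delta = np.clip(delta_raw[:end], 0.0, None)
    t = curve.t_s[j:j + end] - curve.t_s[j]
    # the physical turnaround is the piezo reversal (argmax of noisy
    # delta can land on a neighbouring sample)
    return IndentationHistory(t_s=t, delta_nm=delta, force_nN=fc[j:j + end],
                              tm_index=turn, start_index=j)
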