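"""Ground-truth generators for every pipeline stage.

Single F-Z curves come from the quasi-static force balance between the
cantilever (spring constant k) and the viscoelastic contact force of the
Ting forward model: at every piezo position z the deflection d solves
k*d = F(delta history with delta = (z - z_contact) - d).  Cantilever
dynamics are neglected (the stated ramp speeds are quasi-static for
these cells).  Maps place a spherical-cap phantom cell on a rigid
substrate; per-pixel thickness drives the bottom-effect correction.
Cohorts draw per-cell material parameters and geometry from presets
shipped in ``presets.yaml``.  Assay generators produce log-normal-shaped
ROS bursts and two-component log-normal cytometry mixtures with
closed-form ground truth.

Every generator is deterministic under a fixed seed and embeds its
ground truth and seed in the returned provenance record.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .assays import CytometrySample, KineticsTrace
from .contact import (BEC_NONE, BECModel, Indenter, PLRParams, bec_factor,
                      hertz_prefactor)
from .curve import ForceCurve
from .errors import DomainError, GenerationError
from .fvmap import ForceVolumeMap
from .ting import force_last

__all__ = [
    "CurveSpec", "CohortPreset", "load_presets",
    "simulate_curve", "simulate_cell_map", "simulate_cohort",
    "simulate_kinetics_trace", "simulate_cytometry_sample",
]


@dataclass
class CurveSpec:
    """Everything needed to synthesise one F-Z curve, plus its ground truth.

    Ramp defaults follow the stated acquisition: 3 um vertical ramp,
    183 um/s piezo speed, 1 nN trigger force (upper end of the stated
    0.5-1 nN range), 0.1 N/m spring constant.  The 100 kHz sampling rate
    is a package choice (1.8 nm z-steps, a realistic capture rate).
    contact_z_nm is the piezo extension at first tip-sample contact in
    the map's global frame; the ramp starts approach_clearance_nm below.
    """

    params: PLRParams = field(default_factory=lambda: PLRParams(E1=2800.0))
    indenter: Indenter = field(default_factory=Indenter)
    thickness_nm: float = np.inf
    bec: BECModel = field(default_factory=lambda: BEC_NONE)
    spring_constant_N_per_m: float = 0.1
    ramp_distance_nm: float = 3000.0
    ramp_speed_nm_s: float = 183_000.0
    sampling_rate_hz: float = 100_000.0
    trigger_force_nN: float = 1.0
    contact_z_nm: float = 1000.0
    approach_clearance_nm: float = 1000.0
    baseline_offset_nN: float = 0.0
    baseline_slope_nN_per_nm: float = 0.0
    noise_rms_nN: float = 0.0
    rigid: bool = False
    #: indentation is capped at this fraction of a finite sample thickness;
    #: beyond it the compressed layer bottoms out on the rigid support and
    #: the residual travel loads the cantilever as a hard wall
    max_rel_indentation: float = 0.9
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ramp_speed_nm_s <= 0 or self.sampling_rate_hz <= 0:
            raise DomainError("ramp speed and sampling rate must be > 0")
        if self.noise_rms_nN < 0:
            raise DomainError("noise RMS must be >= 0")
        if self.trigger_force_nN <= 0:
            raise DomainError("trigger force must be > 0")
        if self.approach_clearance_nm >= self.ramp_distance_nm:
            raise GenerationError("spec yields zero contact: clearance >= ramp")


def _solve_elastic_delta(zrel: float, e1: float, pref: float, k: float,
                         thickness_nm: float, indenter, bec,
                         delta_cap: float) -> float:
    """delta solving k*(zrel - delta) = pref * g(delta) * E * delta^1.5.

    delta is confined to [0, delta_cap]; if the balance cannot be met
    below the cap the layer has bottomed out and delta = delta_cap.
    """
    if zrel <= 0:
        return 0.0
    upper = min(zrel, delta_cap)

    def f(d):
        g = bec_factor(d, thickness_nm, indenter, bec)
        return pref * g * e1 * d**1.5 - k * (zrel - d)

    if f(upper) <= 0:
        return upper
    return brentq(f, 0.0, upper, xtol=1e-6)


def simulate_curve(spec: CurveSpec, rng: Optional[np.random.Generator] = None):
    """Synthesise one F-Z curve; returns (ForceCurve, ground_truth dict).

    Force balance at every sample couples the Ting forward model to the
    cantilever; the approach turns around at the trigger force (or the
    ramp end), the retract runs back to the start.  Baseline tilt/offset
    and seeded Gaussian force noise are added afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate_hz
    dz = spec.ramp_speed_nm_s * dt
    n_app = int(np.floor(spec.ramp_distance_nm / dz))
    # spring-constant conversion: d[nm] = F[nN] / k[N/m]
    k = spec.spring_constant_N_per_m
    pref = hertz_prefactor(spec.indenter)
    elastic = (not spec.rigid) and spec.params.alpha == 0.0 and spec.params.eta == 0.0

    z_start = spec.contact_z_nm - spec.approach_clearance_nm
    z_list, f_list = [], []
    # contact history in time-from-contact coordinates (virtual zero node)
    hist_t: list = []
    hist_d: list = []
    contact_index = None
    tm_hist = None
    lost = False
    d_prev = 0.0
    delta_cap = (spec.max_rel_indentation * spec.thickness_nm
                 if np.isfinite(spec.thickness_nm) else np.inf)

    def contact_force(i_sample: int, zrel: float, retract: bool) -> float:
        """Solve the force balance at this sample; appends to the history."""
        nonlocal d_prev, lost
        if spec.rigid:
            return k * max(zrel, 0.0)
        if elastic:
            delta = _solve_elastic_delta(zrel, spec.params.E1, pref, k,
                                         spec.thickness_nm, spec.indenter,
                                         spec.bec, delta_cap)
            return k * (zrel - delta)
        t_now = i_sample * dt - t_contact
        hist_t.append(t_now)
        hist_d.append(0.0)
        tm = tm_hist if retract else len(hist_t) - 1
        d = d_prev
        for _ in range(60):
            delta = min(max(zrel - d, 0.0), delta_cap)
            hist_d[-1] = delta
            force = force_last(np.array(hist_t), np.array(hist_d), tm,
                               spec.params, spec.indenter, spec.thickness_nm,
                               spec.bec)
            if retract and force <= 0.0:
                lost = True
                return 0.0
            d_new = max(force / k, zrel - delta_cap)
            if abs(d_new - d) < 1e-5:
                d = d_new
                break
            d = d_new
        d_prev = d
        hist_d[-1] = min(max(zrel - d, 0.0), delta_cap)
        return k * d

    # ---- approach
    turn = None
    t_contact = 0.0
    for i in range(n_app):
        z = z_start + i * dz
        zrel = z - spec.contact_z_nm
        if zrel <= 0:
            z_list.append(z)
            f_list.append(0.0)
            continue
        if contact_index is None:
            contact_index = i
            # exact crossing time between samples i-1 and i
            t_contact = i * dt - zrel / spec.ramp_speed_nm_s
            hist_t.append(0.0)
            hist_d.append(0.0)
        force = contact_force(i, zrel, retract=False)
        z_list.append(z)
        f_list.append(force)
        if force >= spec.trigger_force_nN:
            turn = i
            break
    if contact_index is None:
        raise GenerationError("spec yields zero contact within the ramp")
    if turn is None:
        turn = n_app - 1
    tm_hist = len(hist_t) - 1 if not spec.rigid and not elastic else None

    # ---- retract, back to the start position
    i = turn
    z = z_list[-1]
    while z > z_start + 1e-9:
        i += 1
        z = max(z - dz, z_start)
        zrel = z - spec.contact_z_nm
        if zrel <= 0 or lost:
            force = 0.0
        else:
            force = contact_force(i, zrel, retract=True)
        z_list.append(z)
        f_list.append(force)

    t = np.arange(len(z_list)) * dt
    z_arr = np.array(z_list)
    f_contact = np.array(f_list)
    f_meas = (f_contact + spec.baseline_offset_nN
              + spec.baseline_slope_nN_per_nm * z_arr)
    if spec.noise_rms_nN > 0:
        f_meas = f_meas + rng.normal(0.0, spec.noise_rms_nN, f_meas.size)

    curve = ForceCurve(t_s=t, z_nm=z_arr, force_nN=f_meas,
                       spring_constant_N_per_m=k, turn_index=turn,
                       probe=spec.indenter,
                       meta={"ramp_distance_nm": spec.ramp_distance_nm,
                             "ramp_speed_nm_s": spec.ramp_speed_nm_s,
                             "trigger_force_nN": spec.trigger_force_nN})
    max_delta = float(np.max(np.clip(z_arr - spec.contact_z_nm - f_contact / k,
                                     0.0, None)))
    truth = {"params": spec.params, "contact_z_nm": spec.contact_z_nm,
             "contact_index": contact_index, "tm_index": turn,
             "max_delta_nm": max_delta,
             "thickness_nm": spec.thickness_nm, "seed": spec.seed,
             "spec": spec}
    return curve, truth


def _cap_height_um(x_um, y_um, apex_um: float, base_radius_um: float):
    """Spherical-cap height profile, zero outside the base circle."""
    rs = (base_radius_um**2 + apex_um**2) / (2.0 * apex_um)
    r2 = np.asarray(x_um) ** 2 + np.asarray(y_um) ** 2
    h = np.sqrt(np.clip(rs**2 - r2, 0.0, None)) - (rs - apex_um)
    return np.clip(h, 0.0, None)


def simulate_cell_map(apex_height_um: float, base_radius_um: float,
                      params: PLRParams, grid_n: int = 16, field_um: float = 30.0,
                      indenter: Optional[Indenter] = None,
                      center_um: tuple = (0.0, 0.0),
                      tilt_nm_per_um: tuple = (0.0, 0.0),
                      substrate_z_nm: float = 1000.0,
                      noise_rms_nN: float = 0.02,
                      bec: Optional[BECModel] = None,
                      seed: Optional[int] = None,
                      spec_overrides: Optional[dict] = None):
    """Force-volume map of one spherical-cap phantom cell on a rigid substrate.

    Per-pixel sample thickness follows the cap geometry (and drives the
    bottom-effect correction); substrate pixels are perfectly rigid.
    ``substrate_z_nm`` is the piezo extension at substrate contact in a
    flat, untilted frame; tilt adds a plane to all contact positions.
    Returns (ForceVolumeMap, ground_truth dict).  apex_height_um = 0
    gives a substrate-only map.
    """
    if grid_n < 8:
        raise DomainError("grid must be at least 8x8")
    if base_radius_um >= field_um / 2:
        raise GenerationError("cap does not fit in the field of view")
    indenter = indenter or Indenter()
    bec = bec if bec is not None else BECModel(kind="bonded_sphere_polynomial")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(grid_n * grid_n)

    px = field_um / grid_n
    coords = (np.arange(grid_n) + 0.5) * px - field_um / 2.0
    xx, yy = np.meshgrid(coords, coords)
    h_map = _cap_height_um(xx - center_um[0], yy - center_um[1],
                           apex_height_um, base_radius_um) if apex_height_um > 0 \
        else np.zeros((grid_n, grid_n))
    contact_z = (substrate_z_nm - h_map * 1000.0
                 + tilt_nm_per_um[0] * xx + tilt_nm_per_um[1] * yy)

    curves = np.empty((grid_n, grid_n), dtype=object)
    overrides = spec_overrides or {}
    for (i, j) in np.ndindex(grid_n, grid_n):
        rigid = h_map[i, j] <= 0.0
        thickness = h_map[i, j] * 1000.0 if not rigid else np.inf
        spec = CurveSpec(params=params, indenter=indenter,
                         thickness_nm=thickness, bec=bec,
                         contact_z_nm=float(contact_z[i, j]),
                         noise_rms_nN=noise_rms_nN, rigid=rigid,
                         **overrides)
        rng = np.random.default_rng(child_seeds[i * grid_n + j])
        curves[i, j], _ = simulate_curve(spec, rng=rng)

    truth = {"height_map_um": h_map, "contact_z_nm": contact_z,
             "params": params, "apex_height_um": apex_height_um,
             "base_radius_um": base_radius_um, "tilt_nm_per_um": tilt_nm_per_um,
             "seed": seed}
    fvmap = ForceVolumeMap(curves=curves, field_um=(field_um, field_um),
                           probe=indenter, ground_truth=truth)
    return fvmap, truth


@dataclass
class CohortPreset:
    """Per-cell sampling distributions for one condition group."""

    label: str
    e1_mean_kpa: float
    e1_sd_kpa: float
    alpha_mean: float
    alpha_sd: float = 0.05
    eta_pa_s: float = 0.0
    height_mean_um: float = 4.0
    height_cv: float = 0.05
    base_radius_um: float = 10.0
    n_cells: int = 20
    grid_n: int = 16
    field_um: float = 30.0

    def draw_cell(self, rng: np.random.Generator):
        """One admissible (PLRParams, apex height) draw (rejection sampling)."""
        cv2 = (self.e1_sd_kpa / self.e1_mean_kpa) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(self.e1_mean_kpa) - 0.5 * sigma**2
        e1_kpa = float(np.exp(rng.normal(mu, sigma)))
        for _ in range(1000):
            alpha = float(rng.normal(self.alpha_mean, self.alpha_sd))
            if 0.0 <= alpha <= 1.0:
                break
        else:
            raise GenerationError("alpha preset cannot produce admissible draws")
        s_h = np.sqrt(np.log1p(self.height_cv**2))
        m_h = np.log(self.height_mean_um) - 0.5 * s_h**2
        apex = float(np.exp(rng.normal(m_h, s_h)))
        return PLRParams(E1=e1_kpa * 1000.0, alpha=alpha, eta=self.eta_pa_s), apex


def load_presets(path: Optional[str] = None) -> dict:
    """Load cohort presets (packaged presets.yaml by default)."""
    if path is None:
        text = resources.files("cellmech").joinpath("presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    defaults = raw.get("defaults", {})
    out = {}
    for label, vals in raw["presets"].items():
        merged = {**defaults, **vals}
        merged.pop("eta", None)
        out[label] = CohortPreset(label=label, **{
            k: merged[k] for k in ("e1_mean_kpa", "e1_sd_kpa", "alpha_mean",
                                   "alpha_sd", "eta_pa_s", "height_mean_um",
                                   "height_cv", "base_radius_um", "n_cells",
                                   "grid_n", "field_um") if k in merged})
    return out


def simulate_cohort(control: CohortPreset, activated: CohortPreset,
                    seed: Optional[int] = None, n_cells: Optional[int] = None,
                    spec_overrides: Optional[dict] = None) -> list:
    """Independent phantom cells per preset; list of per-cell records.

    Each record is a dict with keys group, cell_id, fvmap, truth, seed.
    Cap centers get a small random sub-pixel offset so grid alignment
    does not bias apex sampling.  Requires >= 2 cells per group.
    """
    ss = np.random.SeedSequence(seed)
    records = []
    for preset in (control, activated):
        n = n_cells or preset.n_cells
        if n < 2:
            raise GenerationError("need at least 2 cells per group")
        for c in range(n):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            params, apex = preset.draw_cell(rng)
            px = preset.field_um / preset.grid_n
            off = rng.uniform(-0.5 * px, 0.5 * px, size=2)
            map_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            fvmap, truth = simulate_cell_map(
                apex_height_um=apex, base_radius_um=preset.base_radius_um,
                params=params, grid_n=preset.grid_n, field_um=preset.field_um,
                center_um=(float(off[0]), float(off[1])), seed=map_seed,
                spec_overrides=spec_overrides)
            truth["preset"] = preset.label
            records.append({"group": preset.label, "cell_id": c,
                            "fvmap": fvmap, "truth": truth, "seed": map_seed})
    return records


def simulate_kinetics_trace(peak_time_s: float = 300.0, peak_amplitude: float = 1000.0,
                            width_log: float = 0.5, baseline: float = 50.0,
                            noise_rms: float = 0.0, duration_s: float = 1800.0,
                            dt_s: float = 5.0, activator_time_s: float = 60.0,
                            seed: Optional[int] = None):
    """Seeded log-normal-shaped ROS burst; returns (KineticsTrace, truth).

    Signal = baseline + A*exp(-(ln(tau/tp))^2 / (2 w^2)), tau = t - t_act.
    The analytic baseline-free AUC over [t_act, T] is
    A * tp * w * sqrt(2 pi) * exp(w^2/2) * Phi((ln((T - t_act)/tp) - w^2)/w),
    recorded in the ground truth (full-window value plus a callable).
    """
    if peak_amplitude < 0:
        raise GenerationError("peak amplitude must be >= 0")
    if not (0.0 < peak_time_s < duration_s - activator_time_s):
        raise GenerationError("peak time must fall within the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    tau = t - activator_time_s
    sig = np.full_like(t, float(baseline))
    pos = tau > 0
    sig[pos] += peak_amplitude * np.exp(
        -0.5 * (np.log(tau[pos] / peak_time_s) / width_log) ** 2)
    if noise_rms > 0:
        sig = sig + rng.normal(0.0, noise_rms, sig.size)

    def auc_to(t_end_s: float) -> float:
        tau_end = t_end_s - activator_time_s
        if tau_end <= 0:
            return 0.0
        z = (np.log(tau_end / peak_time_s) - width_log**2) / width_log
        return float(peak_amplitude * peak_time_s * width_log * np.sqrt(2 * np.pi)
                     * np.exp(0.5 * width_log**2) * norm.cdf(z))

    trace = KineticsTrace(t_s=t, signal=sig, activator_time_s=activator_time_s)
    truth = {"auc": auc_to(duration_s), "auc_to": auc_to,
             "peak_time_s": peak_time_s, "peak_amplitude": peak_amplitude,
             "width_log": width_log, "baseline": baseline, "seed": seed}
    return trace, truth


def simulate_cytometry_sample(negative_mfi: float = 100.0, positive_mfi: float = 2000.0,
                              positive_fraction: float = 0.5, n_events: int = 10_000,
                              width_decades: float = 0.15,
                              seed: Optional[int] = None):
    """Two-component log-normal intensity mixture; returns (CytometrySample, truth).

    Component medians are the given MFIs; widths are log10-decades.
    Modes closer than 0.1 decade set a 'overlap_warning' flag in the
    truth record.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise DomainError("positive fraction must be in [0, 1]")
    if n_events < 100:
        raise DomainError("need at least 100 events")
    rng = np.random.default_rng(seed)
    n_pos = int(rng.binomial(n_events, positive_fraction))
    sigma = width_decades * np.log(10.0)
    neg = np.exp(rng.normal(np.log(negative_mfi), sigma, n_events - n_pos))
    pos = np.exp(rng.normal(np.log(positive_mfi), sigma, n_pos))
    intensity = rng.permutation(np.concatenate((neg, pos)))
    overlap = abs(np.log10(positive_mfi) - np.log10(negative_mfi)) < 0.1
    sample = CytometrySample(intensity=intensity,
                             meta={"overlap_warning": bool(overlap)})
    truth = {"positive_fraction": positive_fraction, "n_positive": n_pos,
             "negative_mfi": negative_mfi, "positive_mfi": positive_mfi,
             "overlap_warning": bool(overlap), "seed": seed}
    return sample, truth
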