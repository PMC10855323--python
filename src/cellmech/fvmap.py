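"""Force-volume map processing: topography, tilt, central-part filtering, aggregation.

A fast-force-volume map is a grid of force curves sharing probe
metadata.  Topography comes from per-pixel contact positions referenced
to the substrate plane; per-cell mechanics are aggregated over the
central part of each cell (top 50% of its height distribution), because
peripheral pixels are dominated by the F-actin-rich cortex at the cell
edge and by bottom-effect/thin-layer artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .contact import Indenter
from .curve import ForceCurve, detect_contact_point
from .errors import CellmechError, EmptyCell, EmptyMap, MissingRetract, NoContact
from .models import FitConfig, HertzModel, TingModel

__all__ = [
    "ForceVolumeMap", "CellRecord",
    "reconstruct_topography", "correct_tilt", "central_part_filter",
    "derive_cell_mask", "aggregate_cell", "fit_map", "analyze_map",
    "cohort_summary",
]


@dataclass
class ForceVolumeMap:
    """Grid of force curves with pixel geometry.

    curves is an object array (rows x cols) of ForceCurve (or None for
    skipped pixels); field_um the physical (width, height) of the scan;
    mask an optional integer cell-label image (0 = substrate).
    """

    curves: np.ndarray
    field_um: tuple
    probe: Indenter = field(default_factory=Indenter)
    mask: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=object)
        if self.curves.ndim != 2:
            raise CellmechError("curves must form a 2-d grid")
        if min(self.field_um) <= 0:
            raise CellmechError("physical field size must be positive")
        self._contacts: Optional[np.ndarray] = None

    @property
    def shape(self) -> tuple:
        return self.curves.shape

    def pixel_size_um(self) -> tuple:
        rows, cols = self.shape
        return self.field_um[0] / cols, self.field_um[1] / rows

    def contacts(self, refresh: bool = False) -> np.ndarray:
        """Per-pixel ContactEstimate (None where NoContact); cached."""
        if self._contacts is None or refresh:
            out = np.empty(self.shape, dtype=object)
            for (i, j), curve in np.ndenumerate(self.curves):
                if curve is None:
                    out[i, j] = None
                    continue
                try:
                    out[i, j] = detect_contact_point(curve)
                except (NoContact, CellmechError):
                    out[i, j] = None
            self._contacts = out
        return self._contacts


def _plane_fit(height: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Least-squares plane a + b*col + c*row over selected pixels, evaluated everywhere."""
    rows, cols = height.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    A = np.column_stack((np.ones(sel.sum()), cc[sel], rr[sel]))
    coef, *_ = np.linalg.lstsq(A, height[sel], rcond=None)
    return coef[0] + coef[1] * cc + coef[2] * rr


def _substrate_selector(height: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    finite = np.isfinite(height)
    if mask is not None:
        sel = (np.asarray(mask) == 0) & finite
        if sel.sum() >= 3:
            return sel
    # lowest decile of finite heights
    vals = height[finite]
    if vals.size == 0:
        raise EmptyMap("no finite heights to reference")
    q = np.quantile(vals, 0.10)
    return finite & (height <= q)


def reconstruct_topography(fvmap: ForceVolumeMap, reference: bool = True) -> np.ndarray:
    """Height map (um) from per-pixel contact positions.

    The piezo extension at contact is smaller over taller features, so
    raw height is the negated contact extension; with ``reference`` the
    substrate plane (mask==0 pixels, else the lowest-decile plane fit)
    is subtracted.  Pixels without contact are NaN; raises EmptyMap when
    every pixel is NoContact.
    """
    contacts = fvmap.contacts()
    height = np.full(fvmap.shape, np.nan)
    for (i, j), c in np.ndenumerate(contacts):
        if c is not None:
            height[i, j] = -c.z0_nm / 1000.0
    if not np.isfinite(height).any():
        raise EmptyMap("all pixels are NoContact")
    if reference:
        sel = _substrate_selector(height, fvmap.mask)
        plane = _plane_fit(height, sel)
        height = height - plane
    return height


def correct_tilt(height_um: np.ndarray,
                 substrate_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Subtract the best-fit substrate plane from a height map.

    Substrate pixels come from ``substrate_mask`` (True = substrate) or
    default to the lowest decile.  With fewer than 3 non-collinear
    substrate pixels the correction is skipped with a warning (the
    "if needed" contract); exact for an added plane, idempotent on a
    flat map.
    """
    height = np.asarray(height_um, dtype=float)
    if substrate_mask is not None:
        sel = np.asarray(substrate_mask, dtype=bool) & np.isfinite(height)
    else:
        sel = _substrate_selector(height, None)
    rows_sel, cols_sel = np.nonzero(sel)
    if sel.sum() < 3 or (np.ptp(rows_sel) == 0 and np.ptp(cols_sel) == 0) or \
            np.linalg.matrix_rank(np.column_stack((np.ones(sel.sum()), cols_sel, rows_sel))) < 3:
        warnings.warn("insufficient substrate pixels; tilt correction skipped")
        return height.copy()
    return height - _plane_fit(height, sel)


def central_part_filter(heights_um: np.ndarray) -> np.ndarray:
    """Indices of the retained central-part pixels of one cell.

    Retains exactly ceil(n/2) pixels of highest height — the top 50% of
    the cell's height distribution; ties broken by lower index.  Raises
    EmptyCell for an empty input; requires >= 2 pixels.
    """
    h = np.asarray(heights_um, dtype=float).ravel()
    if h.size == 0:
        raise EmptyCell("empty cell mask")
    if h.size < 2:
        raise EmptyCell("central-part filter needs >= 2 cell pixels")
    keep = int(np.ceil(h.size / 2))
    order = np.argsort(-h, kind="stable")
    return np.sort(order[:keep])


def derive_cell_mask(height_um: np.ndarray, sigma_floor_um: float = 1e-3,
                     min_pixels: int = 4) -> np.ndarray:
    """Cell-label image from height thresholding (substrate + 3x roughness).

    Substrate level and roughness are estimated from the lowest decile of
    heights; connected components above the threshold become cells.
    """
    height = np.asarray(height_um, dtype=float)
    finite = np.isfinite(height)
    vals = height[finite]
    low = vals[vals <= np.quantile(vals, 0.10)]
    level = float(np.median(low))
    rough = max(float(np.std(low)), sigma_floor_um)
    above = finite & (height > level + 3.0 * rough)
    labels, n = ndimage.label(above)
    for lab in range(1, n + 1):
        if (labels == lab).sum() < min_pixels:
            labels[labels == lab] = 0
    # re-number contiguously
    out = np.zeros_like(labels)
    for new, lab in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == lab] = new
    return out


@dataclass
class CellRecord:
    """Per-cell aggregate over retained (central-part) pixels."""

    cell_id: int
    group: str
    ym_kpa: float
    e1_kpa: float
    alpha: float
    eta_pa_s: float
    height_um: float
    n_retained: int
    n_pixels: int
    n_failed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cell_id", "group", "ym_kpa", "e1_kpa", "alpha", "eta_pa_s",
                 "height_um", "n_retained", "n_pixels", "n_failed")}


def fit_map(fvmap: ForceVolumeMap, model: str = "hertz",
            config: Optional[FitConfig] = None, use_thickness: bool = True,
            height_um: Optional[np.ndarray] = None):
    """Fit every pixel of a map; returns (fits, status DataFrame).

    model is 'hertz', 'ting_plr' or 'both'.  With ``use_thickness`` the
    local tilt-corrected height feeds the bottom-effect correction as
    the per-pixel sample thickness.  Every pixel is accounted for in the
    status table: fitted, no_contact, or failed (with reason).
    """
    if model not in ("hertz", "ting_plr", "both"):
        raise CellmechError(f"unknown model {model!r}")
    cfg = config or FitConfig()
    contacts = fvmap.contacts()
    fits: dict = {}
    rows = []
    for (i, j), curve in np.ndenumerate(fvmap.curves):
        status, reason = "fitted", ""
        entry: dict = {}
        if curve is None or contacts[i, j] is None:
            status, reason = "no_contact", "no contact detected"
        else:
            pix_cfg = cfg
            if use_thickness and height_um is not None and np.isfinite(height_um[i, j]) \
                    and height_um[i, j] > 0.02:
                pix_cfg = FitConfig(fit_range=cfg.fit_range,
                                    refine_contact=cfg.refine_contact,
                                    refine_span_steps=cfg.refine_span_steps,
                                    fit_eta=cfg.fit_eta, alpha_grid=cfg.alpha_grid,
                                    thickness_nm=height_um[i, j] * 1000.0, bec=cfg.bec)
            try:
                if model in ("hertz", "both"):
                    entry["hertz"] = HertzModel(curve, pix_cfg).fit()
                if model in ("ting_plr", "both"):
                    entry["ting"] = TingModel(curve, pix_cfg).fit()
            except NoContact:
                status, reason = "no_contact", "no usable indentation"
            except (MissingRetract, CellmechError) as exc:
                status, reason = "failed", str(exc)
        if entry:
            fits[(i, j)] = entry
        rows.append({"row": i, "col": j, "status": status, "reason": reason})
    return fits, pd.DataFrame(rows)


def aggregate_cell(fvmap: ForceVolumeMap, cell_mask: np.ndarray,
                   height_um: np.ndarray, fits: Optional[dict] = None,
                   group: str = "", cell_id: int = 1,
                   height_statistic: str = "max") -> CellRecord:
    """Arithmetic means of YM, E1, alpha, eta over central-part pixels.

    Cell height is the maximum tilt-corrected height over the cell
    (apex) by default, or the mean with ``height_statistic='mean'``.
    NoContact / failed pixels are excluded and counted.  Raises
    EmptyCell when fits are expected but no retained pixel has one.
    """
    sel = np.asarray(cell_mask, dtype=bool)
    idx = np.argwhere(sel)
    if idx.size == 0:
        raise EmptyCell("empty cell mask")
    heights = height_um[sel]
    finite = np.isfinite(heights)
    if finite.sum() < 2:
        raise EmptyCell("fewer than 2 cell pixels with height")
    idx = idx[finite]
    heights = heights[finite]
    keep = central_part_filter(heights)
    retained = [tuple(idx[k]) for k in keep]

    def collect(tag: str, attr):
        vals = []
        for pix in retained:
            entry = (fits or {}).get(pix)
            if entry and tag in entry:
                vals.append(attr(entry[tag]))
        return vals

    ym = collect("hertz", lambda r: r.E_pa / 1000.0)
    e1 = collect("ting", lambda r: r.params.E1 / 1000.0)
    al = collect("ting", lambda r: r.params.alpha)
    et = collect("ting", lambda r: r.params.eta)
    n_fitted = max(len(ym), len(e1))
    if fits is not None and n_fitted == 0:
        raise EmptyCell("no retained pixel carries a fit")
    stat = np.nanmax if height_statistic == "max" else np.nanmean
    return CellRecord(
        cell_id=cell_id, group=group,
        ym_kpa=float(np.mean(ym)) if ym else np.nan,
        e1_kpa=float(np.mean(e1)) if e1 else np.nan,
        alpha=float(np.mean(al)) if al else np.nan,
        eta_pa_s=float(np.mean(et)) if et else np.nan,
        height_um=float(stat(heights)),
        n_retained=len(retained), n_pixels=int(sel.sum()),
        n_failed=len(retained) - n_fitted if fits is not None else 0,
    )


def analyze_map(fvmap: ForceVolumeMap, model: str = "hertz",
                config: Optional[FitConfig] = None, group: str = "",
                height_statistic: str = "max"):
    """Full single-map pipeline: topography, tilt, mask, fits, cell records.

    model='none' skips mechanics (topography/height only).  The cell mask
    is taken from the map when present, else derived by height
    thresholding.  Returns a dict with keys height_um, mask, records,
    fits, status.
    """
    height = reconstruct_topography(fvmap)
    sub_mask = (np.asarray(fvmap.mask) == 0) if fvmap.mask is not None else None
    height = correct_tilt(height, substrate_mask=sub_mask)
    mask = np.asarray(fvmap.mask) if fvmap.mask is not None \
        else derive_cell_mask(height)
    fits, status = (None, None)
    if model != "none":
        fits, status = fit_map(fvmap, model=model, config=config,
                               height_um=height)
    records = []
    for cell_id in np.unique(mask[mask > 0]):
        try:
            records.append(aggregate_cell(fvmap, mask == cell_id, height,
                                          fits=fits, group=group,
                                          cell_id=int(cell_id),
                                          height_statistic=height_statistic))
        except EmptyCell:
            continue
    return {"height_um": height, "mask": mask, "records": records,
            "fits": fits, "status": status}


_FOLD_UP = ("ym_kpa", "e1_kpa", "eta_pa_s")     # reported activated / control
_FOLD_DOWN = ("height_um", "alpha")             # reported control / activated


def cohort_summary(records, pairs=None,
                   value_cols=("ym_kpa", "e1_kpa", "alpha", "eta_pa_s", "height_um")):
    """Per-group mean +/- sd and fold changes between condition pairs.

    records: DataFrame (or list of CellRecord) with a 'group' column.
    pairs: list of (control_group, activated_group) tuples; fold changes
    are activated/control for moduli and viscosity ("fold increase") and
    control/activated for height and the power-law exponent ("fold
    decrease"), matching how activation effects are reported.  Group
    significance uses the standard Mann-Whitney U test (delegated, not
    re-implemented).  Groups with < 2 cells are excluded with a warning.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.to_dict() for r in records])
    counts = records.groupby("group").size()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"groups excluded (<2 cells): {small}")
        records = records[~records["group"].isin(small)]
    if records.empty:
        raise EmptyMap("no groups with >= 2 cells")
    value_cols = [c for c in value_cols if c in records.columns]
    groups = records.groupby("group")[value_cols].agg(["mean", "std", "count"])

    fold_rows = []
    for pair in pairs or []:
        ctl, act = pair[0], pair[1]
        if ctl not in counts.index or act not in counts.index:
            warnings.warn(f"fold pair ({ctl}, {act}) missing a group; skipped")
            continue
        sub_c = records[records["group"] == ctl]
        sub_a = records[records["group"] == act]
        for col in value_cols:
            mc = sub_c[col].mean()
            ma = sub_a[col].mean()
            if not (np.isfinite(mc) and np.isfinite(ma)) or mc == 0 or ma == 0:
                continue
            fold = ma / mc if col in _FOLD_UP else mc / ma
            direction = "activated/control" if col in _FOLD_UP else "control/activated"
            try:
                p = float(stats.mannwhitneyu(sub_c[col].dropna(),
                                             sub_a[col].dropna()).pvalue)
            except ValueError:
                p = np.nan
            fold_rows.append({"control": ctl, "activated": act, "metric": col,
                              "fold": float(fold), "direction": direction,
                              "p_mannwhitney": p})
    return {"groups": groups, "folds": pd.DataFrame(fold_rows)}
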