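"""Plate-reader and flow-cytometry summary computations.

Kinetics traces (chemiluminescence / fluorescence ROS bursts) are
summarised by the baseline-subtracted area under the curve from the
moment of activator addition; well activities are normalised to
double-stranded DNA content as a cell-number proxy; cross-donor
comparison uses per-experiment z-standardization; phagocytosis is
summarised by affinity (percentage of gated cells) and capacity (median
fluorescence intensity of gated cells), with the gate set from a
no-particle control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "KineticsTrace", "CytometrySample",
    "kinetics_auc", "dna_normalize", "zscore_standardize",
    "gate_threshold", "phagocytic_metrics",
]


@dataclass
class KineticsTrace:
    """One well's time series: time (s), signal (counts or a.u.)."""

    t_s: np.ndarray
    signal: np.ndarray
    activator_time_s: float = 0.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.t_s) <= 0):
            raise DomainError("time must be strictly increasing")
        if not (self.t_s[0] <= self.activator_time_s <= self.t_s[-1]):
            raise DomainError("activator time outside the trace")


@dataclass
class CytometrySample:
    """Per-event fluorescence intensities (a.u.) for one sample."""

    intensity: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise DomainError("intensities must be >= 0")

    @property
    def n_events(self) -> int:
        return self.intensity.size


def kinetics_auc(trace: KineticsTrace, t_end_s: float) -> float:
    """Baseline-subtracted trapezoidal AUC from activator addition to t_end.

    The baseline is the mean of pre-activation samples (first sample when
    none exist).  t_end should exceed the burst peak; if it does not, a
    warning is emitted and the (partial) area still returned.
    """
    t0 = trace.activator_time_s
    if not (t0 < t_end_s <= trace.t_s[-1] + 1e-12):
        raise DomainError("t_end must lie after activation and within the trace")
    pre = trace.signal[trace.t_s < t0]
    baseline = float(pre.mean()) if pre.size else float(trace.signal[0])
    sel = (trace.t_s >= t0) & (trace.t_s <= t_end_s)
    t = trace.t_s[sel]
    y = trace.signal[sel] - baseline
    t_peak = t[int(np.argmax(y))] if y.size else t0
    if t_end_s <= t_peak:
        warnings.warn("t_end does not exceed the burst peak time")
    return float(np.trapezoid(y, t))


def dna_normalize(values, dna_ng_per_ml):
    """Activity per unit DNA: value / dna, with non-positive DNA wells dropped.

    Accepts array-likes or pandas Series; returns the same shape with NaN
    (and a warning) where DNA <= 0.
    """
    values = np.asarray(values, dtype=float)
    dna = np.asarray(dna_ng_per_ml, dtype=float)
    if values.shape != dna.shape:
        raise DomainError("values and DNA arrays must align")
    bad = ~(dna > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} well(s) with DNA <= 0 excluded")
    out = np.where(bad, np.nan, values / np.where(bad, np.nan, dna))
    return out


def zscore_standardize(matrix, axis: int = 1):
    """Per-experiment z-scores: (x - row mean) / row sd (sample sd, n-1).

    matrix: 2-d array or DataFrame, rows = biological experiments,
    columns = condition groups (axis=1 standardizes within rows).
    Constant rows are undefined and emitted as NaN with a warning.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix, dtype=float))
    if axis not in (0, 1):
        raise DomainError("axis must be 0 or 1")
    work = df if axis == 1 else df.T
    mean = work.mean(axis=1)
    sd = work.std(axis=1, ddof=1)
    zero = ~(sd > 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant experiment(s) -> NaN z-scores")
        sd = sd.where(~zero, np.nan)
    z = work.sub(mean, axis=0).div(sd, axis=0)
    z = z if axis == 1 else z.T
    return z if isinstance(matrix, pd.DataFrame) else z.to_numpy()


def gate_threshold(control: CytometrySample, quantile: float = 0.995) -> float:
    """Positivity gate from a no-particle control: its 99.5th percentile."""
    if control.n_events < 100:
        raise DomainError("control sample needs >= 100 events")
    return float(np.quantile(control.intensity, quantile))


def phagocytic_metrics(sample: CytometrySample,
                       control: Optional[CytometrySample] = None,
                       threshold: Optional[float] = None,
                       mfi_statistic: str = "median") -> dict:
    """Phagocytic affinity (%) and capacity (MFI of gated cells).

    affinity = 100 * (#events above threshold) / n; capacity = median
    (configurably mean) fluorescence intensity of the events above the
    threshold, NaN when no event is gated.  The threshold comes from the
    matched no-particle control unless given explicitly.
    """
    if sample.n_events < 100:
        raise DomainError("sample needs >= 100 events")
    if threshold is None:
        if control is None:
            raise DomainError("either a control sample or a threshold is required")
        threshold = gate_threshold(control)
    gated = sample.intensity[sample.intensity > threshold]
    affinity = 100.0 * gated.size / sample.n_events
    if gated.size == 0:
        capacity = np.nan
    elif mfi_statistic == "median":
        capacity = float(np.median(gated))
    elif mfi_statistic == "mean":
        capacity = float(np.mean(gated))
    else:
        raise DomainError(f"unknown MFI statistic {mfi_statistic!r}")
    return {"affinity_pct": float(affinity), "capacity_mfi": capacity,
            "threshold": float(threshold), "n_events": sample.n_events,
            "n_gated": int(gated.size)}
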