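"""File formats: HDF5 force-volume container, per-curve CSV, matrices, configs.

Container layout (single HDF5 file):

    /curves/t{row:03d}_{col:03d}   float64 (n, 3): t_s, z_nm, force_nN
        attrs: turn_index
    /meta   attrs: spring_constant_N_per_m, tip_radius_nm, poisson_nu,
                   field_um (2,), shape (2,)
    /mask   optional int cell-label image (0 = substrate)
    /truth/height_map_um   optional ground-truth height map

Per-curve delimited text: '#'-prefixed YAML header (spring_constant_N_per_m,
sensitivity_nm_per_V, tip_radius_nm, poisson_nu, turn_index) followed by
CSV columns t_s, z_nm, force_nN (or deflection_V), phase (0 approach,
1 retract).
"""

from __future__ import annotations

import io as _io
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .assays import CytometrySample, KineticsTrace
from .contact import Indenter
from .curve import ForceCurve
from .errors import ConfigurationError
from .fvmap import ForceVolumeMap

__all__ = [
    "write_fvmap_h5", "read_fvmap_h5",
    "write_curve_csv", "read_curve_csv",
    "write_matrix_tsv", "read_matrix_tsv",
    "read_kinetics_csv", "read_events_csv",
    "render_map", "load_config",
]


def write_fvmap_h5(fvmap: ForceVolumeMap, path) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("curves")
        for (i, j), curve in np.ndenumerate(fvmap.curves):
            if curve is None:
                continue
            data = np.column_stack((curve.t_s, curve.z_nm, curve.force_nN))
            ds = grp.create_dataset(f"t{i:03d}_{j:03d}", data=data)
            ds.attrs["turn_index"] = curve.turn_index
        meta = fh.create_group("meta")
        any_curve = next(c for _, c in np.ndenumerate(fvmap.curves) if c is not None)
        meta.attrs["spring_constant_N_per_m"] = any_curve.spring_constant_N_per_m
        meta.attrs["tip_radius_nm"] = fvmap.probe.radius_nm
        meta.attrs["poisson_nu"] = fvmap.probe.poisson_nu
        meta.attrs["field_um"] = np.asarray(fvmap.field_um, dtype=float)
        meta.attrs["shape"] = np.asarray(fvmap.shape, dtype=int)
        if fvmap.mask is not None:
            fh.create_dataset("mask", data=np.asarray(fvmap.mask, dtype=np.int32))
        truth = fvmap.ground_truth
        if truth.get("height_map_um") is not None:
            fh.create_dataset("truth/height_map_um",
                              data=np.asarray(truth["height_map_um"], dtype=float))


def read_fvmap_h5(path) -> ForceVolumeMap:
    with h5py.File(path, "r") as fh:
        meta = fh["meta"].attrs
        probe = Indenter(radius_nm=float(meta["tip_radius_nm"]),
                         poisson_nu=float(meta["poisson_nu"]))
        k = float(meta["spring_constant_N_per_m"])
        rows, cols = (int(v) for v in meta["shape"])
        curves = np.empty((rows, cols), dtype=object)
        for name, ds in fh["curves"].items():
            i, j = int(name[1:4]), int(name[5:8])
            data = ds[()]
            curves[i, j] = ForceCurve(t_s=data[:, 0], z_nm=data[:, 1],
                                      force_nN=data[:, 2],
                                      spring_constant_N_per_m=k,
                                      turn_index=int(ds.attrs["turn_index"]),
                                      probe=probe)
        mask = fh["mask"][()] if "mask" in fh else None
        truth = {}
        if "truth/height_map_um" in fh:
            truth["height_map_um"] = fh["truth/height_map_um"][()]
        return ForceVolumeMap(curves=curves,
                              field_um=tuple(float(v) for v in meta["field_um"]),
                              probe=probe, mask=mask, ground_truth=truth)


def write_curve_csv(curve: ForceCurve, path) -> None:
    header = {
        "spring_constant_N_per_m": float(curve.spring_constant_N_per_m),
        "sensitivity_nm_per_V": curve.sensitivity_nm_per_V,
        "tip_radius_nm": float(curve.probe.radius_nm),
        "poisson_nu": float(curve.probe.poisson_nu),
        "turn_index": int(curve.turn_index),
    }
    phase = (np.arange(curve.n_samples) > curve.turn_index).astype(int)
    if curve.force_nN is not None:
        df = pd.DataFrame({"t_s": curve.t_s, "z_nm": curve.z_nm,
                           "force_nN": curve.force_nN, "phase": phase})
    else:
        df = pd.DataFrame({"t_s": curve.t_s, "z_nm": curve.z_nm,
                           "deflection_V": curve.deflection_V, "phase": phase})
    with open(path, "w") as fh:
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_curve_csv(path) -> ForceCurve:
    header_lines = []
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                body.append(line)
    header = yaml.safe_load("\n".join(header_lines)) or {}
    df = pd.read_csv(_io.StringIO("".join(body)))
    if "force_nN" not in df.columns and "deflection_V" not in df.columns:
        raise ConfigurationError("curve file needs a force_nN or deflection_V column")
    probe = Indenter(radius_nm=float(header.get("tip_radius_nm", 70.0)),
                     poisson_nu=float(header.get("poisson_nu", 0.5)))
    turn = header.get("turn_index")
    if turn is None and "phase" in df.columns:
        app = np.nonzero(df["phase"].to_numpy() == 0)[0]
        turn = int(app[-1]) if app.size else None
    sens = header.get("sensitivity_nm_per_V")
    return ForceCurve(t_s=df["t_s"].to_numpy(), z_nm=df["z_nm"].to_numpy(),
                      force_nN=df["force_nN"].to_numpy() if "force_nN" in df else None,
                      deflection_V=df["deflection_V"].to_numpy()
                      if "deflection_V" in df else None,
                      spring_constant_N_per_m=float(
                          header.get("spring_constant_N_per_m", 0.1)),
                      sensitivity_nm_per_V=None if sens is None else float(sens),
                      turn_index=None if turn is None else int(turn),
                      probe=probe)


def write_matrix_tsv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.6g")


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def read_kinetics_csv(path) -> KineticsTrace:
    """Plate-reader trace: '#'-header (activator_time_s, label) + t_s, signal."""
    header_lines, body = [], []
    with open(path) as fh:
        for line in fh:
            (header_lines if line.startswith("#") else body).append(
                line[1:].strip() if line.startswith("#") else line)
    header = yaml.safe_load("\n".join(header_lines)) or {}
    df = pd.read_csv(_io.StringIO("".join(body)))
    return KineticsTrace(t_s=df["t_s"].to_numpy(), signal=df["signal"].to_numpy(),
                         activator_time_s=float(header.get("activator_time_s", 0.0)),
                         label=str(header.get("label", "")))


def read_events_csv(path) -> CytometrySample:
    """Flow-cytometry event list: one 'intensity' column (+ optional '#' label)."""
    df = pd.read_csv(path, comment="#")
    return CytometrySample(intensity=df["intensity"].to_numpy())


def render_map(matrix: np.ndarray, path, title: str = "", units: str = "") -> None:
    """Height/modulus map rendered to an image file (headless backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(np.asarray(matrix, dtype=float), origin="lower",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label=units)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config file must hold a mapping")
    return cfg
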