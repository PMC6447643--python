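"""File I/O: curve CSVs, experiment configs (YAML), and NIfTI series."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .experiment import ExperimentConfig
from .synthetic import AorticCurve, DynamicSeries

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "load_config",
    "save_config",
    "save_series",
    "load_series_volumes",
]


def read_curve_csv(path) -> AorticCurve:
    """Read a two-column (time_s, hu) CSV into an :class:`AorticCurve`."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_s" not in cols or "hu" not in cols:
        raise InvalidParameterError(
            f"{path}: expected columns time_s,hu; found {list(df.columns)}"
        )
    return AorticCurve(
        times=df[cols["time_s"]].to_numpy(dtype=float),
        enhancement=df[cols["hu"]].to_numpy(dtype=float),
    )


def write_curve_csv(curve: AorticCurve, path) -> None:
    pd.DataFrame({"time_s": curve.times, "hu": curve.enhancement}).to_csv(
        path, index=False
    )


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    known = ExperimentConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    # YAML lists -> tuples where the dataclass expects them
    for key, value in raw.items():
        if isinstance(value, list):
            raw[key] = tuple(value)
    return ExperimentConfig(**raw)


def _plain(value):
    if isinstance(value, (tuple, list)):
        return [_plain(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    return value


def save_config(config: ExperimentConfig, path) -> None:
    data = {k: _plain(v) for k, v in asdict(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def save_series(series: DynamicSeries, outdir) -> None:
    """Write a series as a 4-D NIfTI plus label masks and a gate manifest."""
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([series.phantom.voxel_size] * 3 + [1.0])

    vols = np.moveaxis(series.volumes, 0, -1)  # (x, y, z, gate)
    nib.save(nib.Nifti1Image(vols.astype(np.float32), affine), out / "series.nii")
    labels = np.zeros(series.phantom.grid_shape, dtype=np.int16)
    labels[np.asarray(series.phantom.aorta_mask, bool)] = 1
    labels[np.asarray(series.phantom.myocardium_mask, bool)] = 2
    nib.save(nib.Nifti1Image(labels, affine), out / "labels.nii")
    nib.save(
        nib.Nifti1Image(series.phantom.true_perfusion.astype(np.float32), affine),
        out / "true_perfusion.nii",
    )
    pd.DataFrame(
        {"gate": np.arange(series.n_gates), "time_s": series.gate_times}
    ).to_csv(out / "gates.csv", index=False)


def load_series_volumes(indir) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load (volumes[gate, x, y, z], gate_times, labels) written by save_series."""
    import nibabel as nib

    indir = Path(indir)
    vols = np.moveaxis(np.asarray(nib.load(indir / "series.nii").dataobj), -1, 0)
    labels = np.asarray(nib.load(indir / "labels.nii").dataobj)
    gates = pd.read_csv(indir / "gates.csv")["time_s"].to_numpy(dtype=float)
    return vols, gates, labels
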