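"""NIfTI volume and tabular event I/O.

Volumes are stored as NIfTI-1 with isotropic voxel size and the repetition
time carried in the header zooms.  Event tables follow a BIDS-events-like
tab-separated dialect: ``onset`` and ``duration`` first, then the custom
columns used by this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: The three task conditions (two regulation strategies plus the control).
CONDITIONS = ("positive", "negative", "now")

EVENT_COLUMNS = ["onset", "duration", "condition", "cue_id", "stimulus_id", "run", "rating"]


class VolumeError(ValueError):
    """Raised for malformed or inconsistent volumetric images."""


class EventTableError(ValueError):
    """Raised for malformed event tables."""


def default_affine(voxel_size_mm: float, shape: tuple[int, ...]) -> np.ndarray:
    """RAS affine with isotropic voxels, origin at the grid centre."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape[:3]) - 1) / 2.0
    return affine


@dataclass
class Volume4D:
    """A 4D scalar grid (x, y, z, time) with voxel size and TR metadata."""

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise VolumeError(f"Volume4D requires 4D data, got {self.data.ndim}D")
        if self.tr_s <= 0:
            raise VolumeError("tr_s must be positive")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm, self.data.shape)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_s


def write_volume(volume: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    vs = float(volume.voxel_size_mm)
    img.header.set_zooms((vs, vs, vs, float(volume.tr_s)))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_volume(path: str | Path) -> Volume4D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise VolumeError(f"{path}: expected a 4D time series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    vs = float(zooms[0])
    if not np.allclose(zooms[:3], vs, rtol=1e-5):
        raise VolumeError(f"{path}: anisotropic voxels not supported: {zooms[:3]}")
    tr = float(zooms[3])
    if tr <= 0:
        raise VolumeError(f"{path}: header carries no positive TR")
    return Volume4D(data=data, voxel_size_mm=vs, tr_s=tr, affine=np.asarray(img.affine))


def write_label_volume(labels: np.ndarray, voxel_size_mm: float, path: str | Path,
                       affine: np.ndarray | None = None) -> None:
    """Write a 3D integer label volume (e.g. a parcellation atlas)."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise VolumeError(f"label volume must be 3D, got {labels.ndim}D")
    if affine is None:
        affine = default_affine(voxel_size_mm, labels.shape)
    img = nib.Nifti1Image(labels.astype(np.int32), affine)
    vs = float(voxel_size_mm)
    img.header.set_zooms((vs, vs, vs))
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D integer label volume; returns (labels, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    return data.astype(np.int64), np.asarray(img.affine)


def write_map(data: np.ndarray, voxel_size_mm: float, path: str | Path,
              affine: np.ndarray | None = None) -> None:
    """Write a 3D scalar map (contrast, accuracy, ...) as NIfTI-1."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise VolumeError(f"scalar map must be 3D, got {data.ndim}D")
    if affine is None:
        affine = default_affine(voxel_size_mm, data.shape)
    img = nib.Nifti1Image(data, affine)
    vs = float(voxel_size_mm)
    img.header.set_zooms((vs, vs, vs))
    nib.save(img, str(path))


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D scalar map; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D map, got {data.ndim}D")
    return data, np.asarray(img.affine)


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table against the pipeline's event dialect."""
    missing = [c for c in ("onset", "duration", "condition") if c not in table.columns]
    if missing:
        raise EventTableError(f"event table lacks required columns: {missing}")
    if len(table) == 0:
        return table
    bad = sorted(set(table["condition"]) - set(CONDITIONS))
    if bad:
        raise EventTableError(
            f"unknown condition label(s) {bad}; allowed: {list(CONDITIONS)}")
    if not np.all(np.isfinite(table["onset"])) or not np.all(np.isfinite(table["duration"])):
        raise EventTableError("onset/duration must be finite numbers")
    if (table["duration"] <= 0).any():
        raise EventTableError("durations must be positive")
    runs = table["run"] if "run" in table.columns else pd.Series(1, index=table.index)
    for run, grp in table.groupby(runs):
        onsets = grp["onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise EventTableError(f"onsets not strictly increasing within run {run}")
    return table


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    validate_events(table)
    cols = [c for c in EVENT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    table = pd.read_csv(path, sep="\t", na_values=["n/a"])
    try:
        table["onset"] = pd.to_numeric(table["onset"])
        table["duration"] = pd.to_numeric(table["duration"])
    except (ValueError, KeyError) as exc:
        raise EventTableError(f"{path}: onset/duration must be numeric") from exc
    return validate_events(table)
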