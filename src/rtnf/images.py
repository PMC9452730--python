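"""4-D BOLD runs and NIfTI-1 persistence.

A run is stored as a ``.nii``/``.nii.gz`` file (data + affine + TR in the
header pixdim) together with a YAML sidecar carrying the per-volume condition
labels, which NIfTI cannot hold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .paradigm import Condition


@dataclass
class BoldRun:
    """A 4-D functional series with voxel-to-world affine and TR."""

    data: np.ndarray          # (x, y, z, t), float
    affine: np.ndarray        # 4x4 voxel-to-world
    tr_seconds: float
    labels: list[Condition]   # one condition per volume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.labels) != self.data.shape[3]:
            raise ValueError(
                f"label count {len(self.labels)} != t dimension {self.data.shape[3]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.labels = [Condition(l) for l in self.labels]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def mean_volume(self) -> np.ndarray:
        return self.data.mean(axis=3)

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".yaml")
    return path.with_suffix(".yaml")


def write_run(run: BoldRun, path: str | Path) -> Path:
    """Write a run as NIfTI-1 plus a YAML label sidecar; returns the NIfTI path."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float64), run.affine)
    img.header.set_zooms((*np.abs(run.voxel_sizes_mm()), run.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "tr_seconds": float(run.tr_seconds),
        "labels": [l.value for l in run.labels],
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar))
    return path


def read_run(path: str | Path) -> BoldRun:
    """Read a NIfTI run and its YAML sidecar back into a :class:`BoldRun`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(
            f"malformed NIfTI header field dim: expected 4-D image, got dim={data.ndim}"
        )
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"label sidecar not found: {sidecar_file}")
    sidecar = yaml.safe_load(sidecar_file.read_text())
    labels = [Condition(l) for l in sidecar["labels"]]
    if len(labels) != data.shape[3]:
        raise ValueError(
            f"malformed run: NIfTI dim[4]={data.shape[3]} but sidecar has "
            f"{len(labels)} labels"
        )
    tr = float(sidecar["tr_seconds"])
    zooms = img.header.get_zooms()
    if len(zooms) >= 4 and zooms[3] > 0 and abs(zooms[3] - tr) > 1e-3:
        raise ValueError(
            f"malformed run: header pixdim[4]={zooms[3]} disagrees with sidecar "
            f"tr_seconds={tr}"
        )
    return BoldRun(data=data, affine=img.affine, tr_seconds=tr, labels=labels)
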