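"""NIfTI and CSV input/output.

Volumes are written as NIfTI-1 with an RAS+ affine and 3 mm isotropic
voxels (the acquisition resolution the protocol emulates).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .cvr import BoldRun
from .errors import ConfigurationError

VOXEL_MM = 3.0


def _affine(voxel_mm: float = VOXEL_MM) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def save_volume(data: np.ndarray, path, voxel_mm: float = VOXEL_MM) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_mm))
    nib.save(img, path)
    return path


def save_labels(labels: np.ndarray, path, voxel_mm: float = VOXEL_MM) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_mm))
    nib.save(img, path)
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj)


def save_run(run: BoldRun, path, voxel_mm: float = VOXEL_MM) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float64), _affine(voxel_mm))
    img.header.set_zooms((voxel_mm, voxel_mm, voxel_mm, run.tr))
    nib.save(img, path)
    return path


def load_run(path, condition: str = "normo", run_type: str = "cvr") -> BoldRun:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ConfigurationError(f"{path} is not a 4D NIfTI volume")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return BoldRun(data, tr=tr, condition=condition, run_type=run_type)
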