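"""NIfTI, FSL gradient-table and YAML/JSON config I/O."""
from __future__ import annotations

import importlib.resources
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import FormatError, GradientTable


# ---------------------------------------------------------------------------
# NIfTI


def save_nifti(data: np.ndarray, path, voxel_size: float = 2.0) -> None:
    """Write an array as NIfTI-1 with an isotropic scaled affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, voxel size in mm)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, float(zooms[0])


# ---------------------------------------------------------------------------
# FSL-dialect gradient tables


def write_gradients(gtab: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-style files: bvals one row; bvecs three rows of K columns."""
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in gtab.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in gtab.bvecs.T:
            f.write(" ".join(f"{x:.8f}" for x in row) + "\n")


def read_gradients(bval_path, bvec_path) -> GradientTable:
    """Read FSL-style bval/bvec files.

    Directions with norms off unity by more than 1e-3 are re-normalized
    with a warning; a count mismatch between the two files is an error.
    """
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse gradient files: {exc}") from exc
    if bvecs.shape[0] != 3:
        raise FormatError("bvec file must contain exactly 3 rows")
    if bvecs.shape[1] != bvals.size:
        raise FormatError(
            f"{bvals.size} b-values but {bvecs.shape[1]} directions")
    bvecs = bvecs.T.copy()
    dwi = bvals > 0
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("re-normalizing gradient directions with norm off unity")
    bvecs[dwi] /= np.maximum(norms, np.finfo(float).tiny)[:, None]
    return GradientTable(bvals, bvecs)


def default_gradient_table() -> GradientTable:
    """The shipped acquisition scheme: one b=0 plus 20 directions at b=1000."""
    data = importlib.resources.files("dtialps") / "data"
    return read_gradients(str(data / "default.bval"), str(data / "default.bvec"))


# ---------------------------------------------------------------------------
# config and report serialization


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def load_yaml(path) -> dict:
    try:
        with open(path) as f:
            out = yaml.safe_load(f)
    except Exception as exc:
        raise FormatError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(out, dict):
        raise FormatError(f"YAML {path} does not hold a mapping")
    return out


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
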