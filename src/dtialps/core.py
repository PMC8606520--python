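"""Shared containers, label conventions and error types.

Coordinate convention used throughout: array axis 0 is x (right -> left),
axis 1 is y (anterior -> posterior), axis 2 is z (inferior -> superior).
Voxel indices are 0-based; the "right" hemisphere is x index < midline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# label classes


class Label:
    """Integer classes of a :class:`LabelVolume`."""

    BACKGROUND = 0
    PROJ_RIGHT = 1
    PROJ_LEFT = 2
    ASSOC_RIGHT = 3
    ASSOC_LEFT = 4
    VENTRICLE = 5
    INFARCT = 6
    HEMORRHAGE = 7


LESION_LABELS = (Label.INFARCT, Label.HEMORRHAGE)


# ---------------------------------------------------------------------------
# errors


class DTIALPSError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DTIALPSError, ValueError):
    """A numeric parameter violates its precondition."""


class GeometryError(DTIALPSError):
    """A requested structure does not fit in the phantom grid."""


class RankDeficiencyError(DTIALPSError):
    """Too few usable diffusion directions for a tensor fit."""


class MissingRegionError(DTIALPSError):
    """A required ROI is empty."""


class ContaminationError(DTIALPSError):
    """A fiber ROI overlaps lesion voxels."""


class DegenerateInputError(DTIALPSError):
    """A statistical routine received data with no usable variance."""


class UndefinedMeasurementError(DTIALPSError):
    """A measurement has no defined value (e.g. fully excluded ROI)."""


class FormatError(DTIALPSError):
    """A file could not be parsed as the expected format."""


# ---------------------------------------------------------------------------
# gradient table


@dataclass
class GradientTable:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit directions.

    Directions are expressed in image coordinates. b=0 entries carry the
    zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise InvalidParameterError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise InvalidParameterError("b>0 directions must have unit norm")
        if np.any(norms[~dwi] > 1e-12):
            raise InvalidParameterError("b=0 entries must carry the zero vector")
        if self.n_dwi < 6:
            raise InvalidParameterError("need at least 6 b>0 directions")
        # non-collinearity: the quadratic-form design must have rank 6
        g = self.bvecs[dwi]
        design = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])
        if np.linalg.matrix_rank(design) < 6:
            raise InvalidParameterError("b>0 directions are collinear/degenerate")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(~self.b0_mask))


# ---------------------------------------------------------------------------
# volumes


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal (x, y, z, direction) plus its scheme."""

    data: np.ndarray
    voxel_size: float
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidParameterError("DWI data must be 4D (x, y, z, k)")
        if self.data.shape[3] != len(self.gtab):
            raise InvalidParameterError(
                "4th dimension must match the gradient table length"
            )
        if np.any(self.data < 0):
            raise InvalidParameterError("signals must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class LabelVolume:
    """Integer region map on the phantom grid."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidParameterError("labels must be integer-valued")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size) ** 3

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.data, labels)

    def count(self, *labels: int) -> int:
        return int(np.count_nonzero(self.mask(*labels)))
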