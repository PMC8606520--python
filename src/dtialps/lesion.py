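"""Infarct volume and volume-weighted lesion ADC/FA.

The lesion volume counts every infarcted voxel including hemorrhagic
ones; the mean ADC and FA exclude hemorrhagic voxels, whose
susceptibility-driven signal would corrupt the diffusivity estimates.
Means are computed slice-by-slice weighted by the per-slice infarct
voxel count, which is algebraically identical to the plain voxel-wise
mean over all included voxels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Label, LabelVolume, LESION_LABELS, UndefinedMeasurementError

SLICE_AXIS = 2   # transverse acquisition: slices stack along z


@dataclass
class LesionMetrics:
    """Measured infarct burden of one subject."""

    volume_cm3: float
    mean_adc: float | None       # 1e-6 mm^2/s, hemorrhage excluded
    mean_fa: float | None
    hemorrhage: bool

    def __post_init__(self) -> None:
        if self.volume_cm3 < 0:
            raise ValueError("volume must be >= 0")
        if self.mean_fa is not None and not 0 <= self.mean_fa <= 1:
            raise ValueError("FA must lie in [0, 1]")


def infarct_volume(labels: LabelVolume, voxel_size: float | None = None) -> float:
    """Whole-lesion volume in cm^3 (hemorrhagic voxels included)."""
    vs = labels.voxel_size if voxel_size is None else voxel_size
    return labels.count(*LESION_LABELS) * float(vs) ** 3 / 1000.0


def slice_weighted_mean(values: np.ndarray, mask: np.ndarray,
                        axis: int = SLICE_AXIS) -> float:
    """Per-slice means weighted by per-slice voxel counts.

    Equals the global mean over masked voxels; kept explicit because the
    per-slice view is how lesion means are reported clinically.
    """
    counts = mask.sum(axis=tuple(i for i in range(mask.ndim) if i != axis))
    sums = np.where(mask, values, 0.0).sum(
        axis=tuple(i for i in range(mask.ndim) if i != axis))
    total = counts.sum()
    if total == 0:
        raise UndefinedMeasurementError("empty mask")
    present = counts > 0
    slice_means = sums[present] / counts[present]
    return float(np.average(slice_means, weights=counts[present]))


def infarct_mean_maps(
    adc_map: np.ndarray,
    fa_map: np.ndarray,
    labels: LabelVolume,
) -> tuple[float, float]:
    """Volume-weighted mean ADC (in 1e-6 mm^2/s) and FA of the infarct.

    Hemorrhagic voxels count toward the volume but are excluded here.
    """
    include = labels.mask(Label.INFARCT)
    if not include.any():
        raise UndefinedMeasurementError(
            "no non-hemorrhagic infarct voxels to average")
    mean_adc = slice_weighted_mean(adc_map, include) * 1e6
    mean_fa = slice_weighted_mean(fa_map, include)
    return mean_adc, mean_fa


def measure_lesion(
    adc_map: np.ndarray,
    fa_map: np.ndarray,
    labels: LabelVolume,
) -> LesionMetrics:
    """All lesion metrics of one subject."""
    vol = infarct_volume(labels)
    if vol == 0:
        return LesionMetrics(0.0, None, None, False)
    mean_adc, mean_fa = infarct_mean_maps(adc_map, fa_map, labels)
    return LesionMetrics(
        volume_cm3=vol,
        mean_adc=mean_adc,
        mean_fa=mean_fa,
        hemorrhage=bool(labels.count(Label.HEMORRHAGE) > 0),
    )
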