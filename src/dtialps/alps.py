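"""Per-hemisphere perivascular-diffusivity (ALPS) index and ratios.

The index contrasts the x-axis diffusivity inside the periventricular
projection- and association-fiber regions, where perivascular spaces of
the medullary veins run left-right, against the diffusivities
perpendicular to both the fibers and the x-axis:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

A value of 1 means no excess x diffusivity; higher values indicate more
mobile perivascular fluid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ContaminationError,
    InvalidParameterError,
    Label,
    LabelVolume,
    LESION_LABELS,
    MissingRegionError,
)


@dataclass
class ALPSInputs:
    """ROI-averaged axis diffusivities of one hemisphere (mm^2/s)."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    hemisphere: str
    n_proj: int
    n_assoc: int

    def __post_init__(self) -> None:
        for name in ("dxx_proj", "dxx_assoc", "dyy_proj", "dzz_assoc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_proj < 1 or self.n_assoc < 1:
            raise InvalidParameterError("ROI voxel counts must be >= 1")


@dataclass
class ALPSResult:
    """Per-subject ALPS indices and interhemispheric ratios."""

    right_index: float
    left_index: float
    ratio_rl: float
    ratio_lr: float
    ipsi_index: float | None = None
    contra_index: float | None = None

    def __post_init__(self) -> None:
        if self.right_index <= 0 or self.left_index <= 0:
            raise InvalidParameterError("indices must be positive")
        if abs(self.ratio_rl * self.ratio_lr - 1.0) > 1e-12:
            raise InvalidParameterError("ratios must be reciprocal")


def roi_diffusivities(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    labels: LabelVolume,
    hemisphere: str,
    lesion_mask: np.ndarray | None = None,
) -> ALPSInputs:
    """Mean axis diffusivities over one hemisphere's fiber ROIs.

    Dxx is averaged over both ROIs; Dyy over the projection ROI and Dzz
    over the association ROI (the directions perpendicular to each
    fiber). ROIs that overlap lesion voxels are refused: infarcted
    tissue must not enter the index.
    """
    if hemisphere == "right":
        proj_label, assoc_label = Label.PROJ_RIGHT, Label.ASSOC_RIGHT
    elif hemisphere == "left":
        proj_label, assoc_label = Label.PROJ_LEFT, Label.ASSOC_LEFT
    else:
        raise InvalidParameterError(f"unknown hemisphere {hemisphere!r}")

    proj = labels.mask(proj_label)
    assoc = labels.mask(assoc_label)
    if not proj.any() or not assoc.any():
        raise MissingRegionError(f"empty fiber ROI in {hemisphere} hemisphere")
    if lesion_mask is None:
        lesion_mask = labels.mask(*LESION_LABELS)
    if np.any(lesion_mask & (proj | assoc)):
        raise ContaminationError("fiber ROI overlaps lesion voxels")

    return ALPSInputs(
        dxx_proj=float(dxx[proj].mean()),
        dxx_assoc=float(dxx[assoc].mean()),
        dyy_proj=float(dyy[proj].mean()),
        dzz_assoc=float(dzz[assoc].mean()),
        hemisphere=hemisphere,
        n_proj=int(proj.sum()),
        n_assoc=int(assoc.sum()),
    )


def alps_index(inputs: ALPSInputs) -> float:
    """Perivascular-space diffusivity index of one hemisphere."""
    den = 0.5 * (inputs.dyy_proj + inputs.dzz_assoc)
    if den <= 0:
        raise InvalidParameterError("denominator diffusivities must be positive")
    return 0.5 * (inputs.dxx_proj + inputs.dxx_assoc) / den


def lateralize(
    right_index: float, left_index: float, infarct_side: str | None
) -> tuple[float, float]:
    """Map per-hemisphere indices to (ipsilateral, contralateral)."""
    if infarct_side == "right":
        return right_index, left_index
    if infarct_side == "left":
        return left_index, right_index
    raise InvalidParameterError("lateralization needs an infarct side")


def alps_ratios(right_index: float, left_index: float) -> tuple[float, float]:
    """Right-to-left and left-to-right index ratios."""
    if right_index <= 0 or left_index <= 0:
        raise InvalidParameterError("indices must be positive")
    return right_index / left_index, left_index / right_index


def subject_alps(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    labels: LabelVolume,
    infarct_side: str | None = None,
) -> ALPSResult:
    """Both hemispheres' indices, ratios and (for patients) laterality."""
    indices = {
        h: alps_index(roi_diffusivities(dxx, dyy, dzz, labels, h))
        for h in ("right", "left")
    }
    rl, lr = alps_ratios(indices["right"], indices["left"])
    ipsi = contra = None
    if infarct_side is not None:
        ipsi, contra = lateralize(indices["right"], indices["left"],
                                  infarct_side)
    return ALPSResult(
        right_index=indices["right"],
        left_index=indices["left"],
        ratio_rl=rl,
        ratio_lr=lr,
        ipsi_index=ipsi,
        contra_index=contra,
    )
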