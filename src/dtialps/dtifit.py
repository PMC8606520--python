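"""Per-voxel diffusion tensor estimation and derived scalar maps.

The signal model is the single-tensor monoexponential model
``S_k = S0 * exp(-b_k g_k^T D g_k)``; the fit is log-linear least squares
in the 6 unique tensor elements plus ``ln S0``, so it is exact on
noiseless data and invariant to global signal scaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DWIVolume,
    GradientTable,
    InvalidParameterError,
    RankDeficiencyError,
)

# element order of the 6 unique tensor components
TENSOR_ELEMENTS = ("xx", "yy", "zz", "xy", "xz", "yz")

#: negative eigenvalues are clamped to this floor (mm^2/s)
EIGENVALUE_EPS = 1e-12

#: signals are floored at this fraction of the voxel's b=0 level before log
SIGNAL_FLOOR_FRAC = 1e-6


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear design: columns for -b * quadratic form, plus ln(S0)."""
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack([
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])


def _quadratic_weights(gtab: GradientTable) -> np.ndarray:
    """Per-direction weights w such that b g^T D g = elements . w."""
    return -design_matrix(gtab)[:, :6]


@dataclass
class TensorVolume:
    """Symmetric tensor field stored as 6 unique elements per voxel.

    ``elements[..., :]`` follows :data:`TENSOR_ELEMENTS` order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), in mm^2/s. Eigen-decomposition is
    computed lazily and cached; eigenvalues are sorted descending and
    clamped at :data:`EIGENVALUE_EPS` (the clamp count is recorded).
    """

    elements: np.ndarray
    voxel_size: float
    mask: np.ndarray | None = None
    n_floored_signals: int = 0
    _evals: np.ndarray | None = field(default=None, repr=False)
    _evecs: np.ndarray | None = field(default=None, repr=False)
    n_clamped_eigenvalues: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[3] != 6:
            raise InvalidParameterError("elements must have shape (x, y, z, 6)")

    @property
    def shape(self) -> tuple:
        return self.elements.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 tensor per voxel, shape (x, y, z, 3, 3)."""
        e = self.elements
        m = np.empty(self.shape + (3, 3))
        m[..., 0, 0] = e[..., 0]
        m[..., 1, 1] = e[..., 1]
        m[..., 2, 2] = e[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = e[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = e[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = e[..., 5]
        return m

    def _decompose(self) -> None:
        if self._evals is not None:
            return
        if self.mask is not None:
            # only fitted voxels carry tensors; skip the zero background
            e = self.elements[self.mask]
            m = np.zeros((e.shape[0], 3, 3))
            m[:, 0, 0] = e[:, 0]
            m[:, 1, 1] = e[:, 1]
            m[:, 2, 2] = e[:, 2]
            m[:, 0, 1] = m[:, 1, 0] = e[:, 3]
            m[:, 0, 2] = m[:, 2, 0] = e[:, 4]
            m[:, 1, 2] = m[:, 2, 1] = e[:, 5]
            vals, vecs = np.linalg.eigh(m)
            full_vals = np.zeros(self.shape + (3,))
            full_vecs = np.zeros(self.shape + (3, 3))
            full_vecs[..., :, :] = np.eye(3)
            full_vals[self.mask] = vals[:, ::-1]
            full_vecs[self.mask] = vecs[:, :, ::-1]
            vals, vecs = full_vals, full_vecs
        else:
            vals, vecs = np.linalg.eigh(self.as_matrices())
            vals = vals[..., ::-1]          # descending: l1 >= l2 >= l3
            vecs = vecs[..., ::-1]
        self.n_clamped_eigenvalues = int(np.count_nonzero(vals < 0))
        self._evals = np.maximum(vals, EIGENVALUE_EPS)
        self._evecs = vecs

    @property
    def eigenvalues(self) -> np.ndarray:
        self._decompose()
        return self._evals

    @property
    def principal_eigenvector(self) -> np.ndarray:
        self._decompose()
        return self._evecs[..., :, 0]


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None,
               wls: bool = False) -> TensorVolume:
    """Log-linear least-squares tensor fit.

    Parameters
    ----------
    dwi : DWIVolume
        4D signal with its gradient table. At least one b=0 channel and
        six non-collinear b>0 directions are required.
    mask : ndarray of bool, optional
        Voxels to fit; unfitted voxels get zero tensors.
    wls : bool
        Weighted least squares with the squared floored signals as
        weights (the usual approximation to the log-domain noise
        variance). Default is the plain unweighted fit.
    """
    gtab = dwi.gtab
    if gtab.n_b0 < 1:
        raise RankDeficiencyError("at least one b=0 channel is required")
    A = design_matrix(gtab)
    if np.linalg.matrix_rank(A) < 7:
        raise RankDeficiencyError("gradient scheme does not support a tensor fit")

    shape = dwi.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    S = dwi.data[mask]                               # (N, K)

    s0 = S[:, gtab.b0_mask].mean(axis=1)
    s0 = np.maximum(s0, np.finfo(float).tiny)
    floor = SIGNAL_FLOOR_FRAC * s0
    n_floored = int(np.count_nonzero(S < floor[:, None]))
    y = np.log(np.maximum(S, floor[:, None]))        # (N, K)

    if wls:
        w = np.maximum(S, floor[:, None]) ** 2       # (N, K)
        ata = np.einsum("nk,ki,kj->nij", w, A, A)
        atb = np.einsum("nk,ki,nk->ni", w, A, y)
        coef = np.linalg.solve(ata, atb[..., None])[..., 0]   # (N, 7)
    else:
        coef = y @ np.linalg.pinv(A).T               # (N, 7)

    elements = np.zeros(shape + (6,))
    elements[mask] = coef[:, :6]
    return TensorVolume(elements, dwi.voxel_size, mask=mask,
                        n_floored_signals=n_floored)


def fa_adc_maps(tensors: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Fractional anisotropy and mean diffusivity (ADC) maps.

    FA = sqrt(1/2) * sqrt(sum of squared eigenvalue differences) /
    sqrt(sum of squared eigenvalues); FA of an all-zero tensor is 0.
    ADC is the eigenvalue mean (trace / 3).
    """
    lam = tensors.eigenvalues
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    adc = lam.mean(axis=-1)
    return fa, adc


def axis_diffusivities(
    tensors: TensorVolume,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apparent diffusivity along each image axis: the tensor diagonal."""
    e = tensors.elements
    return e[..., 0].copy(), e[..., 1].copy(), e[..., 2].copy()


def dec_map(tensors: TensorVolume) -> np.ndarray:
    """Directionally-encoded color volume.

    Channel c = FA * |principal eigenvector component c|, clipped to
    [0, 1]; red = x, green = y, blue = z.
    """
    fa, _ = fa_adc_maps(tensors)
    v1 = tensors.principal_eigenvector
    return np.clip(fa[..., None] * np.abs(v1), 0.0, 1.0)
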