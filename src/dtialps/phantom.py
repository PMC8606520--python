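"""Synthetic two-hemisphere diffusion phantoms and study-calibrated cohorts.

The phantom emulates the periventricular geometry that the perivascular
diffusivity (ALPS) method exploits: in each hemisphere, a projection-fiber
region (corona radiata, principal diffusion along z) sits beside the
lateral-ventricle body and an association-fiber region (superior
longitudinal fascicle, principal diffusion along y) lies lateral to it.
Perivascular flow along the medullary veins shows up as an elevated
left-right (x) diffusivity component in both regions, and the ALPS index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

quantifies it. ``solve_region_tensors`` inverts this relation so a phantom
hemisphere realizes any requested index exactly; ``sample_cohort`` draws
whole stroke-patient/control cohorts whose covariates, lesion parameters
and per-hemisphere index targets are calibrated to the published cohort
statistics (see docs/methods.md for the calibration).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats as sps

from .core import (
    GradientTable,
    DWIVolume,
    GeometryError,
    InvalidParameterError,
    Label,
    LabelVolume,
)
from .dtifit import TensorVolume, _quadratic_weights

Side = Literal["right", "left"]

# ---------------------------------------------------------------------------
# region tensors


@dataclass
class RegionTensorSet:
    """Diagonal tensors (mm^2/s) of one hemisphere's fiber regions.

    The x entries may be ``None`` in a baseline set; they are filled by
    :func:`solve_region_tensors`.
    """

    proj_dxx: float | None
    proj_dyy: float
    proj_dzz: float
    assoc_dxx: float | None
    assoc_dyy: float
    assoc_dzz: float

    def validate(self) -> None:
        vals = [self.proj_dxx, self.proj_dyy, self.proj_dzz,
                self.assoc_dxx, self.assoc_dyy, self.assoc_dzz]
        if any(v is None or v <= 0 for v in vals):
            raise InvalidParameterError("all tensor entries must be positive")
        if self.proj_dzz < max(self.proj_dxx, self.proj_dyy):
            raise InvalidParameterError("projection region must have Dzz largest")
        if self.assoc_dyy < max(self.assoc_dxx, self.assoc_dzz):
            raise InvalidParameterError("association region must have Dyy largest")

    def alps_index(self) -> float:
        """Index realized by this set (x diffusivities over cross terms)."""
        return ((self.proj_dxx + self.assoc_dxx) / 2.0) / (
            (self.proj_dyy + self.assoc_dzz) / 2.0
        )


#: baseline white-matter diffusivities; only the ratio enters the index.
DEFAULT_BASELINE = RegionTensorSet(
    proj_dxx=None, proj_dyy=0.7e-3, proj_dzz=1.7e-3,
    assoc_dxx=None, assoc_dyy=1.7e-3, assoc_dzz=0.7e-3,
)


def solve_region_tensors(
    target_alps: float, baseline: RegionTensorSet = DEFAULT_BASELINE
) -> RegionTensorSet:
    """Fill the x-axis diffusivities so the region set realizes an index.

    Sets ``Dxx_proj = Dxx_assoc = target * mean(Dyy_proj, Dzz_assoc)``,
    copying all other entries from the baseline, so the realized index
    equals ``target_alps`` exactly.
    """
    if not np.isfinite(target_alps) or target_alps <= 0:
        raise InvalidParameterError("target ALPS index must be positive")
    for v in (baseline.proj_dyy, baseline.proj_dzz,
              baseline.assoc_dyy, baseline.assoc_dzz):
        if v is None or v <= 0:
            raise InvalidParameterError("baseline entries must be positive")
    dxx = target_alps * 0.5 * (baseline.proj_dyy + baseline.assoc_dzz)
    out = replace(baseline, proj_dxx=dxx, assoc_dxx=dxx)
    out.validate()
    return out


def prolate_eigenvalues(adc: float, fa: float) -> tuple[float, float]:
    """Eigenvalues (l1, l2=l3) of a prolate tensor with given ADC and FA.

    With l1 = m(1+2d) and l2 = m(1-d), FA reduces to 3d/sqrt(3+6d^2),
    which inverts to d = fa / sqrt(3 - 2 fa^2).
    """
    if adc <= 0:
        raise InvalidParameterError("ADC must be positive")
    if not 0 <= fa < 1:
        raise InvalidParameterError("FA must lie in [0, 1)")
    d = fa / math.sqrt(3.0 - 2.0 * fa * fa)
    return adc * (1 + 2 * d), adc * (1 - d)


# ---------------------------------------------------------------------------
# geometry


def _mirror(xs: tuple[int, int], nx: int) -> tuple[int, int]:
    """Mirror an inclusive x-index range across the midline."""
    return (nx - 1 - xs[1], nx - 1 - xs[0])


@dataclass
class PhantomGeometry:
    """Grid layout of the two-hemisphere phantom.

    All ROI boxes are inclusive index ranges on the *right* hemisphere
    (x < midline); left-hemisphere structures are mirror images across
    the midline, so ROI voxel counts are equal by construction. The fiber
    ROIs live on the single slice at the lateral-ventricle-body level.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: float = 2.0          # mm, isotropic
    alps_slice: int = 16             # z index of the ventricle-body level
    proj_x: tuple[int, int] = (25, 26)
    proj_y: tuple[int, int] = (30, 31)
    assoc_x: tuple[int, int] = (20, 21)
    assoc_y: tuple[int, int] = (30, 31)
    ventricle_x: tuple[int, int] = (28, 35)
    ventricle_y: tuple[int, int] = (24, 40)
    ventricle_z: tuple[int, int] = (12, 20)
    infarct_seed_right: tuple[int, int, int] = (12, 20, 16)
    roi_guard: int = 2               # voxels kept clear around fiber ROIs

    @property
    def midline(self) -> int:
        return self.shape[0] // 2

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size ** 3

    def hemisphere_mask(self, side: Side) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if side == "right":
            m[: self.midline] = True
        else:
            m[self.midline:] = True
        return m

    def _box(self, xs, ys, zs) -> tuple[slice, slice, slice]:
        return (slice(xs[0], xs[1] + 1), slice(ys[0], ys[1] + 1),
                slice(zs[0], zs[1] + 1))

    def roi_box(self, region: str, side: Side) -> tuple[slice, slice, slice]:
        xs, ys = ((self.proj_x, self.proj_y) if region == "proj"
                  else (self.assoc_x, self.assoc_y))
        if side == "left":
            xs = _mirror(xs, self.shape[0])
        return self._box(xs, ys, (self.alps_slice, self.alps_slice))

    def ventricle_box(self) -> tuple[slice, slice, slice]:
        return self._box(self.ventricle_x, self.ventricle_y, self.ventricle_z)

    def infarct_seed(self, side: Side) -> tuple[int, int, int]:
        x, y, z = self.infarct_seed_right
        if side == "left":
            x = self.shape[0] - 1 - x
        return (x, y, z)


# ---------------------------------------------------------------------------
# subject and cohort specifications


@dataclass
class SubjectSpec:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    group: Literal["patient", "control"]
    age: float
    sex: Literal["man", "woman"]
    alps_target_right: float
    alps_target_left: float
    infarct_side: Side | None = None
    infarct_volume_cm3: float | None = None
    infarct_adc: float | None = None        # 1e-6 mm^2/s
    infarct_fa: float | None = None
    hemorrhage: bool = False
    time_since_onset_days: float | None = None
    s0: float = 1000.0
    noise_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alps_target_right <= 0 or self.alps_target_left <= 0:
            raise InvalidParameterError("ALPS targets must be positive")
        if self.group == "patient":
            if self.infarct_side not in ("right", "left"):
                raise InvalidParameterError("patients need an infarct side")
            if self.time_since_onset_days is None or self.time_since_onset_days < 1:
                raise InvalidParameterError("time since onset must be >= 1 day")
            if None in (self.infarct_volume_cm3, self.infarct_adc,
                        self.infarct_fa):
                raise InvalidParameterError("patients need lesion targets")
        else:
            if self.infarct_side is not None or self.hemorrhage:
                raise InvalidParameterError("controls carry no lesion fields")

    @property
    def alps_target_ipsi(self) -> float:
        if self.infarct_side is None:
            raise InvalidParameterError("no infarct side defined")
        return (self.alps_target_right if self.infarct_side == "right"
                else self.alps_target_left)

    @property
    def alps_target_contra(self) -> float:
        if self.infarct_side is None:
            raise InvalidParameterError("no infarct side defined")
        return (self.alps_target_left if self.infarct_side == "right"
                else self.alps_target_right)


@dataclass
class CohortConfig:
    """Distributional parameters of a simulated stroke cohort.

    The defaults built by :func:`default_cohort_config` reproduce the
    published cohort: covariate moments, the stratified time-since-onset
    and infarct-volume distributions, the linear dependence of the
    ipsilateral index on time (slope per day, with the residual spread
    solved so the standardized coefficient matches in expectation), and
    the interhemispheric ratio distributions. Time and volume strata are
    negatively coupled through a Gaussian rank copula.
    """

    n_patients: int = 50
    n_controls: int = 44
    # covariates
    age_patient: tuple[float, float] = (56.7, 15.2)
    age_patient_range: tuple[float, float] = (18.0, 95.0)
    age_control: tuple[float, float] = (53.3, 9.9)
    age_control_range: tuple[float, float] = (27.0, 83.0)
    male_prob_patient: float = 30 / 50
    male_prob_control: float = 23 / 44
    right_side_prob: float = 32 / 50
    hemorrhage_prob: float = 19 / 50
    # lesion tissue targets
    infarct_adc: tuple[float, float] = (709.13, 310.39)     # 1e-6 mm^2/s
    infarct_adc_range: tuple[float, float] = (100.0, 1600.0)
    infarct_fa: tuple[float, float] = (0.149, 0.086)
    infarct_fa_range: tuple[float, float] = (0.02, 0.45)
    # time since onset: early/late stratum mixture on [1, 60] days
    time_split_day: float = 14.0
    time_early_prob: float = 0.656636
    time_early: tuple[float, float] = (9.69314, 3.4)        # mean, sd
    time_late: tuple[float, float] = (31.26457, 16.0)
    time_range: tuple[float, float] = (1.0, 60.0)
    # infarct volume: small/large stratum mixture on [4.12, 134.14] cm^3
    vol_split_cm3: float = 20.0
    vol_small_prob: float = 33 / 50
    vol_small_parent: tuple[float, float] = (10.924818, 5.712178)
    vol_large_parent: tuple[float, float] = (79.204099, 48.630577)
    vol_range: tuple[float, float] = (4.12, 134.14)
    # rank-copula correlation between time and volume
    time_volume_rho: float = -0.6956
    # ALPS model: ipsi = ratio * contra, ratio linear in time
    alps_time_slope: float = 0.007          # d(ipsi)/d(day) in expectation
    contra_mean: float = 1.335
    contra_sd: float = 0.0563               # solved, see default_cohort_config
    ratio_mean_right: float = 0.84          # E[ipsi/contra | right infarct]
    ratio_mean_left: float = 0.92
    ratio_resid_sd: float = 0.02
    # controls
    control_alps_mean: float = 1.37
    control_alps_sd: float = 0.14
    control_ratio: tuple[float, float] = (0.95, 0.07)       # right-to-left
    # acquisition
    s0: float = 1000.0
    noise_sigma: float = 20.0               # Rician sigma; SNR 50 at b=0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contra_sd", "ratio_resid_sd", "control_alps_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not np.isfinite(self.alps_time_slope):
            raise InvalidParameterError("slope must be finite")
        if self.contra_mean <= 0 or self.control_alps_mean <= 0:
            raise InvalidParameterError("ALPS levels must be positive")

    # -- derived quantities ------------------------------------------------

    @property
    def ratio_slope_per_day(self) -> float:
        """Slope of the ipsi/contra ratio in time implied by the index slope."""
        return self.alps_time_slope / self.contra_mean

    @property
    def time_mean(self) -> float:
        p = self.time_early_prob
        return p * self.time_early[0] + (1 - p) * self.time_late[0]

    @property
    def time_sd(self) -> float:
        p = self.time_early_prob
        between = p * (1 - p) * (self.time_late[0] - self.time_early[0]) ** 2
        within = p * self.time_early[1] ** 2 + (1 - p) * self.time_late[1] ** 2
        return math.sqrt(between + within)

    def ratio_intercept(self, side: Side) -> float:
        mean = self.ratio_mean_right if side == "right" else self.ratio_mean_left
        return mean - self.ratio_slope_per_day * self.time_mean

    def alps_time_intercept(self, side: Side) -> float:
        """Intercept of E[ipsi | time] = intercept + slope * time."""
        return self.contra_mean * self.ratio_intercept(side)

    def expected_std_beta(self) -> float:
        """Closed-form standardized coefficient of the ipsi-on-time regression."""
        return self.alps_time_slope * self.time_sd / self.ipsi_sd

    @property
    def ratio_mean(self) -> float:
        p = self.right_side_prob
        return p * self.ratio_mean_right + (1 - p) * self.ratio_mean_left

    @property
    def ipsi_sd(self) -> float:
        """Marginal SD of the true ipsilateral index under this config."""
        p = self.right_side_prob
        side_var = p * (1 - p) * (self.ratio_mean_right - self.ratio_mean_left) ** 2
        var_q = (self.ratio_slope_per_day ** 2 * self.time_sd ** 2
                 + side_var + self.ratio_resid_sd ** 2)
        eq2 = self.ratio_mean ** 2 + var_q
        return math.sqrt(eq2 * self.contra_sd ** 2
                         + var_q * self.contra_mean ** 2)


#: published cohort values the defaults are calibrated against.
STUDY = {
    "ipsi_mean": 1.162, "ipsi_sd": 0.126,
    "contra_mean": 1.335, "contra_sd": 0.160,
    "ratio_rl_right_infarct": 0.84, "ratio_lr_left_infarct": 0.92,
    "control_ratio_rl": 0.95, "control_ratio_lr": 1.05,
    "time_mean": 17.1, "time_sd": 14.8,
    "alps_time_slope": 0.007, "std_beta_time": 0.794,
    "alps_time_early": 1.108, "alps_time_late": 1.259,
    "alps_vol_small": 1.189, "alps_vol_large": 1.110,
    "icc_alps": 0.838,
}


def default_cohort_config(master_seed: int = 0, **overrides) -> CohortConfig:
    """Cohort configuration calibrated to the published tables.

    The time-stratum mixture (fraction, conditional means) is solved in
    closed form from the time-stratified index means and the slope; the
    contralateral spread is solved so that the standardized coefficient
    of the ipsi-on-time regression matches the published value via
    beta = slope * SD_time / SD_ipsi.
    """
    cfg = CohortConfig(master_seed=master_seed)
    bq = cfg.ratio_slope_per_day
    rbar = cfg.ratio_mean
    # time offsets (days, relative to the overall mean) that reproduce the
    # time-stratified index means under the linear-ratio model
    a_early = (STUDY["alps_time_early"] / cfg.contra_mean - rbar) / bq
    a_late = (STUDY["alps_time_late"] / cfg.contra_mean - rbar) / bq
    p_early = a_late / (a_late - a_early)
    mu_t = STUDY["time_mean"]
    cfg = replace(
        cfg,
        time_early_prob=p_early,
        time_early=(mu_t + a_early, cfg.time_early[1]),
        time_late=(mu_t + a_late, cfg.time_late[1]),
    )
    # contralateral spread from the standardized-coefficient identity
    p = cfg.right_side_prob
    side_var = p * (1 - p) * (cfg.ratio_mean_right - cfg.ratio_mean_left) ** 2
    var_q = bq ** 2 * cfg.time_sd ** 2 + side_var + cfg.ratio_resid_sd ** 2
    sd_y = cfg.alps_time_slope * cfg.time_sd / STUDY["std_beta_time"]
    contra_var = (sd_y ** 2 - var_q * cfg.contra_mean ** 2) / (rbar ** 2 + var_q)
    if contra_var <= 0:
        raise InvalidParameterError("standardized-beta calibration infeasible")
    cfg = replace(cfg, contra_sd=math.sqrt(contra_var))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# cohort sampling


def _beta_from_moments(lo: float, hi: float, mean: float, sd: float):
    """Scaled Beta distribution on [lo, hi] with the given moments."""
    w = hi - lo
    m = (mean - lo) / w
    vf = (sd / w) ** 2
    s = m * (1 - m) / vf - 1
    if s <= 0 or not 0 < m < 1:
        raise InvalidParameterError("Beta moments infeasible on this interval")
    return sps.beta(m * s, (1 - m) * s, loc=lo, scale=w)


def _truncnorm(parent: tuple[float, float], lo: float, hi: float):
    m, s = parent
    return sps.truncnorm((lo - m) / s, (hi - m) / s, loc=m, scale=s)


def _mixture_ppf(u, p_low, d_low, d_high):
    """Quantile of a two-component mixture with ordered disjoint supports."""
    u = np.asarray(u, dtype=float)
    lo = d_low.ppf(np.clip(u / p_low, 0.0, 1.0))
    hi = d_high.ppf(np.clip((u - p_low) / (1.0 - p_low), 0.0, 1.0))
    return np.where(u < p_low, lo, hi)


def _draw_trunc_normal(rng, mean, sd, lo, hi) -> float:
    """Rejection-sampled normal restricted to [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InvalidParameterError("truncation bounds reject all samples")


def sample_cohort(config: CohortConfig) -> list[SubjectSpec]:
    """Draw patient and control specifications for one replicate cohort.

    Patients: time since onset and infarct volume come from their
    stratum mixtures coupled by a Gaussian rank copula; the ipsi/contra
    ratio is linear in time with a side-specific level; the ipsilateral
    index is ratio x contralateral. Controls: a left-hemisphere level
    and a right-to-left ratio. All draws derive from the master seed, so
    identical configurations yield identical cohorts.
    """
    rng = np.random.default_rng(config.master_seed)
    d_time_early = _beta_from_moments(config.time_range[0], config.time_split_day,
                                      *config.time_early)
    d_time_late = _beta_from_moments(config.time_split_day, config.time_range[1],
                                     *config.time_late)
    d_vol_small = _truncnorm(config.vol_small_parent, config.vol_range[0],
                             config.vol_split_cm3)
    d_vol_large = _truncnorm(config.vol_large_parent, config.vol_split_cm3,
                             config.vol_range[1])
    rho = config.time_volume_rho

    specs: list[SubjectSpec] = []
    for i in range(config.n_patients):
        z1 = rng.standard_normal()
        z2 = rho * z1 + math.sqrt(1 - rho ** 2) * rng.standard_normal()
        t = float(_mixture_ppf(sps.norm.cdf(z1), config.time_early_prob,
                               d_time_early, d_time_late))
        vol = float(_mixture_ppf(sps.norm.cdf(z2), config.vol_small_prob,
                                 d_vol_small, d_vol_large))
        side: Side = "right" if rng.random() < config.right_side_prob else "left"
        contra = _draw_trunc_normal(rng, config.contra_mean, config.contra_sd,
                                    1e-6, np.inf)
        q = (config.ratio_intercept(side) + config.ratio_slope_per_day * t
             + rng.normal(0.0, config.ratio_resid_sd))
        q = max(q, 1e-6)
        ipsi = q * contra
        right, left = (ipsi, contra) if side == "right" else (contra, ipsi)
        specs.append(SubjectSpec(
            subject_id=f"pat{i:03d}",
            group="patient",
            age=_draw_trunc_normal(rng, *config.age_patient,
                                   *config.age_patient_range),
            sex="man" if rng.random() < config.male_prob_patient else "woman",
            alps_target_right=right,
            alps_target_left=left,
            infarct_side=side,
            infarct_volume_cm3=vol,
            infarct_adc=_draw_trunc_normal(rng, *config.infarct_adc,
                                           *config.infarct_adc_range),
            infarct_fa=_draw_trunc_normal(rng, *config.infarct_fa,
                                          *config.infarct_fa_range),
            hemorrhage=bool(rng.random() < config.hemorrhage_prob),
            time_since_onset_days=t,
            s0=config.s0,
            noise_sigma=config.noise_sigma,
            seed=int(rng.integers(2 ** 31)),
        ))

    for i in range(config.n_controls):
        left = _draw_trunc_normal(rng, config.control_alps_mean,
                                  config.control_alps_sd, 1e-6, np.inf)
        q = _draw_trunc_normal(rng, *config.control_ratio, 1e-6, np.inf)
        specs.append(SubjectSpec(
            subject_id=f"ctl{i:03d}",
            group="control",
            age=_draw_trunc_normal(rng, *config.age_control,
                                   *config.age_control_range),
            sex="man" if rng.random() < config.male_prob_control else "woman",
            alps_target_right=q * left,
            alps_target_left=left,
            s0=config.s0,
            noise_sigma=config.noise_sigma,
            seed=int(rng.integers(2 ** 31)),
        ))
    return specs


# ---------------------------------------------------------------------------
# phantom construction

#: isotropic diffusivities of non-fiber tissue classes (mm^2/s)
BACKGROUND_DIFFUSIVITY = 0.75e-3
CSF_DIFFUSIVITY = 3.0e-3
HEMORRHAGE_ADC = 0.40e-3
HEMORRHAGE_FA = 0.05
HEMORRHAGE_CORE_FRACTION = 0.10


def _diag(dxx: float, dyy: float, dzz: float) -> np.ndarray:
    return np.array([dxx, dyy, dzz, 0.0, 0.0, 0.0])


def build_subject_phantom(
    spec: SubjectSpec,
    geometry: PhantomGeometry | None = None,
    baseline: RegionTensorSet = DEFAULT_BASELINE,
) -> tuple[LabelVolume, TensorVolume]:
    """Label volume and piecewise-constant ground-truth tensor field.

    Fiber ROIs are mirror-symmetric boxes on the ventricle-body slice;
    each hemisphere's region tensors are solved from the subject's index
    target. Patient phantoms add an infarct grown voxel-by-voxel around
    a deep seed point on the specified side (nearest-first, deterministic
    tie-break) until it matches the target volume within one voxel,
    avoiding the ventricle and a guard band around the fiber ROIs. The
    infarct tensor is prolate (principal axis z) with the target ADC and
    FA; an optional hemorrhagic core replaces the innermost tenth of the
    lesion.
    """
    geom = geometry or PhantomGeometry()
    labels = np.zeros(geom.shape, dtype=np.int16)
    tensors = np.empty(geom.shape + (6,))
    tensors[:] = _diag(BACKGROUND_DIFFUSIVITY, BACKGROUND_DIFFUSIVITY,
                       BACKGROUND_DIFFUSIVITY)

    labels[geom.ventricle_box()] = Label.VENTRICLE
    tensors[geom.ventricle_box()] = _diag(
        CSF_DIFFUSIVITY, CSF_DIFFUSIVITY, CSF_DIFFUSIVITY)

    region_labels = {
        ("proj", "right"): Label.PROJ_RIGHT, ("proj", "left"): Label.PROJ_LEFT,
        ("assoc", "right"): Label.ASSOC_RIGHT, ("assoc", "left"): Label.ASSOC_LEFT,
    }
    for side in ("right", "left"):
        target = (spec.alps_target_right if side == "right"
                  else spec.alps_target_left)
        rts = solve_region_tensors(target, baseline)
        for region in ("proj", "assoc"):
            box = geom.roi_box(region, side)
            labels[box] = region_labels[(region, side)]
            if region == "proj":
                tensors[box] = _diag(rts.proj_dxx, rts.proj_dyy, rts.proj_dzz)
            else:
                tensors[box] = _diag(rts.assoc_dxx, rts.assoc_dyy, rts.assoc_dzz)

    if spec.group == "patient":
        _add_infarct(spec, geom, labels, tensors)

    return (LabelVolume(labels, geom.voxel_size),
            TensorVolume(tensors, geom.voxel_size))


def _add_infarct(spec: SubjectSpec, geom: PhantomGeometry,
                 labels: np.ndarray, tensors: np.ndarray) -> None:
    n_target = int(round(spec.infarct_volume_cm3 * 1000.0
                         / geom.voxel_volume_mm3))
    if n_target < 1:
        raise GeometryError("infarct volume below one voxel")

    allowed = geom.hemisphere_mask(spec.infarct_side)
    allowed &= labels == Label.BACKGROUND
    # guard band around the fiber ROIs so lesion growth never contaminates them
    g = geom.roi_guard
    for region in ("proj", "assoc"):
        sx, sy, sz = geom.roi_box(region, spec.infarct_side)
        allowed[max(0, sx.start - g): sx.stop + g,
                max(0, sy.start - g): sy.stop + g,
                max(0, sz.start - g): sz.stop + g] = False
    if n_target > int(allowed.sum()):
        raise GeometryError(
            f"infarct of {n_target} voxels exceeds hemisphere capacity")

    seed = np.array(geom.infarct_seed(spec.infarct_side), dtype=float)
    idx = np.argwhere(allowed)
    dist = np.linalg.norm(idx - seed, axis=1)
    flat = np.ravel_multi_index(idx.T, geom.shape)
    order = np.lexsort((flat, dist))          # nearest first, deterministic
    chosen = idx[order[:n_target]]

    lam1, lam2 = prolate_eigenvalues(spec.infarct_adc * 1e-6, spec.infarct_fa)
    labels[tuple(chosen.T)] = Label.INFARCT
    tensors[tuple(chosen.T)] = _diag(lam2, lam2, lam1)

    if spec.hemorrhage:
        n_core = max(1, int(round(HEMORRHAGE_CORE_FRACTION * n_target)))
        core = idx[order[:n_core]]
        h1, h2 = prolate_eigenvalues(HEMORRHAGE_ADC, HEMORRHAGE_FA)
        labels[tuple(core.T)] = Label.HEMORRHAGE
        tensors[tuple(core.T)] = _diag(h2, h2, h1)


# ---------------------------------------------------------------------------
# signal simulation


def simulate_dwi(
    truth: TensorVolume,
    gtab: GradientTable,
    s0: float = 1000.0,
    sigma: float = 20.0,
    seed: int = 0,
) -> DWIVolume:
    """Monoexponential tensor signal with Rician noise.

    The noiseless signal is ``S0 exp(-b g^T D g)`` per voxel and
    direction; Rician noise is the magnitude of the complex signal after
    adding independent Gaussian noise of standard deviation ``sigma`` to
    both quadrature channels. Identical seeds give identical volumes.
    """
    if s0 < 0:
        raise InvalidParameterError("S0 must be non-negative")
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    w = _quadratic_weights(gtab)                       # (K, 6)
    exponent = truth.elements @ w.T                    # b g^T D g
    signal = s0 * np.exp(-exponent)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((2,) + signal.shape)
        noise *= sigma
        noise[0] += signal
        np.square(noise, out=noise)
        signal = np.sqrt(noise[0] + noise[1])
    return DWIVolume(signal, truth.voxel_size, gtab)
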