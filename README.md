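# dtialps

Simulation and analysis of the **DTI-ALPS** index — a diffusion-MRI
proxy for glymphatic (perivascular fluid clearance) function — in an
ischemic-stroke cohort design.

At the level of the lateral-ventricle body, perivascular spaces of the
deep medullary veins run left–right (x), perpendicular to the
projection fibers (z) and association fibers (y) beside them. The
index contrasts the x-axis diffusivity in both fiber regions against
the diffusivities perpendicular to both the fibers and x:

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

Values near 1 mean no perivascular excess; stroke lowers the index in
the infarcted hemisphere, and it recovers with time since onset.

The package is aimed at researchers who want a fully testable, fully
synthetic version of this analysis: every stage — two-hemisphere
phantom with known region tensors, Rician-noise DWI synthesis,
log-linear tensor fitting, ROI-based index extraction, infarct
volume/ADC/FA measurement, and the cohort statistics (paired t-test,
age/sex-adjusted ANCOVA of interhemispheric ratios, ICC, univariable
and stepwise regression) — runs against ground truth, with a cohort
generator calibrated to a published 50-patient / 44-control stroke
study. See `docs/methods.md` for the model and calibration details.

## Worked example

```python
import dtialps as d

# one hemisphere engineered to a target index of 1.335
rts = d.solve_region_tensors(1.335)
print(f"{rts.proj_dxx:.4e}", f"{rts.alps_index():.3f}")
# 9.3450e-04 1.335

# a patient phantom, noisy DWI, tensor fit, index measurement
spec = d.SubjectSpec(
    subject_id="demo", group="patient", age=61.0, sex="man",
    alps_target_right=1.10, alps_target_left=1.30,
    infarct_side="right", infarct_volume_cm3=8.0,
    infarct_adc=709.0, infarct_fa=0.149,
    time_since_onset_days=10.0, seed=7,
)
labels, truth = d.build_subject_phantom(spec)
dwi = d.simulate_dwi(truth, d.default_gradient_table(),
                     s0=1000.0, sigma=20.0, seed=7)
tensors = d.fit_tensor(dwi, mask=labels.data > 0)
dxx, dyy, dzz = d.axis_diffusivities(tensors)
res = d.subject_alps(dxx, dyy, dzz, labels, infarct_side="right")
print(f"right {res.right_index:.3f}  left {res.left_index:.3f}  "
      f"R/L {res.ratio_rl:.3f}")
# right 1.136  left 1.274  R/L 0.892
```

The estimated indices scatter a few percent around the built-in
targets (1.10 / 1.30) for a single subject at the default SNR of 50 —
the ROIs are only four voxels each, as in the clinical protocol — while
the bias averaged across subjects stays below 1%. The right-to-left
ratio below 1 reflects the simulated right-sided infarct. A whole
calibrated cohort with the four-table statistical report:

```python
from dtialps.pipeline import RunConfig, run_pipeline
result = run_pipeline(RunConfig(outdir="out"))   # ~20-30 s, 94 subjects
print(result.report.table4.loc["time_since_onset_days"])
```

or from the shell:

```
dtialps run --seed 0 --outdir out
dtialps simulate --seed 0 --n-patients 1 --n-controls 1 --outdir vols
dtialps fit --dwi vols/pat000/dwi.nii.gz --bval vols/pat000/dwi.bval \
            --bvec vols/pat000/dwi.bvec --outdir maps
```

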