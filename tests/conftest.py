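import numpy as np
import pytest

import dtialps as d


@pytest.fixture(scope="session")
def gtab():
    return d.default_gradient_table()


@pytest.fixture(scope="session")
def small_geometry():
    """Compact grid for fast end-to-end unit tests."""
    return d.PhantomGeometry(
        shape=(32, 32, 16),
        alps_slice=8,
        proj_x=(11, 12), proj_y=(15, 16),
        assoc_x=(7, 8), assoc_y=(15, 16),
        ventricle_x=(14, 17), ventricle_y=(12, 20), ventricle_z=(6, 10),
        infarct_seed_right=(5, 8, 8),
    )


@pytest.fixture(scope="session")
def patient_spec():
    return d.SubjectSpec(
        subject_id="pat000", group="patient", age=60.0, sex="man",
        alps_target_right=1.10, alps_target_left=1.30,
        infarct_side="right", infarct_volume_cm3=8.0,
        infarct_adc=709.0, infarct_fa=0.149, hemorrhage=True,
        time_since_onset_days=10.0, seed=42,
    )


@pytest.fixture(scope="session")
def control_spec():
    return d.SubjectSpec(
        subject_id="ctl000", group="control", age=55.0, sex="woman",
        alps_target_right=1.30, alps_target_left=1.35, seed=43,
    )


@pytest.fixture(scope="session")
def noiseless_patient(patient_spec, small_geometry, gtab):
    """Phantom, truth tensors and a noiseless fit for one patient."""
    labels, truth = d.build_subject_phantom(patient_spec, small_geometry)
    dwi = d.simulate_dwi(truth, gtab, s0=1000.0, sigma=0.0, seed=0)
    tensors = d.fit_tensor(dwi)
    return labels, truth, tensors
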