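import numpy as np
import pytest

from prait import (
    ConcentrationSeries,
    InfusionRecord,
    TwoCompartmentParams,
    predict_concentration,
)
from prait.population_fit import PatientRecord
from prait.synthetic_cohort import NoiseConfig, sample_patient, simulate_trial


@pytest.fixture(scope="session")
def tf2_population_params():
    """Published population estimates of the antibody serum model."""
    return TwoCompartmentParams(k_pc=0.034, k_cp=0.0075, k_el=0.182, vol_per_m2=1.86)


@pytest.fixture(scope="session")
def serum_schedule():
    return np.array([0.417, 0.583, 1.5, 3.0, 24.0, 48.0, 96.0, 120.0, 168.0])


@pytest.fixture(scope="session")
def noise_free_record(tf2_population_params, serum_schedule):
    """One patient's noise-free antibody series at the trial's schedule."""
    infusions = [InfusionRecord(dose=84.0)]
    values = predict_concentration(tf2_population_params, 1.9, infusions, serum_schedule)
    series = ConcentrationSeries(times=serum_schedule, values=values)
    return PatientRecord("p1", 1.9, [series], [infusions])


@pytest.fixture(scope="session")
def synthetic_cohort_8():
    """Seeded 8-patient cohort with trial-level noise, both sessions each."""
    trials = []
    for i in range(8):
        patient = sample_patient(100 + i, "I")
        trials.append(simulate_trial(patient, noise=NoiseConfig(), seed=500 + i))
    return trials
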