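import numpy as np
import pandas as pd
import pytest

from ki67prog import synthetic_data as sd


@pytest.fixture(scope="session")
def rendered_core():
    """One rendered core with ground truth: 500 nuclei, 30 % positive."""
    truth = sd.random_core_truth(500, frac_positive=0.30, seed=11)
    image, truth, conc = sd.generate_core_image(
        truth, seed=11, return_concentrations=True
    )
    return image, truth, conc


@pytest.fixture(scope="session")
def small_cohort():
    """~1500-patient simulated cohort with the default study conditions."""
    cfg = sd.SimCohortConfig(patients_per_study=(150,) * 10, seed=5)
    return sd.simulate_cohort(cfg), cfg


def surv_frame(entry, exit_, event, **cols):
    """Helper: minimal survival DataFrame."""
    df = pd.DataFrame(
        {"entry_time": np.asarray(entry, float),
         "exit_time": np.asarray(exit_, float),
         "event": np.asarray(event, int)}
    )
    for k, v in cols.items():
        df[k] = v
    return df
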