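import numpy as np
import pytest

from ipmnsurv import LabSeries
from ipmnsurv.simulate import GeneratorConfig, generate_cohort


def make_series(analyte, days, values, unit=None, detection_limit=None):
    units = {"ca19_9": "U/mL", "hba1c": "%", "p_amylase": "U/L",
             "lipase": "U/L", "amylase": "U/L", "cea": "ng/mL"}
    return LabSeries(analyte=analyte, unit=unit or units[analyte],
                     days=np.asarray(days, float),
                     values=np.asarray(values, float),
                     detection_limit=detection_limit)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-case carcinoma cohort plus 20 surveillance controls."""
    cfg = GeneratorConfig(seed=424242, n_carcinoma_cases=120,
                          n_noncancer_patients=20)
    records, truth = generate_cohort(cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def medium_cohort():
    """A 400-case carcinoma cohort for parameter-recovery checks."""
    cfg = GeneratorConfig(seed=20260927, n_carcinoma_cases=400,
                          n_noncancer_patients=0)
    records, truth = generate_cohort(cfg)
    return records, truth, cfg
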