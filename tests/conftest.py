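import dataclasses
import warnings

import pytest

from bmivol.cohort import GeneratorConfig, default_roi_effects, generate_cohort


def pytest_configure(config):
    # statsmodels emits boundary/singular warnings on variance components
    # that are legitimately zero in generated data; fits record them as notes.
    warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at test scale: 6 sites x 50 subjects, 8 ROIs."""
    cfg = GeneratorConfig(n_sites=6, subjects_per_site=50, qc_missing_rate=0.0,
                          seed=2024)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_config():
    """All variance components zero: volumes are exact linear functions."""
    effects = {
        roi: dataclasses.replace(eff, var_site=0.0, var_subject=0.0,
                                 var_residual=0.0)
        for roi, eff in default_roi_effects().items()
    }
    return GeneratorConfig(n_sites=4, subjects_per_site=40, roi_effects=effects,
                           qc_missing_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def noisefree_cohort(noisefree_config):
    return generate_cohort(noisefree_config)
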