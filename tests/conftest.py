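import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cryptdrift import DriftParams, make_niche
from cryptdrift.cohort_synthesis import ArmDesign, CohortDesign


@pytest.fixture
def neutral_params():
    return DriftParams(n_stem=8, replacement_rate=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_arm_design(
    n_stem=8,
    n_centre=4,
    rate=0.5,
    timepoints=(4.0, 10.0),
    mice=2,
    crypts=50,
    labelling_mean=1.2,
    inhibitor_mode="remove_border",
    strength=1.0,
    seed=0,
):
    """Small two-arm cohort design used across cohort/inference tests."""
    params = DriftParams(n_stem=n_stem, replacement_rate=rate)
    layout = make_niche(n_centre, n_stem - n_centre)
    return CohortDesign(
        arms=(
            ArmDesign(name="vehicle", params=params, layout=layout),
            ArmDesign(
                name="inhibitor",
                params=params,
                layout=layout,
                inhibition_mode=inhibitor_mode,
                strength=strength,
            ),
        ),
        timepoints=tuple(float(t) for t in timepoints),
        mice_per_arm=mice,
        crypts_per_mouse=crypts,
        labelling_mean=labelling_mean,
        seed=seed,
    )
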