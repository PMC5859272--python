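"""The package's single documented default parameter set.

No numeric values of N, lambda, bias, compartment sizes or recombination
efficiencies are available from experiments as direct measurements; the
defaults below are one jointly calibrated set, chosen once so that the
simulated cohorts reproduce the headline clonal kinetics (see
docs/methods.md for the calibration rationale), and used everywhere a
default is needed.  They are deliberately defined in a single module so that
"the documented default parameter set" is one importable object.
"""

from __future__ import annotations

from .cohort_synthesis import ArmDesign, CohortDesign
from .drift_core import DriftParams
from .niche_model import NicheLayout, make_niche

#: Competing stem-cell positions per untreated crypt (ring length).
DEFAULT_N_STEM = 20
#: Centre (crypt-base) positions; the pool that survives Wnt inhibition.
DEFAULT_N_CENTRE = 4
DEFAULT_N_BORDER = DEFAULT_N_STEM - DEFAULT_N_CENTRE
#: Replacement events per stem cell per day (boundary-resolution rate).
DEFAULT_REPLACEMENT_RATE = 0.75
#: Apc-null vs wild-type displacement probability at a clone boundary.
DEFAULT_APC_BIAS = 0.55
#: Border-cell expulsion rate (per cell per day) in border_loss mode.
DEFAULT_BORDER_LOSS_RATE = 0.5
#: Mean induced cells per labelled crypt at low (0.15 mg-style) induction,
#: zero-truncated Poisson.
DEFAULT_LABELLING_MEAN_LOW = 1.2
#: Mean induced cells per labelled crypt at high (3 mg-style) induction.
DEFAULT_LABELLING_MEAN_HIGH = 8.0
#: Crypts per microscope field for the clones-per-field readout.
DEFAULT_CRYPTS_PER_FIELD = 50
#: Fixed-tissue scoring days for the sparse-labelling time course.
DEFAULT_TIMEPOINTS = (4.0, 7.0, 10.0, 14.0, 21.0)
#: Scoring day for the reporter/Apc discordance readout.
DEFAULT_DISCORDANCE_DAY = 10.0
#: Treatment begins 24 h after induction.
DEFAULT_TREATMENT_DAY = 1.0


def default_drift_params(**overrides) -> DriftParams:
    kw = dict(
        n_stem=DEFAULT_N_STEM,
        replacement_rate=DEFAULT_REPLACEMENT_RATE,
    )
    kw.update(overrides)
    return DriftParams(**kw)


def default_layout() -> NicheLayout:
    return make_niche(DEFAULT_N_CENTRE, DEFAULT_N_BORDER)


def vehicle_arm(**param_overrides) -> ArmDesign:
    return ArmDesign(
        name="vehicle",
        params=default_drift_params(**param_overrides),
        layout=default_layout(),
        inhibition_mode="none",
    )


def inhibitor_arm(mode: str = "remove_border", **param_overrides) -> ArmDesign:
    strength = 1.0 if mode == "remove_border" else DEFAULT_BORDER_LOSS_RATE
    return ArmDesign(
        name="inhibitor",
        params=default_drift_params(**param_overrides),
        layout=default_layout(),
        inhibition_mode=mode,
        strength=strength,
    )


def default_fixation_design(
    mice_per_arm: int = 4,
    crypts_per_mouse: int = 250,
    timepoints=DEFAULT_TIMEPOINTS,
    seed: int = 0,
) -> CohortDesign:
    """Sparse-labelling fixation cohort: vehicle vs pool-reducing inhibitor."""
    return CohortDesign(
        arms=(vehicle_arm(), inhibitor_arm()),
        timepoints=tuple(float(t) for t in timepoints),
        mice_per_arm=mice_per_arm,
        crypts_per_mouse=crypts_per_mouse,
        labelling_mean=DEFAULT_LABELLING_MEAN_LOW,
        induction="low",
        seed=seed,
        treatment_day=DEFAULT_TREATMENT_DAY,
        crypts_per_field=DEFAULT_CRYPTS_PER_FIELD,
    )


def default_imaging_design(
    clones_per_arm: int = 60, seed: int = 0
) -> CohortDesign:
    """Daily intravital tracks, single-cell clones, border_loss inhibition."""
    return CohortDesign(
        arms=(vehicle_arm(), inhibitor_arm(mode="border_loss")),
        timepoints=(1.0, 2.0, 3.0, 4.0),
        mice_per_arm=1,
        crypts_per_mouse=clones_per_arm,
        labelling_mean=1e-6,  # effectively exactly one induced cell
        induction="low",
        seed=seed,
        treatment_day=DEFAULT_TREATMENT_DAY,
    )


def default_apc_design(
    mice_per_arm: int = 3,
    crypts_per_mouse: int = 300,
    timepoints=(4.0, 7.0, 14.0, 21.0),
    seed: int = 0,
) -> CohortDesign:
    """High-induction Apc tumour-initiation cohort."""
    return CohortDesign(
        arms=(vehicle_arm(), inhibitor_arm()),
        timepoints=tuple(float(t) for t in timepoints),
        mice_per_arm=mice_per_arm,
        crypts_per_mouse=crypts_per_mouse,
        labelling_mean=DEFAULT_LABELLING_MEAN_HIGH,
        induction="high",
        seed=seed,
        treatment_day=DEFAULT_TREATMENT_DAY,
    )
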