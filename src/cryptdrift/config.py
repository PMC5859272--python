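"""YAML configuration loading and validation for the command-line interface.

Configuration is a single YAML mapping with optional ``cohort`` and
``inference`` sections plus run-level keys (seed, out_dir, log_level).
Unknown keys are rejected with the offending YAML path; numeric values are
validated by the domain dataclasses before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .cohort_synthesis import ArmDesign, CohortDesign
from .defaults import (
    DEFAULT_APC_BIAS,
    DEFAULT_BORDER_LOSS_RATE,
    DEFAULT_CRYPTS_PER_FIELD,
    DEFAULT_LABELLING_MEAN_LOW,
    DEFAULT_N_CENTRE,
    DEFAULT_N_STEM,
    DEFAULT_REPLACEMENT_RATE,
    DEFAULT_TIMEPOINTS,
    DEFAULT_TREATMENT_DAY,
)
from .drift_core import DriftParams
from .errors import ConfigError, ParameterError
from .niche_model import make_niche

_COHORT_KEYS = {
    "kind",
    "n_stem",
    "n_centre",
    "replacement_rate",
    "bias",
    "het_bias",
    "timepoints",
    "mice_per_arm",
    "crypts_per_mouse",
    "labelling_mean",
    "clones_scored_min",
    "induction",
    "inhibitor_mode",
    "inhibitor_strength",
    "treatment_day",
    "crypts_per_field",
    "region_mix",
}
_INFERENCE_KEYS = {
    "n_grid_min",
    "n_grid_max",
    "rate_min",
    "rate_max",
    "labelling_mean",
    "n_rate_grid",
    "condition_on_survival",
}
_TOP_KEYS = {"seed", "out_dir", "log_level", "cohort", "inference"}


@dataclass
class InferenceConfig:
    n_grid_min: int = 4
    n_grid_max: int = 32
    rate_min: float = 0.02
    rate_max: float = 3.0
    labelling_mean: float = DEFAULT_LABELLING_MEAN_LOW
    n_rate_grid: int = 40
    condition_on_survival: bool = True

    def __post_init__(self) -> None:
        if self.n_grid_min < 2 or self.n_grid_max < self.n_grid_min:
            raise ConfigError("inference n grid must satisfy 2 <= min <= max")
        if not 0 < self.rate_min < self.rate_max:
            raise ConfigError("inference rate bounds must satisfy 0 < min < max")


@dataclass
class RunConfig:
    seed: Optional[int] = None
    out_dir: str = "results"
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)
    inference: InferenceConfig = field(default_factory=InferenceConfig)


def _reject_unknown(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under {path!r}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "<top level>")
    cohort = raw.get("cohort", {}) or {}
    if not isinstance(cohort, dict):
        raise ConfigError("'cohort' must be a mapping")
    _reject_unknown(cohort, _COHORT_KEYS, "cohort")
    inf_raw = raw.get("inference", {}) or {}
    if not isinstance(inf_raw, dict):
        raise ConfigError("'inference' must be a mapping")
    _reject_unknown(inf_raw, _INFERENCE_KEYS, "inference")
    try:
        inference = InferenceConfig(**inf_raw)
        cfg = RunConfig(
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir", "results"),
            log_level=str(raw.get("log_level", "INFO")),
            cohort=cohort,
            inference=inference,
        )
        if cfg.cohort:
            design_from_config(cfg.cohort, seed=cfg.seed or 0)  # validate early
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    return cfg


def design_from_config(cohort: dict, seed: int = 0) -> CohortDesign:
    """Build a two-arm cohort design from the ``cohort`` config section."""
    n_stem = int(cohort.get("n_stem", DEFAULT_N_STEM))
    n_centre = int(cohort.get("n_centre", DEFAULT_N_CENTRE))
    if n_centre >= n_stem:
        raise ConfigError("n_centre must be smaller than n_stem")
    rate = float(cohort.get("replacement_rate", DEFAULT_REPLACEMENT_RATE))
    layout = make_niche(n_centre, n_stem - n_centre)
    params = DriftParams(n_stem=n_stem, replacement_rate=rate)
    mode = cohort.get("inhibitor_mode", "remove_border")
    strength = float(
        cohort.get(
            "inhibitor_strength",
            1.0 if mode == "remove_border" else DEFAULT_BORDER_LOSS_RATE,
        )
    )
    arms = (
        ArmDesign(name="vehicle", params=params, layout=layout),
        ArmDesign(
            name="inhibitor",
            params=params,
            layout=layout,
            inhibition_mode=mode,
            strength=strength,
        ),
    )
    return CohortDesign(
        arms=arms,
        timepoints=tuple(float(t) for t in cohort.get("timepoints", DEFAULT_TIMEPOINTS)),
        mice_per_arm=int(cohort.get("mice_per_arm", 3)),
        crypts_per_mouse=int(cohort.get("crypts_per_mouse", 200)),
        labelling_mean=float(
            cohort.get("labelling_mean", DEFAULT_LABELLING_MEAN_LOW)
        ),
        clones_scored_min=int(cohort.get("clones_scored_min", 1)),
        induction=cohort.get("induction", "low"),
        seed=seed,
        treatment_day=float(cohort.get("treatment_day", DEFAULT_TREATMENT_DAY)),
        crypts_per_field=int(
            cohort.get("crypts_per_field", DEFAULT_CRYPTS_PER_FIELD)
        ),
    )


def apc_options(cohort: dict) -> dict:
    """Apc-specific options (bias, heterozygote bias, region mix)."""
    return {
        "bias": float(cohort.get("bias", DEFAULT_APC_BIAS)),
        "het_bias": float(cohort.get("het_bias", 0.5)),
        "region_mix": cohort.get("region_mix"),
    }
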