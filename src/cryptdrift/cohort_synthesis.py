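"""Synthetic-cohort generator for the three experiment families consumed here.

Emulated designs:

* sparse-labelling clonal time courses (tamoxifen induces a zero-truncated
  Poisson number of reporter-labelled cells per labelled crypt, treatment
  switches on 24 h after induction, crypts are scored in eighths at fixed
  timepoints, >= 200 clones per mouse);
* daily intravital imaging tracks over days 1-4 from single-cell clones with
  a recorded centre/border starting compartment;
* Apc tumour-initiation cohorts, where induced cells additionally draw a
  three-allele Cre-lox genotype, Apc-null cells drift with a replacement
  bias, and the readouts are partial/full crypt scores, reporter/genotype
  discordance and adenoma-initiation counts per mouse.

All randomness flows from a single integer seed through per-crypt
counter-based streams (numpy SeedSequence spawn keys), so datasets are
byte-identical across reruns and safe to generate in parallel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .allele_recombination import RecombinationParams, regional_params
from .clonal_readouts import CloneRecord, score_eighths, summarize_timepoint
from .drift_core import CryptTrajectory, DriftParams, simulate_crypt
from .errors import ParameterError, SchemaError
from .niche_model import CENTRE, BORDER, NicheLayout, apply_wnt_inhibition

INHIBITION_MODES = ("none", "remove_border", "border_loss")

DATASET_COLUMNS = [
    "mouse_id",
    "arm",
    "day",
    "crypt_id",
    "clone_size_cells",
    "eighths",
    "fixed",
    "surviving",
    "start_compartment",
    "n_stem",
]


@dataclass(frozen=True)
class ArmDesign:
    """One treatment arm: baseline drift parameters plus an inhibition mode."""

    name: str
    params: DriftParams
    layout: NicheLayout
    inhibition_mode: str = "none"
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.inhibition_mode not in INHIBITION_MODES:
            raise ParameterError(
                f"unknown inhibition mode {self.inhibition_mode!r}; "
                f"expected one of {INHIBITION_MODES}"
            )
        if self.layout.n_stem != self.params.n_stem:
            raise ParameterError(
                f"layout covers {self.layout.n_stem} positions but n_stem is "
                f"{self.params.n_stem}"
            )

    def treated(self) -> tuple[DriftParams, NicheLayout]:
        """Drift parameters and layout in force from the treatment switch."""
        if self.inhibition_mode == "none":
            return self.params, self.layout
        return apply_wnt_inhibition(
            self.params, self.layout, self.inhibition_mode, self.strength
        )


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: arms x timepoints x mice x crypts, plus labelling."""

    arms: tuple[ArmDesign, ...]
    timepoints: tuple[float, ...]
    mice_per_arm: int
    crypts_per_mouse: int
    labelling_mean: float
    clones_scored_min: int = 1
    induction: str = "low"
    seed: int = 0
    treatment_day: float = 1.0
    crypts_per_field: int = 50

    def __post_init__(self) -> None:
        if not self.arms:
            raise ParameterError("design needs at least one arm")
        if self.mice_per_arm < 1 or self.crypts_per_mouse < 1:
            raise ParameterError("mice_per_arm and crypts_per_mouse must be >= 1")
        tps = tuple(self.timepoints)
        if not tps or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ParameterError("timepoints must be non-empty and ascending")
        if not self.labelling_mean > 0:
            raise ParameterError(
                f"labelling_mean must be > 0, got {self.labelling_mean}"
            )
        if self.induction not in ("low", "high"):
            raise ParameterError(f"unknown induction level {self.induction!r}")
        if self.mice_per_arm * self.crypts_per_mouse < self.clones_scored_min:
            raise ParameterError(
                "crypts_per_mouse * mice_per_arm is below clones_scored_min"
            )

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ClonalDataset:
    """Tidy table of clone records plus a provenance block."""

    records: pd.DataFrame
    provenance: dict

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            for key in sorted(self.provenance):
                fh.write(f"# {key}: {self.provenance[key]}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "ClonalDataset":
        provenance = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, value = line[1:].partition(":")
                provenance[key.strip()] = value.strip()
        records = pd.read_csv(path, skiprows=skip)
        missing = [c for c in DATASET_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"dataset is missing column(s) {missing}")
        return cls(records=records, provenance=provenance)

    def summaries(
        self, crypts_per_field: int = 50, fixed_denominator: str = "surviving"
    ) -> pd.DataFrame:
        """Per (arm, day) fixation summaries as a tidy frame."""
        rows = []
        for (arm, day), grp in self.records.groupby(["arm", "day"]):
            recs = [
                CloneRecord(
                    crypt_id=int(r.crypt_id),
                    mouse_id=str(r.mouse_id),
                    arm=arm,
                    day=day,
                    clone_size_cells=int(r.clone_size_cells),
                    eighths=int(r.eighths),
                    fixed=bool(r.fixed),
                    surviving=bool(r.surviving),
                )
                for r in grp.itertuples()
            ]
            s = summarize_timepoint(recs, crypts_per_field, fixed_denominator)
            rows.append(
                {
                    "arm": arm,
                    "day": day,
                    "mean_clone_size_eighths": s.mean_clone_size_eighths,
                    "fraction_fixed": s.fraction_fixed,
                    "clones_per_field": s.clones_per_field,
                    "n_clones": s.n_clones,
                    "n_surviving": s.n_surviving,
                }
            )
        return pd.DataFrame(rows).sort_values(["arm", "day"]).reset_index(drop=True)


def _provenance(design: CohortDesign, kind: str, extra: Optional[dict] = None) -> dict:
    prov = {
        "generator": kind,
        "seed": design.seed,
        "parameter_hash": design.parameter_hash(),
        "package_version": __version__,
        "note": "synthetic cohort; adenoma counts model initiation only",
    }
    if extra:
        prov.update(extra)
    return prov


def zero_truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse CDF (stable for small means)."""
    if mean <= 0:
        raise ParameterError(f"labelling_mean must be > 0, got {mean}")
    p0 = np.exp(-mean)
    u = rng.random(size)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), mean).astype(np.int64)


@dataclass(frozen=True)
class CryptInit:
    """Initial state of one labelled crypt."""

    labels: np.ndarray
    genotypes: np.ndarray
    start_compartment: str
    region: str = ""


def _one_labelling(
    layout: NicheLayout,
    mean: float,
    rng: np.random.Generator,
    recombination: Optional[RecombinationParams] = None,
    region: str = "",
) -> CryptInit:
    n = layout.n_stem
    k = min(int(zero_truncated_poisson(rng, mean, 1)[0]), n)
    pos = rng.choice(n, size=k, replace=False)
    labels = np.zeros(n, dtype=np.int64)
    genotypes = np.zeros(n, dtype=np.int64)
    if recombination is None:
        labels[pos] = 1
    else:
        from .allele_recombination import sample_genotypes

        reporter, alleles = sample_genotypes(recombination, k, rng)
        labels[pos] = reporter.astype(np.int64)
        genotypes[pos] = alleles
    active = pos if recombination is None else pos
    start = CENTRE if (~layout.border_mask[active]).any() else BORDER
    return CryptInit(
        labels=labels, genotypes=genotypes, start_compartment=start, region=region
    )


def generate_labelling(
    design: CohortDesign,
    seed,
    n_crypts: Optional[int] = None,
    recombination: Optional[RecombinationParams] = None,
    arm: Optional[ArmDesign] = None,
) -> list[CryptInit]:
    """Draw initial states for ``n_crypts`` labelled crypts.

    Induced-cell counts are zero-truncated Poisson with mean
    ``design.labelling_mean``; cells are placed uniformly without replacement
    over the niche positions.  With ``recombination`` given, each induced
    cell draws a three-allele genotype and only reporter-positive cells are
    labelled.
    """
    arm = arm if arm is not None else design.arms[0]
    n_crypts = n_crypts if n_crypts is not None else design.crypts_per_mouse
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        _one_labelling(arm.layout, design.labelling_mean, rng, recombination)
        for _ in range(n_crypts)
    ]


def _simulate_to_days(
    arm: ArmDesign,
    init: CryptInit,
    days: Sequence[float],
    treatment_day: float,
    rng: np.random.Generator,
    bias: Optional[float] = None,
    het_bias: float = 0.5,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Simulate one crypt, switching to the treated regime at treatment_day.

    Returns (day, labels, genotypes) snapshots for every requested day; the
    snapshot ring may be shorter after a remove_border switch.
    """
    days = sorted(days)
    base_params = arm.params if bias is None else replace(arm.params, bias=bias)
    pre_days = [d for d in days if d <= treatment_day]
    post_days = [d for d in days if d > treatment_day]
    out: list[tuple[float, np.ndarray, np.ndarray]] = []

    grid_a = sorted(set(pre_days + [treatment_day]))
    traj = simulate_crypt(
        base_params,
        init.labels,
        grid_a,
        rng,
        init_genotypes=init.genotypes,
        het_bias=het_bias,
    )
    for d in pre_days:
        i = int(np.searchsorted(traj.times, d))
        out.append((d, traj.labels[i].copy(), traj.genotypes[i].copy()))
    labels = traj.labels[-1].copy()
    genotypes = traj.genotypes[-1].copy()

    if post_days:
        t_params, t_layout = arm.treated()
        if bias is not None:
            t_params = replace(t_params, bias=bias)
        keep = t_layout.n_stem
        labels, genotypes = labels[:keep], genotypes[:keep]
        grid_b = [d - treatment_day for d in post_days]
        traj_b = simulate_crypt(
            t_params,
            labels,
            grid_b,
            rng,
            init_genotypes=genotypes,
            border_mask=t_layout.border_mask if t_params.border_loss_rate > 0 else None,
            het_bias=het_bias,
        )
        for d in post_days:
            i = int(np.searchsorted(traj_b.times, d - treatment_day))
            out.append((d, traj_b.labels[i].copy(), traj_b.genotypes[i].copy()))
    return out


def run_neutral_cohort(
    design: CohortDesign, longitudinal: bool = False
) -> ClonalDataset:
    """Simulate the sparse-labelling fixation experiment.

    Cross-sectional by default (fresh mice and crypts per timepoint, as in
    fixed-tissue scoring); ``longitudinal=True`` scores the same crypts at
    every timepoint, which is cheaper for dense day grids where only mean
    curves are needed.
    """
    rows = []
    for ai, arm in enumerate(design.arms):
        tp_groups = [list(design.timepoints)] if longitudinal else [
            [tp] for tp in design.timepoints
        ]
        for ti, tps in enumerate(tp_groups):
            for m in range(design.mice_per_arm):
                mouse_id = f"{arm.name}_t{ti}_m{m}"
                for c in range(design.crypts_per_mouse):
                    rng = np.random.default_rng((design.seed, ai, ti, m, c))
                    init = _one_labelling(arm.layout, design.labelling_mean, rng)
                    snaps = _simulate_to_days(
                        arm, init, tps, design.treatment_day, rng
                    )
                    for day, labels, _ in snaps:
                        size = int((labels == 1).sum())
                        rows.append(
                            {
                                "mouse_id": mouse_id,
                                "arm": arm.name,
                                "day": day,
                                "crypt_id": c,
                                "clone_size_cells": size,
                                "eighths": score_eighths(size, len(labels)),
                                "fixed": size == len(labels),
                                "surviving": size >= 1,
                                "start_compartment": init.start_compartment,
                                "n_stem": len(labels),
                            }
                        )
    records = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    extra = {"labelling_mean": design.labelling_mean, "longitudinal": longitudinal}
    return ClonalDataset(records, _provenance(design, "neutral_cohort", extra))


def run_imaging_cohort(
    design: CohortDesign, seed: Optional[int] = None
) -> dict[str, list[CryptTrajectory]]:
    """Daily intravital tracks, days 1-4, from single-cell clones.

    Every crypt starts with exactly one labelled cell at induction (day 0);
    treatment switches at ``design.treatment_day``.  remove_border arms are
    not imageable here (the ring must keep its length); use border_loss.
    """
    seed = design.seed if seed is None else seed
    out: dict[str, list[CryptTrajectory]] = {}
    days = [float(d) for d in design.timepoints]
    for ai, arm in enumerate(design.arms):
        if arm.inhibition_mode == "remove_border":
            raise ParameterError(
                "imaging cohorts require mode 'none' or 'border_loss' so the "
                "ring keeps a constant length"
            )
        t_params, t_layout = arm.treated()
        trajs = []
        n_crypts = design.crypts_per_mouse * design.mice_per_arm
        for c in range(n_crypts):
            rng = np.random.default_rng((seed, ai, c))
            pos = int(rng.integers(arm.layout.n_stem))
            labels = np.zeros(arm.layout.n_stem, dtype=np.int64)
            labels[pos] = 1
            pre = simulate_crypt(
                arm.params, labels, [0.0, design.treatment_day], rng
            )
            post = simulate_crypt(
                t_params,
                pre.labels[-1],
                [d - design.treatment_day for d in days if d >= design.treatment_day],
                rng,
                border_mask=t_layout.border_mask,
            )
            times = np.concatenate(([0.0], post.times + design.treatment_day))
            lab = np.vstack([pre.labels[:1], post.labels])
            gen = np.vstack([pre.genotypes[:1], post.genotypes])
            trajs.append(
                CryptTrajectory(
                    times=times,
                    labels=lab,
                    genotypes=gen,
                    events=pre.events + post.events,
                    absorbed_time=post.absorbed_time,
                    border_mask=arm.layout.border_mask,
                )
            )
        out[arm.name] = trajs
    return out


APC_COLUMNS = DATASET_COLUMNS + ["region", "n_null", "genotype_category"]


def run_apc_cohort(
    design: CohortDesign,
    bias: float,
    recombination: Optional[dict[str, RecombinationParams]] = None,
    region_mix: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
    het_bias: float = 0.5,
) -> tuple[ClonalDataset, pd.DataFrame]:
    """Apc tumour-initiation cohort with genotype-dependent biased drift.

    Returns the scored dataset (longitudinal snapshots at every design
    timepoint) and per-mouse adenoma-initiation counts: the number of crypts
    fully fixed for the Apc-null clone by the final timepoint.  Heterozygous
    cells compete with ``het_bias`` (neutral by default).
    """
    if bias < 0.5:
        raise ParameterError(f"Apc-null bias must be >= 0.5, got {bias}")
    seed = design.seed if seed is None else seed
    if region_mix is None:
        region_mix = {"proximal": 0.5, "distal": 0.5}
    if abs(sum(region_mix.values()) - 1.0) > 1e-9:
        raise ParameterError("region_mix fractions must sum to 1")
    regions = sorted(region_mix)
    cum = np.cumsum([region_mix[r] for r in regions])
    rec = {
        r: (recombination[r] if recombination else regional_params(r))
        for r in regions
    }
    rows = []
    adenoma_rows = []
    final_day = design.timepoints[-1]
    for ai, arm in enumerate(design.arms):
        for m in range(design.mice_per_arm):
            mouse_id = f"{arm.name}_m{m}"
            n_adenoma = 0
            for c in range(design.crypts_per_mouse):
                rng = np.random.default_rng((seed, ai, m, c))
                region = regions[int(np.searchsorted(cum, rng.random(), side="right"))]
                init = _one_labelling(
                    arm.layout, design.labelling_mean, rng, rec[region], region
                )
                snaps = _simulate_to_days(
                    arm,
                    init,
                    list(design.timepoints),
                    design.treatment_day,
                    rng,
                    bias=bias,
                    het_bias=het_bias,
                )
                for day, labels, genotypes in snaps:
                    n = len(labels)
                    size = int((labels == 1).sum())
                    n_null = int((genotypes == 2).sum())
                    category = (
                        "none" if n_null == 0 else "full" if n_null == n else "partial"
                    )
                    rows.append(
                        {
                            "mouse_id": mouse_id,
                            "arm": arm.name,
                            "day": day,
                            "crypt_id": c,
                            "clone_size_cells": size,
                            "eighths": score_eighths(size, n),
                            "fixed": size == n,
                            "surviving": size >= 1,
                            "start_compartment": init.start_compartment,
                            "n_stem": n,
                            "region": region,
                            "n_null": n_null,
                            "genotype_category": category,
                        }
                    )
                    if day == final_day and category == "full":
                        n_adenoma += 1
            adenoma_rows.append(
                {"mouse_id": mouse_id, "arm": arm.name, "count": n_adenoma}
            )
    records = pd.DataFrame(rows, columns=APC_COLUMNS)
    extra = {"bias": bias, "region_mix": json.dumps(region_mix, sort_keys=True)}
    dataset = ClonalDataset(records, _provenance(design, "apc_cohort", extra))
    return dataset, pd.DataFrame(adenoma_rows)


def discordance_table(dataset: ClonalDataset, day: float) -> pd.DataFrame:
    """Crypt-weighted reporter/genotype discordance among tdTom+ crypts.

    For each region, among crypts with >= 1 reporter-labelled cell at ``day``:
    fraction with zero Apc-null niche cells (crypt still expresses Apc
    everywhere), with a minority of null cells, and with null cells in the
    majority (>= 50% of positions).
    """
    df = dataset.records
    if "region" not in df.columns:
        raise SchemaError("dataset carries no region column (not an Apc cohort)")
    at_day = df[(df["day"] == day) & df["surviving"]]
    if at_day.empty:
        raise ParameterError(f"no surviving tdTom+ crypts at day {day}")
    rows = []
    for region, grp in at_day.groupby("region"):
        frac_null = grp["n_null"] / grp["n_stem"]
        rows.append(
            {
                "region": region,
                "day": day,
                "n_tdtom_crypts": len(grp),
                "frac_apc_intact": float((grp["n_null"] == 0).mean()),
                "frac_minority_loss": float(
                    ((grp["n_null"] > 0) & (frac_null < 0.5)).mean()
                ),
                "frac_majority_loss": float((frac_null >= 0.5).mean()),
            }
        )
    return pd.DataFrame(rows)
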