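"""Scoring layer: eighths clone sizes, fixation summaries, genotype scoring.

Clone size is scored in "eighths" — the fraction of the crypt circumference
occupied by the labelled clone, discretised to 0..8 with 8 meaning the crypt
is fully fixed (monoclonal for the label).  A surviving non-fixed clone always
scores 1..7: the bin is ``round(8 * size / N)`` clamped to [1, 7], with 0 and
8 reserved for lost and fixed clones respectively.  Crypt genotype scoring
(none/partial/full) mirrors nuclear-beta-catenin immunohistochemistry read on
Apc-mutant clones: "full" means every competing position carries the
Apc-null genotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .drift_core import GENOTYPE_NULL
from .errors import ParameterError

GENOTYPE_CATEGORIES = ("none", "partial", "full")


@dataclass(frozen=True)
class CloneRecord:
    """One scored clonal observation (one crypt at one timepoint)."""

    crypt_id: int
    mouse_id: str
    arm: str
    day: float
    clone_size_cells: int
    eighths: int
    fixed: bool
    surviving: bool
    start_compartment: str = ""

    @classmethod
    def from_size(
        cls,
        crypt_id: int,
        mouse_id: str,
        arm: str,
        day: float,
        clone_size_cells: int,
        n_stem: int,
        start_compartment: str = "",
    ) -> "CloneRecord":
        e = score_eighths(clone_size_cells, n_stem)
        return cls(
            crypt_id=crypt_id,
            mouse_id=mouse_id,
            arm=arm,
            day=day,
            clone_size_cells=clone_size_cells,
            eighths=e,
            fixed=e == 8,
            surviving=clone_size_cells >= 1,
            start_compartment=start_compartment,
        )


@dataclass(frozen=True)
class FixationSummary:
    """Per-timepoint summary of a clonal cohort arm."""

    day: float
    mean_clone_size_eighths: float
    fraction_fixed: float
    clones_per_field: float
    n_clones: int
    n_surviving: int


@dataclass(frozen=True)
class CryptGenotypeScore:
    """Crypt category for the Apc-null (nuclear-beta-catenin) clone."""

    crypt_id: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in GENOTYPE_CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}")


def score_eighths(clone_size_cells: int, n_stem: int) -> int:
    """Discretise a clone size into the 0..8 eighths scale."""
    if clone_size_cells < 0 or clone_size_cells > n_stem:
        raise ParameterError(
            f"clone size must lie in [0, {n_stem}], got {clone_size_cells}"
        )
    if clone_size_cells == 0:
        return 0
    if clone_size_cells == n_stem:
        return 8
    raw = int(np.floor(8.0 * clone_size_cells / n_stem + 0.5))
    return min(7, max(1, raw))


def eighths_size_sets(n_stem: int) -> dict[int, list[int]]:
    """Exact mapping bin -> clone sizes, inverse of :func:`score_eighths`."""
    out: dict[int, list[int]] = {b: [] for b in range(9)}
    for size in range(n_stem + 1):
        out[score_eighths(size, n_stem)].append(size)
    return out


def summarize_timepoint(
    records: Sequence[CloneRecord],
    crypts_per_field: int = 50,
    fixed_denominator: str = "surviving",
) -> FixationSummary:
    """Summarise all records of one (arm, day) cell.

    ``fraction_fixed`` is computed among surviving clones by default (the
    documented convention; clone loss is accounted separately by
    ``clones_per_field``).  Pass ``fixed_denominator='induced'`` to divide by
    all induced clones instead.  ``clones_per_field`` is the number of
    surviving clones normalised per field of ``crypts_per_field`` crypts.
    """
    records = list(records)
    if not records:
        raise ParameterError("summarize_timepoint requires at least one record")
    if crypts_per_field <= 0:
        raise ParameterError(f"crypts_per_field must be > 0, got {crypts_per_field}")
    days = {r.day for r in records}
    if len(days) != 1:
        raise ParameterError(f"records span multiple days: {sorted(days)}")
    if fixed_denominator not in ("surviving", "induced"):
        raise ParameterError(f"unknown denominator {fixed_denominator!r}")
    survivors = [r for r in records if r.surviving]
    n_fixed = sum(r.fixed for r in records)
    denom = len(survivors) if fixed_denominator == "surviving" else len(records)
    mean_eighths = (
        float(np.mean([r.eighths for r in survivors])) if survivors else float("nan")
    )
    return FixationSummary(
        day=records[0].day,
        mean_clone_size_eighths=mean_eighths,
        fraction_fixed=n_fixed / denom if denom else float("nan"),
        clones_per_field=crypts_per_field * len(survivors) / len(records),
        n_clones=len(records),
        n_surviving=len(survivors),
    )


def score_crypt_genotype(
    genotype_snapshot: Sequence[int], crypt_id: int = 0
) -> CryptGenotypeScore:
    """Categorise a crypt by its Apc-null content: none / partial / full."""
    snap = np.asarray(genotype_snapshot)
    if snap.size == 0:
        raise ParameterError("genotype snapshot is empty")
    if not np.isin(snap, [0, 1, 2]).all():
        bad = sorted(set(snap.tolist()) - {0, 1, 2})
        raise ParameterError(f"unknown genotype code(s) {bad}")
    n_null = int((snap == GENOTYPE_NULL).sum())
    if n_null == 0:
        category = "none"
    elif n_null == snap.size:
        category = "full"
    else:
        category = "partial"
    return CryptGenotypeScore(crypt_id=crypt_id, category=category)


def full_crypt_ratio(scores: Iterable[CryptGenotypeScore]) -> float:
    """#full / (#full + #partial); crypts scoring 'none' are excluded."""
    counts = Counter(s.category for s in scores)
    denom = counts["full"] + counts["partial"]
    if denom == 0:
        raise ParameterError("no recombined crypts: denominator is zero")
    return counts["full"] / denom
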