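"""Centre/border structure of the crypt niche and Wnt-inhibition mapping.

In vivo, stem cells at the upper edge of the niche ("border") are
preferentially lost when Wnt-ligand secretion is reduced, while cells at the
crypt base ("centre") keep competing normally.  This module lays the two
compartments out on the model ring and maps a Porcupine-inhibitor treatment
onto either an instantaneous shrinkage of the competing pool
(``remove_border``) or a stochastic per-cell expulsion rate (``border_loss``).
It also computes the intravital-imaging readout: the fraction of clones that
still have at least one cell anywhere in the niche on each imaging day
(cells pushed into the transit-amplifying zone are not counted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .drift_core import CryptTrajectory, DriftParams
from .errors import ParameterError

CENTRE = "centre"
BORDER = "border"


@dataclass(frozen=True)
class NicheLayout:
    """Compartment assignment of the ring positions.

    Convention: positions ``0 .. n_centre-1`` are centre (crypt base);
    positions ``n_centre .. n_stem-1`` form the contiguous border arc adjacent
    to the transit-amplifying exit.
    """

    n_centre: int
    n_border: int

    def __post_init__(self) -> None:
        if self.n_centre < 1:
            raise ParameterError(f"n_centre must be >= 1, got {self.n_centre}")
        if self.n_border < 0:
            raise ParameterError(f"n_border must be >= 0, got {self.n_border}")

    @property
    def n_stem(self) -> int:
        return self.n_centre + self.n_border

    @property
    def assignment(self) -> np.ndarray:
        """Per-position compartment labels."""
        return np.array([CENTRE] * self.n_centre + [BORDER] * self.n_border)

    @property
    def border_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_stem, dtype=bool)
        mask[self.n_centre :] = True
        return mask

    def compartment_of(self, position: int) -> str:
        return CENTRE if position < self.n_centre else BORDER


@dataclass(frozen=True)
class PersistenceCurve:
    """Per-day fraction of imaged clones with >= 1 cell still in the niche.

    Day-one value is 1 by conditioning (only clones present at the first
    imaging day are followed); the curve is non-increasing because a clone
    that has lost its last niche cell cannot regain one.
    """

    days: np.ndarray
    fraction_surviving: np.ndarray
    start_compartment: str
    n_clones: int

    def to_dataframe(self, arm: str = ""):
        import pandas as pd

        return pd.DataFrame(
            {
                "arm": arm,
                "start_compartment": self.start_compartment,
                "day": self.days,
                "n_clones": self.n_clones,
                "fraction_surviving": self.fraction_surviving,
            }
        )


def make_niche(n_centre: int, n_border: int) -> NicheLayout:
    """Deterministic centre/border assignment (see :class:`NicheLayout`)."""
    return NicheLayout(n_centre=n_centre, n_border=n_border)


def apply_wnt_inhibition(
    params: DriftParams,
    layout: NicheLayout,
    mode: str,
    strength: float,
) -> tuple[DriftParams, NicheLayout]:
    """Map Wnt-ligand inhibition onto the drift model.

    ``remove_border`` converts ``round(strength * n_border)`` border positions
    to non-competing, shrinking the effective pool; ``border_loss`` sets the
    stochastic expulsion rate of border cells to ``strength`` per cell per
    day.  Centre replacement kinetics are unchanged in both modes.
    """
    if strength < 0:
        raise ParameterError(f"strength must be >= 0, got {strength}")
    if mode == "remove_border":
        k = int(round(strength * layout.n_border))
        if k == 0:
            return params, layout
        new_layout = NicheLayout(layout.n_centre, layout.n_border - k)
        new_params = replace(params, n_stem=params.n_stem - k)
        return new_params, new_layout
    if mode == "border_loss":
        return replace(params, border_loss_rate=float(strength)), layout
    raise ParameterError(
        f"unknown inhibition mode {mode!r}; expected 'remove_border' or 'border_loss'"
    )


def persistence_curve(
    trajectories: Sequence[CryptTrajectory],
    start_compartment: str,
    label: int = 1,
) -> PersistenceCurve:
    """Imaging readout: surviving-clone fraction per day, by starting position.

    Each trajectory must begin (first sampled time, the induction snapshot)
    with exactly one cell carrying ``label``, located in ``start_compartment``.
    Days are the remaining sampled times; clones already lost on the first
    imaging day are excluded (they would never have been followed), which
    makes the day-one value 1 by conditioning.
    """
    if start_compartment not in (CENTRE, BORDER):
        raise ParameterError(f"unknown compartment {start_compartment!r}")
    trajectories = list(trajectories)
    if not trajectories:
        raise ParameterError("persistence_curve requires at least one trajectory")
    days = None
    alive = []
    for k, traj in enumerate(trajectories):
        if traj.border_mask is None:
            raise ParameterError(f"trajectory {k} carries no niche layout")
        init = traj.labels[0]
        pos = np.flatnonzero(init == label)
        if len(pos) != 1:
            raise ParameterError(
                f"trajectory {k} does not start with exactly one labelled cell"
            )
        comp = BORDER if traj.border_mask[pos[0]] else CENTRE
        if comp != start_compartment:
            raise ParameterError(
                f"trajectory {k} starts in {comp!r}, expected {start_compartment!r}"
            )
        if days is None:
            days = traj.times[1:]
        elif not np.array_equal(traj.times[1:], days):
            raise ParameterError(f"trajectory {k} was sampled on a different day grid")
        alive.append((traj.labels[1:] == label).any(axis=1))
    if days is None or len(days) == 0:
        raise ParameterError("trajectories contain no imaging days after induction")
    alive_arr = np.stack(alive)  # (clones, days)
    followed = alive_arr[:, 0]
    if not followed.any():
        raise ParameterError("no clone survives to the first imaging day")
    frac = alive_arr[followed].mean(axis=0)
    return PersistenceCurve(
        days=np.asarray(days, dtype=float),
        fraction_surviving=frac,
        start_compartment=start_compartment,
        n_clones=int(followed.sum()),
    )


def export_persistence(
    curves: Iterable[tuple[str, PersistenceCurve]], path
) -> None:
    """Write (arm, curve) pairs as a tidy CSV."""
    import pandas as pd

    pd.concat([c.to_dataframe(arm) for arm, c in curves], ignore_index=True).to_csv(
        path, index=False
    )
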