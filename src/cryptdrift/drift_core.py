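"""One-dimensional ring Moran model of intestinal stem-cell replacement.

The crypt stem-cell niche is modelled as a ring of ``N`` equipotent positions.
Replacement events occur at total rate ``N * replacement_rate`` per crypt: a
uniformly chosen cell divides and its progeny displaces one of its two ring
neighbours (uniform side).  Equivalently, every undirected ring edge "resolves"
at rate ``replacement_rate``, the winner being uniform for equal genotypes and
decided by ``bias`` at a mutant/wild-type boundary.  Under this convention a
contiguous single clone of size ``0 < n < N`` performs a continuous-time
birth–death walk with total stepping rate ``2 * replacement_rate`` (two
boundaries), up-step probability ``bias`` — the exact chain built by
:func:`build_clonal_chain` and used as the simulator's oracle.

Genotype codes: 0 = wild type, 1 = Apc heterozygous, 2 = Apc null.  Clone
labels are arbitrary non-negative integers; label 0 conventionally means
"unlabelled" in the cohort layer but the core treats all labels symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ParameterError

GENOTYPE_WT = 0
GENOTYPE_HET = 1
GENOTYPE_NULL = 2

_CHUNK = 64  # random numbers pre-drawn per refill in the event loop


@dataclass(frozen=True)
class DriftParams:
    """The drift model's named parameters.

    Parameters
    ----------
    n_stem:
        Number of competing stem-cell positions N (ring length).
    replacement_rate:
        Expected replacement events per stem cell per day (lambda).
    bias:
        Probability that, at a mutant/wild-type boundary resolution, the
        mutant displaces the wild-type cell.  0.5 is neutral drift.
    border_loss_rate:
        Expected expulsions per border position per day under Wnt-ligand
        inhibition; 0 for the untreated niche.
    """

    n_stem: int
    replacement_rate: float
    bias: float = 0.5
    border_loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if int(self.n_stem) != self.n_stem or self.n_stem < 2:
            raise ParameterError(f"n_stem must be an integer >= 2, got {self.n_stem}")
        if not self.replacement_rate > 0:
            raise ParameterError(
                f"replacement_rate must be > 0, got {self.replacement_rate}"
            )
        if not 0.0 <= self.bias <= 1.0:
            raise ParameterError(f"bias must lie in [0, 1], got {self.bias}")
        if self.border_loss_rate < 0:
            raise ParameterError(
                f"border_loss_rate must be >= 0, got {self.border_loss_rate}"
            )


@dataclass(frozen=True)
class ClonalChain:
    """Continuous-time birth–death chain for one contiguous clone on the ring.

    States are clone sizes 0..N; 0 and N are absorbing.  For interior states
    the total stepping rate is constant (a contiguous clone always has exactly
    two boundaries): ``rate_up = 2*lambda*bias``, ``rate_down =
    2*lambda*(1-bias)``.
    """

    n_stem: int
    rate_up: float
    rate_down: float

    @property
    def absorbing_states(self) -> tuple[int, int]:
        return (0, self.n_stem)

    def generator(self) -> np.ndarray:
        """Return the (N+1) x (N+1) infinitesimal generator Q."""
        n = self.n_stem
        q = np.zeros((n + 1, n + 1))
        for i in range(1, n):
            q[i, i + 1] = self.rate_up
            q[i, i - 1] = self.rate_down
            q[i, i] = -(self.rate_up + self.rate_down)
        return q

    def jump_matrix(self) -> np.ndarray:
        """Embedded jump chain; absorbing states map to themselves."""
        n = self.n_stem
        total = self.rate_up + self.rate_down
        p = np.zeros((n + 1, n + 1))
        p[0, 0] = 1.0
        p[n, n] = 1.0
        for i in range(1, n):
            p[i, i + 1] = self.rate_up / total
            p[i, i - 1] = self.rate_down / total
        return p


@dataclass
class CryptTrajectory:
    """Time-resolved per-position clone labels and genotypes of one crypt.

    ``labels`` and ``genotypes`` have shape (len(times), ring length).  The
    ring length is constant within a trajectory; no label is ever created
    after time zero.  ``absorbed_time`` is the time the crypt became fully
    homogeneous (monoclonal and genotype-uniform), if observed.
    """

    times: np.ndarray
    labels: np.ndarray
    genotypes: np.ndarray
    events: int
    absorbed_time: Optional[float] = None
    border_mask: Optional[np.ndarray] = None

    @property
    def n_stem(self) -> int:
        return self.labels.shape[1]

    def clone_size(self, label: int) -> np.ndarray:
        """Number of positions carrying ``label`` at each sampled time."""
        return (self.labels == label).sum(axis=1)

    def to_dataframe(self, crypt_id: int = 0):
        """Tidy export: one row per (day, position)."""
        import pandas as pd

        t_rep = np.repeat(self.times, self.n_stem)
        pos = np.tile(np.arange(self.n_stem), len(self.times))
        return pd.DataFrame(
            {
                "crypt_id": crypt_id,
                "day": t_rep,
                "position": pos,
                "clone_label": self.labels.ravel(),
                "genotype": self.genotypes.ravel(),
            }
        )


def build_clonal_chain(params: DriftParams) -> ClonalChain:
    """Exact single-contiguous-clone birth–death chain for ``params``.

    The boundary-resolution convention: every undirected ring edge resolves at
    rate ``replacement_rate``; the mutant side wins with probability ``bias``.
    """
    lam = params.replacement_rate
    return ClonalChain(
        n_stem=params.n_stem,
        rate_up=2.0 * lam * params.bias,
        rate_down=2.0 * lam * (1.0 - params.bias),
    )


def clone_size_distribution(chain: ClonalChain, n0: int, t: float) -> np.ndarray:
    """Exact clone-size distribution at time ``t`` days, starting from ``n0``.

    Returns a probability vector over sizes 0..N (sums to 1 within 1e-10).
    """
    n = chain.n_stem
    if not 0 <= n0 <= n:
        raise ParameterError(f"n0 must lie in [0, {n}], got {n0}")
    if t < 0:
        raise ParameterError(f"t must be >= 0, got {t}")
    p0 = np.zeros(n + 1)
    p0[n0] = 1.0
    if t == 0:
        return p0
    return p0 @ expm(chain.generator() * t)


class ChainPropagator:
    """Cached spectral propagator for a :class:`ClonalChain`.

    Diagonalises the generator once so distributions at many (t, lambda)
    combinations are cheap; used by the inference layer.  Agreement with the
    matrix exponential is covered by tests.
    """

    def __init__(self, chain: ClonalChain):
        self.chain = chain
        q = chain.generator()
        w, v = np.linalg.eig(q)
        self._w = w
        self._v = v
        self._vinv = np.linalg.inv(v)

    def distribution(self, p0: np.ndarray, t: float) -> np.ndarray:
        out = (p0 @ self._v) * np.exp(self._w * t) @ self._vinv
        out = np.real(out)
        np.clip(out, 0.0, 1.0, out=out)
        return out / out.sum()


def fixation_probability(n_stem: int, n0: int, bias: float = 0.5) -> float:
    """Probability a clone of ``n0`` of ``n_stem`` cells ultimately fixes.

    Neutral: n0/N.  Biased: gambler's-ruin form (1-rho^n0)/(1-rho^N) with
    rho = (1-bias)/bias; the limits bias -> 0, 0.5, 1 are handled so the
    function is continuous in bias.
    """
    if n_stem < 2:
        raise ParameterError(f"n_stem must be >= 2, got {n_stem}")
    if not 0 <= n0 <= n_stem:
        raise ParameterError(f"n0 must lie in [0, {n_stem}], got {n0}")
    if not 0.0 <= bias <= 1.0:
        raise ParameterError(f"bias must lie in [0, 1], got {bias}")
    if n0 == 0:
        return 0.0
    if n0 == n_stem:
        return 1.0
    if bias == 0.0:
        return 0.0
    if bias == 1.0:
        return 1.0
    rho = (1.0 - bias) / bias
    if abs(rho - 1.0) < 1e-9:
        return n0 / n_stem
    return float(np.expm1(n0 * np.log(rho)) / np.expm1(n_stem * np.log(rho)))


def win_probability_matrix(bias: float, het_bias: float = 0.5) -> np.ndarray:
    """P(left cell wins | edge resolution) indexed by (genotype_i, genotype_j).

    Equal genotypes resolve uniformly (equivalent to "the divider wins" with a
    uniformly chosen divider).  Apc-null vs non-null resolves with ``bias`` in
    favour of the null cell; heterozygous vs wild type with ``het_bias``
    (neutral by default).
    """
    w = np.full((3, 3), 0.5)
    w[GENOTYPE_NULL, GENOTYPE_WT] = bias
    w[GENOTYPE_NULL, GENOTYPE_HET] = bias
    w[GENOTYPE_WT, GENOTYPE_NULL] = 1.0 - bias
    w[GENOTYPE_HET, GENOTYPE_NULL] = 1.0 - bias
    w[GENOTYPE_HET, GENOTYPE_WT] = het_bias
    w[GENOTYPE_WT, GENOTYPE_HET] = 1.0 - het_bias
    return w


class _RandomBlock:
    """Chunked draws from a Generator; keeps the event loop off scalar calls."""

    __slots__ = ("rng", "exp", "uni", "i")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._refill()

    def _refill(self) -> None:
        self.exp = self.rng.exponential(size=_CHUNK)
        self.uni = self.rng.random(size=(_CHUNK, 3))
        self.i = 0

    def draw(self):
        if self.i == _CHUNK:
            self._refill()
        e = self.exp[self.i]
        u = self.uni[self.i]
        self.i += 1
        return e, u


def _advance(
    labels: np.ndarray,
    genotypes: np.ndarray,
    diff: np.ndarray,
    win: np.ndarray,
    lam: float,
    mu: float,
    border_idx: np.ndarray,
    t0: float,
    t1: float,
    sample_times: Sequence[float],
    snapshots: list,
    blk: _RandomBlock,
) -> tuple[float, int, Optional[float]]:
    """Advance the ring from t0 to t1, recording snapshots at sample_times.

    Mutates ``labels``/``genotypes``/``diff`` in place.  Returns
    (time reached, events applied, absorption time or None).  ``diff[i]``
    flags heterogeneity of edge (i, i+1 mod N).  Absorption = full state
    homogeneity, after which nothing can change (border refills are no-ops).
    """
    n = labels.shape[0]
    n_border = len(border_idx)
    t = t0
    si = 0
    events = 0
    absorbed: Optional[float] = None
    while si < len(sample_times) and sample_times[si] < t0:
        si += 1

    while True:
        n_edges = int(np.count_nonzero(diff))
        if n_edges == 0:
            if absorbed is None:
                absorbed = t
            break
        rate = lam * n_edges + mu * n_border
        e, u = blk.draw()
        t_next = t + e / rate
        while si < len(sample_times) and sample_times[si] <= min(t_next, t1):
            snapshots.append((sample_times[si], labels.copy(), genotypes.copy()))
            si += 1
        if t_next >= t1:
            t = t1
            return t, events, absorbed
        t = t_next
        events += 1
        if mu > 0.0 and u[0] * rate >= lam * n_edges:
            # border expulsion: the border lineage leaves the niche and the
            # position is refilled by a uniform ring neighbour's progeny
            pos = int(border_idx[int(u[1] * n_border)])
            nb = (pos + 1) % n if u[2] < 0.5 else (pos - 1) % n
            labels[pos] = labels[nb]
            genotypes[pos] = genotypes[nb]
            _update_diff(labels, genotypes, diff, pos)
        else:
            edges = np.flatnonzero(diff)
            i = int(edges[int(u[1] * n_edges)])
            j = (i + 1) % n
            p_left = win[genotypes[i], genotypes[j]]
            winner, loser = (i, j) if u[2] < p_left else (j, i)
            labels[loser] = labels[winner]
            genotypes[loser] = genotypes[winner]
            _update_diff(labels, genotypes, diff, loser)

    # absorbed: state frozen for the rest of the interval
    while si < len(sample_times) and sample_times[si] <= t1:
        snapshots.append((sample_times[si], labels.copy(), genotypes.copy()))
        si += 1
    return t1, events, absorbed


def _update_diff(
    labels: np.ndarray, genotypes: np.ndarray, diff: np.ndarray, pos: int
) -> None:
    n = labels.shape[0]
    prev = (pos - 1) % n
    nxt = (pos + 1) % n
    diff[prev] = labels[prev] != labels[pos] or genotypes[prev] != genotypes[pos]
    diff[pos] = labels[pos] != labels[nxt] or genotypes[pos] != genotypes[nxt]


def _make_diff(labels: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    rolled_l = np.roll(labels, -1)
    rolled_g = np.roll(genotypes, -1)
    return (labels != rolled_l) | (genotypes != rolled_g)


def simulate_crypt(
    params: DriftParams,
    init_labels: Sequence[int],
    t_grid: Sequence[float],
    seed,
    init_genotypes: Optional[Sequence[int]] = None,
    border_mask: Optional[np.ndarray] = None,
    het_bias: float = 0.5,
) -> CryptTrajectory:
    """Event-driven (Gillespie) simulation of one crypt, sampled at ``t_grid``.

    ``seed`` may be an integer, a seed sequence, or a Generator; identical
    seed and inputs give a bit-identical trajectory.  ``border_mask`` marks
    positions subject to ``params.border_loss_rate`` expulsions.
    """
    labels = np.asarray(init_labels, dtype=np.int64).copy()
    if labels.shape != (params.n_stem,):
        raise ParameterError(
            f"init_labels must have length n_stem={params.n_stem}, "
            f"got {labels.shape}"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ParameterError("t_grid must not be empty")
    if np.any(np.diff(t_grid) < 0) or t_grid[0] < 0:
        raise ParameterError("t_grid must be sorted ascending and non-negative")
    if init_genotypes is None:
        genotypes = np.zeros(params.n_stem, dtype=np.int64)
    else:
        genotypes = np.asarray(init_genotypes, dtype=np.int64).copy()
        if genotypes.shape != (params.n_stem,):
            raise ParameterError("init_genotypes must have length n_stem")
    mu = params.border_loss_rate
    if mu > 0 and border_mask is None:
        raise ParameterError("border_loss_rate > 0 requires a border_mask")
    border_idx = (
        np.flatnonzero(np.asarray(border_mask))
        if border_mask is not None
        else np.empty(0, dtype=np.int64)
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blk = _RandomBlock(rng)
    diff = _make_diff(labels, genotypes)
    win = win_probability_matrix(params.bias, het_bias)

    snapshots: list = []
    if t_grid[0] == 0.0:
        snapshots.append((0.0, labels.copy(), genotypes.copy()))
        sample = t_grid[1:]
    else:
        sample = t_grid
    _, events, absorbed = _advance(
        labels,
        genotypes,
        diff,
        win,
        params.replacement_rate,
        mu,
        border_idx,
        0.0,
        float(t_grid[-1]) if t_grid[-1] > 0 else 0.0,
        list(sample),
        snapshots,
        blk,
    )
    times = np.array([s[0] for s in snapshots])
    lab_hist = np.stack([s[1] for s in snapshots])
    gen_hist = np.stack([s[2] for s in snapshots])
    mask = (
        np.asarray(border_mask, dtype=bool).copy() if border_mask is not None else None
    )
    return CryptTrajectory(
        times=times,
        labels=lab_hist,
        genotypes=gen_hist,
        events=events,
        absorbed_time=absorbed,
        border_mask=mask,
    )
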