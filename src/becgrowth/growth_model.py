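"""Stochastic two-state growth model of biliary epithelial cell (BEC) clones.

Chronic liver injury triggers the ductular reaction, in which the intrahepatic
biliary tree expands by proliferation of the pre-existing biliary epithelium.
Clonal lineage tracing of single BECs shows unimodal, long-tailed colony-size
distributions: most labeled cells stay small while a minority found large
clones. This module implements the discrete-time stochastic model that
reproduces that heterogeneity.

Model
-----
A clone starts from one founder cell, proliferative (P) with probability ``p``
or quiescent (Q) otherwise. Each simulated day:

1. every P cell independently enters the cell cycle with probability ``m``
   (Bernoulli trial; inter-mitotic times are therefore geometric with mean
   ``1/m`` days);
2. each division replaces the mother with two daughters whose joint state is
   one of three fates — PP, PQ or QQ — with probabilities ``r + s``,
   ``1 - 2r`` and ``r - s`` respectively (``r`` controls size stability,
   ``s`` the expansion imbalance; ``s = 0`` recovers the balanced
   critical-process limit used for homeostatic epithelia);
3. every cell, newborn daughters included, is lost with probability ``l``.

The P->Q conversion is irreversible: Q cells never divide, so once a clone's
P pool is empty its size can only shrink through loss. Growth starts only
``lag_days`` after injury onset (cell-cycle entry is first detected about six
days in), so an observation at week ``w`` corresponds to
``max(0, 7 w - lag_days)`` growth days.

Besides the Monte Carlo simulator, the module provides two deterministic
twins used as oracles: closed-form expected P/Q counts, and the exact
day-by-day master equation over ``(n_P, n_Q)`` states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ParameterDomainError",
    "TruncationOverflowError",
    "FateDistribution",
    "ModelParameters",
    "ColonyState",
    "Trajectory",
    "SizeDistribution",
    "StateDistribution",
    "fate_probabilities",
    "step_colony",
    "simulate_colony",
    "simulate_states",
    "simulate_cohort",
    "expected_counts",
    "master_equation_distribution",
    "empirical_size_pmf",
    "total_variation",
    "as_rng",
]

DEFAULT_BIN_EDGES: tuple[float, ...] = (1, 2, 3, 6, 11, 21, math.inf)
"""Half-open colony-size bins 1, 2, 3-5, 6-10, 11-20, >=21 used throughout."""


class ParameterDomainError(ValueError):
    """A model parameter violates its domain constraint."""


class TruncationOverflowError(RuntimeError):
    """Master-equation state space too small for the requested horizon."""

    def __init__(self, truncated_mass: float, max_cells: int):
        self.truncated_mass = truncated_mass
        self.max_cells = max_cells
        super().__init__(
            f"probability mass {truncated_mass:.3e} escaped the state space "
            f"(max_cells={max_cells}); increase max_cells"
        )


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce an int seed (or None) to a numpy Generator; pass Generators through."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class FateDistribution:
    """Probabilities of the three division fates of a proliferative cell."""

    prob_pp: float
    prob_pq: float
    prob_qq: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ParameterDomainError(f"{name}={v} outside [0, 1]")
        total = self.prob_pp + self.prob_pq + self.prob_qq
        if abs(total - 1.0) > 1e-12:
            raise ParameterDomainError(f"fate probabilities sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "prob_pp": self.prob_pp,
            "prob_pq": self.prob_pq,
            "prob_qq": self.prob_qq,
        }


def fate_probabilities(r: float, s: float) -> FateDistribution:
    """Map the stability/imbalance parameters (r, s) to fate probabilities.

    ``prob_PP = r + s``, ``prob_PQ = 1 - 2r``, ``prob_QQ = r - s``. At
    ``s = 0`` this reduces to the balanced model (``prob_PP = prob_QQ = r``)
    in which the expected number of proliferative cells is conserved; ``s``
    is the pure expansion term (each division adds ``2s`` P cells in
    expectation).

    Raises
    ------
    ParameterDomainError
        Naming the violated inequality when any fate probability would fall
        outside [0, 1].
    """
    if r - s < 0:
        raise ParameterDomainError(
            f"constraint r - s >= 0 violated (r={r}, s={s}): prob_QQ would be negative"
        )
    if r + s > 1:
        raise ParameterDomainError(
            f"constraint r + s <= 1 violated (r={r}, s={s}): prob_PP would exceed 1"
        )
    if 1 - 2 * r < 0:
        raise ParameterDomainError(
            f"constraint 1 - 2r >= 0 violated (r={r}): prob_PQ would be negative"
        )
    if r + s < 0:
        raise ParameterDomainError(
            f"constraint r + s >= 0 violated (r={r}, s={s}): prob_PP would be negative"
        )
    return FateDistribution(prob_pp=r + s, prob_pq=1 - 2 * r, prob_qq=r - s)


@dataclass(frozen=True)
class ModelParameters:
    """The five growth parameters plus the proliferation-onset lag.

    Parameters
    ----------
    p : fraction of labeled founder cells initially in the proliferative state.
    m : per-day probability that a proliferative cell enters the cell cycle.
    r : fate-stability parameter (see :func:`fate_probabilities`).
    s : fate-imbalance (expansion) parameter.
    l : per-day probability that any cell is lost to death.
    lag_days : days between injury onset and the first cell-cycle entry.

    Defaults are the values fitted to the thioacetamide injury time course.
    """

    p: float = 0.465
    m: float = 0.175
    r: float = 0.15
    s: float = 0.06
    l: float = 0.001
    lag_days: int = 6

    def __post_init__(self) -> None:
        for name in ("p", "m", "l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterDomainError(f"{name}={v} outside [0, 1]")
        if self.lag_days < 0:
            raise ParameterDomainError(f"lag_days={self.lag_days} must be >= 0")
        fate_probabilities(self.r, self.s)  # validates (r, s) jointly

    @property
    def fates(self) -> FateDistribution:
        return fate_probabilities(self.r, self.s)

    def growth_days(self, week: float) -> int:
        """Growth days for an observation at `week` weeks after injury onset."""
        return max(0, int(round(7 * week)) - self.lag_days)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "p": self.p,
            "m": self.m,
            "r": self.r,
            "s": self.s,
            "l": self.l,
            "lag_days": self.lag_days,
        }


@dataclass(frozen=True)
class ColonyState:
    """Counts of proliferative and quiescent cells in one clone on one day."""

    n_p: int
    n_q: int
    day: int = 0

    def __post_init__(self) -> None:
        if self.n_p < 0 or self.n_q < 0 or self.day < 0:
            raise ValueError(f"negative count or day in {self!r}")

    @property
    def size(self) -> int:
        return self.n_p + self.n_q


@dataclass(frozen=True)
class Trajectory:
    """Daily states of one simulated clone, day 0 (single founder) onward."""

    states: tuple[ColonyState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("trajectory must contain at least the founder state")
        days = [st.day for st in self.states]
        if days != list(range(days[0], days[0] + len(days))):
            raise ValueError("trajectory days must increase by 1")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> ColonyState:
        return self.states[-1]

    def sizes(self) -> np.ndarray:
        return np.array([st.size for st in self.states])

    def to_dataframe(self, colony_id: int | str = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "colony_id": colony_id,
                "day": [st.day for st in self.states],
                "n_P": [st.n_p for st in self.states],
                "n_Q": [st.n_q for st in self.states],
            }
        )


@dataclass(frozen=True)
class SizeDistribution:
    """Histogram (counts or probability mass) over colony sizes.

    `support` holds distinct sizes, or the bin lower edges when `bin_edges`
    is set (half-open integer bins ``[e_i, e_{i+1})``, the last edge may be
    ``inf``). Extinct (size-0) clones are excluded by default — they are
    unobservable in tissue — and their number is reported separately.
    """

    support: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray | None = None
    excludes_extinct: bool = True
    n_extinct: float = 0
    truncated_mass: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            if len(edges) != len(self.support) + 1:
                raise ValueError("bin_edges length must be n_bins + 1")
            object.__setattr__(self, "bin_edges", edges)
        if np.any(self.counts < 0):
            raise ValueError("negative mass in size distribution")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts)
        return self.counts / self.total

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.probabilities

    @classmethod
    def from_sizes(
        cls, sizes: Iterable[int], exclude_extinct: bool = True
    ) -> "SizeDistribution":
        arr = np.asarray(list(sizes) if not isinstance(sizes, np.ndarray) else sizes)
        n_extinct = int(np.sum(arr == 0))
        if exclude_extinct:
            arr = arr[arr > 0]
        support, counts = np.unique(arr, return_counts=True)
        return cls(
            support=support,
            counts=counts,
            excludes_extinct=exclude_extinct,
            n_extinct=n_extinct,
        )

    def binned(self, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> "SizeDistribution":
        """Rebin an unbinned distribution onto half-open integer bins."""
        if self.bin_edges is not None:
            raise ValueError("distribution is already binned")
        edges = np.asarray(bin_edges, dtype=float)
        idx = np.searchsorted(edges, self.support, side="right") - 1
        if np.any(idx < 0) or np.any(self.support >= edges[-1]):
            raise ValueError("bin edges do not cover all observed sizes")
        counts = np.zeros(len(edges) - 1)
        np.add.at(counts, idx, self.counts)
        return SizeDistribution(
            support=edges[:-1],
            counts=counts,
            bin_edges=edges,
            excludes_extinct=self.excludes_extinct,
            n_extinct=self.n_extinct,
            truncated_mass=self.truncated_mass,
        )

    def to_frame(self) -> pd.DataFrame:
        if self.bin_edges is not None:
            return pd.DataFrame(
                {
                    "bin_low": self.bin_edges[:-1],
                    "bin_high": self.bin_edges[1:],
                    "count": self.counts,
                    "probability": self.probabilities,
                }
            )
        return pd.DataFrame(
            {
                "size": self.support.astype(int),
                "count": self.counts,
                "probability": self.probabilities,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SizeDistribution":
        df = pd.read_csv(path)
        if "size" in df.columns:
            return cls(support=df["size"].to_numpy(), counts=df["count"].to_numpy())
        edges = np.append(df["bin_low"].to_numpy(), df["bin_high"].to_numpy()[-1])
        return cls(support=edges[:-1], counts=df["count"].to_numpy(), bin_edges=edges)


# ---------------------------------------------------------------------------
# Monte Carlo simulation
# ---------------------------------------------------------------------------


def _step_arrays(
    n_p: np.ndarray | int,
    n_q: np.ndarray | int,
    params: ModelParameters,
    rng: np.random.Generator,
):
    """One-day update of (n_P, n_Q); works on scalars or aligned arrays.

    Divisions first, then loss applied to every cell including newborns.
    The multinomial fate split is drawn as two nested binomials, which is
    exact and vectorizes over clones.
    """
    f = params.fates
    divisions = rng.binomial(n_p, params.m)
    n_pp = rng.binomial(divisions, f.prob_pp)
    rest = divisions - n_pp
    denom = f.prob_pq + f.prob_qq
    if denom > 0:
        n_pq = rng.binomial(rest, f.prob_pq / denom)
    else:
        n_pq = rest * 0
    n_qq = rest - n_pq
    n_p = n_p - divisions + 2 * n_pp + n_pq
    n_q = n_q + n_pq + 2 * n_qq
    if params.l > 0:
        n_p = rng.binomial(n_p, 1.0 - params.l)
        n_q = rng.binomial(n_q, 1.0 - params.l)
    return n_p, n_q


def step_colony(
    state: ColonyState, params: ModelParameters, rng: np.random.Generator | int
) -> ColonyState:
    """Advance one clone by one day under the stochastic kernel."""
    rng = as_rng(rng)
    n_p, n_q = _step_arrays(state.n_p, state.n_q, params, rng)
    return ColonyState(n_p=int(n_p), n_q=int(n_q), day=state.day + 1)


def simulate_colony(
    founder_proliferative: bool,
    params: ModelParameters,
    days: int,
    rng: np.random.Generator | int,
) -> Trajectory:
    """Simulate one clone from a single founder for `days` days."""
    if days < 0:
        raise ValueError("days must be >= 0")
    rng = as_rng(rng)
    state = ColonyState(n_p=1 if founder_proliferative else 0, n_q=0 if founder_proliferative else 1)
    states = [state]
    for _ in range(days):
        state = step_colony(state, params, rng)
        states.append(state)
    return Trajectory(states=tuple(states))


def simulate_states(
    founders_proliferative: np.ndarray,
    params: ModelParameters,
    days: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cohort simulation: final (n_P, n_Q) per clone.

    `founders_proliferative` is a boolean array, one entry per clone. All
    clones advance in lockstep on a single random stream, which makes a
    cohort bit-reproducible for a given seed.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    rng = as_rng(rng)
    founders = np.asarray(founders_proliferative, dtype=bool)
    n_p = founders.astype(np.int64)
    n_q = 1 - n_p
    for _ in range(days):
        n_p, n_q = _step_arrays(n_p, n_q, params, rng)
    return n_p, n_q


def simulate_cohort(
    n_founders: int,
    params: ModelParameters,
    days: int,
    rng: np.random.Generator | int,
    exclude_extinct: bool = True,
) -> SizeDistribution:
    """Simulate `n_founders` clones and return the final colony-size histogram.

    Each founder is proliferative with probability ``p``. Extinct clones are
    excluded from the histogram by default and reported via ``n_extinct``.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    rng = as_rng(rng)
    founders = rng.random(n_founders) < params.p
    n_p, n_q = simulate_states(founders, params, days, rng)
    return SizeDistribution.from_sizes(n_p + n_q, exclude_extinct=exclude_extinct)


# ---------------------------------------------------------------------------
# Deterministic twins (oracles)
# ---------------------------------------------------------------------------


def expected_counts(params: ModelParameters, days: int) -> tuple[float, float]:
    """Exact expected (n_P, n_Q) after `days` days from one proliferative founder.

    E[n_P] multiplies by ``(1 + 2 m s)(1 - l)`` per day: a division changes
    the P count by +1 (PP), 0 (PQ) or -1 (QQ), so the expected net gain per
    division is ``2s``. E[n_Q] gains ``m (1 - 2s) E[n_P]`` per day before
    loss thinning.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    e_p, e_q = 1.0, 0.0
    for _ in range(days):
        e_q = (e_q + params.m * (1 - 2 * params.s) * e_p) * (1 - params.l)
        e_p = e_p * (1 + 2 * params.m * params.s) * (1 - params.l)
    return e_p, e_q


def _per_p_cell_kernel(params: ModelParameters) -> np.ndarray:
    """One-day offspring pmf of a single P cell over (dP, dQ) in {0,1,2}^2.

    Loss is folded in: each resulting cell (undivided mother or newborn
    daughter) survives the day with probability 1 - l.
    """
    f = params.fates
    m, l = params.m, params.l
    keep = 1.0 - l
    k = np.zeros((3, 3))
    # no division: the mother either survives as P or is lost
    k[1, 0] += (1 - m) * keep
    k[0, 0] += (1 - m) * l
    # PP: two P daughters, independent survival
    w = m * f.prob_pp
    k[2, 0] += w * keep * keep
    k[1, 0] += w * 2 * keep * l
    k[0, 0] += w * l * l
    # PQ
    w = m * f.prob_pq
    k[1, 1] += w * keep * keep
    k[1, 0] += w * keep * l
    k[0, 1] += w * l * keep
    k[0, 0] += w * l * l
    # QQ
    w = m * f.prob_qq
    k[0, 2] += w * keep * keep
    k[0, 1] += w * 2 * keep * l
    k[0, 0] += w * l * l
    return k


@dataclass(frozen=True)
class StateDistribution:
    """Exact joint pmf over (n_P, n_Q) colony states at one day.

    ``pmf[i, j]`` is P(n_P = i, n_Q = j); mass that escaped the truncated
    square state space is accumulated in ``truncated_mass`` so that
    ``pmf.sum() + truncated_mass = 1``.
    """

    pmf: np.ndarray
    truncated_mass: float
    day: int

    @property
    def max_cells(self) -> int:
        return self.pmf.shape[0] - 1

    def size_pmf(self) -> np.ndarray:
        """Marginal pmf of colony size n_P + n_Q (index = size, incl. 0)."""
        n = self.pmf.shape[0]
        idx = np.add.outer(np.arange(n), np.arange(n)).ravel()
        return np.bincount(idx, weights=self.pmf.ravel())

    def size_distribution(self, exclude_extinct: bool = True) -> SizeDistribution:
        pmf = self.size_pmf()
        extinct = pmf[0]
        support = np.nonzero(pmf)[0]
        if exclude_extinct:
            support = support[support > 0]
        return SizeDistribution(
            support=support,
            counts=pmf[support],
            excludes_extinct=exclude_extinct,
            n_extinct=extinct,
            truncated_mass=self.truncated_mass,
        )

    def expected_counts(self) -> tuple[float, float]:
        n = self.pmf.shape[0]
        i = np.arange(n)
        return (
            float(i @ self.pmf.sum(axis=1)),
            float(i @ self.pmf.sum(axis=0)),
        )


def master_equation_distribution(
    params: ModelParameters,
    days: int,
    max_cells: int = 128,
    founder_proliferative: bool = True,
    max_truncated_mass: float = 1e-6,
) -> StateDistribution:
    """Exact day-by-day distribution over (n_P, n_Q) under the same kernel.

    Cells act independently, so the colony's one-day transition from state
    ``(i, j)`` is the i-fold convolution of the per-P-cell offspring pmf with
    binomial thinning of the j quiescent cells. Mass leaving the
    ``[0, max_cells]^2`` square is tracked as ``truncated_mass``.

    Raises
    ------
    TruncationOverflowError
        If the accumulated truncated mass exceeds `max_truncated_mass`.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    if max_cells < 2:
        raise ValueError("max_cells must be >= 2")
    mm = max_cells
    kernel = _per_p_cell_kernel(params)
    # iterated convolutions of the per-P-cell kernel: conv_p[i] has shape (2i+1, 2i+1)
    conv_p: list[np.ndarray] = [np.ones((1, 1))]
    for _ in range(mm):
        conv_p.append(signal.convolve2d(conv_p[-1], kernel))
    # binomial thinning matrix for pre-existing Q cells: b[j, q] = P(q of j survive)
    j_idx = np.arange(mm + 1)
    b_thin = stats.binom.pmf(j_idx[None, :], j_idx[:, None], 1.0 - params.l)

    pmf = np.zeros((mm + 1, mm + 1))
    if founder_proliferative:
        pmf[1, 0] = 1.0
    else:
        pmf[0, 1] = 1.0
    truncated = 0.0
    for _ in range(days):
        thinned = pmf @ b_thin  # thins the existing Q pool
        new = np.zeros_like(pmf)
        for i in range(mm + 1):
            row = thinned[i]
            if row.sum() <= 1e-300:
                continue
            if i == 0:
                new[0] += row  # no P cells: nothing divides, Q already thinned
                continue
            ci = conv_p[i]
            for d_p in range(2 * i + 1):
                krow = ci[d_p]
                if not krow.any():
                    continue
                conv = np.convolve(row, krow)
                if d_p <= mm:
                    new[d_p] += conv[: mm + 1]
                    truncated += conv[mm + 1 :].sum()
                else:
                    truncated += conv.sum()
        pmf = new
        if truncated > max_truncated_mass:
            raise TruncationOverflowError(truncated, mm)
    return StateDistribution(pmf=pmf, truncated_mass=truncated, day=days)


# ---------------------------------------------------------------------------
# Small helpers shared by tests, inference and the acceptance script
# ---------------------------------------------------------------------------


def empirical_size_pmf(sizes: np.ndarray, length: int) -> np.ndarray:
    """Empirical pmf over sizes 0..length-1 (overflow pooled into the top bin)."""
    sizes = np.minimum(np.asarray(sizes, dtype=np.int64), length - 1)
    counts = np.bincount(sizes, minlength=length)
    return counts / counts.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on a common support."""
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
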