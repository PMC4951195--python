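"""Consecutive dual-nucleotide labeling predictions.

The experiment that discriminates the two candidate growth modes: animals
receive a first nucleotide analog (e.g. BrdU) continuously for eight days,
then after an eight-day washout a one-day pulse of a second analog (e.g.
EdU). Any cell that divides while a label is present incorporates it, and
both daughters stay positive.

Two hypotheses make different predictions about the overlap of the two
labels among second-label-positive cells:

* **Two-state, irreversible** — cells cycling at the pulse have been
  proliferative throughout, so almost all of them already divided during the
  long first window: the second-label-positive population is (nearly) a
  subset of the first. The analytic ceiling is the probability of at least
  one division in the first window, ``1 - (1 - m)^w`` (0.78539 for
  m = 0.175, w = 8 days).
* **Unregulated switching** — cells drift freely between states, the two
  labelings are independent events, and the double-positive fraction among
  second-label-positive cells equals the population-wide first-label
  fraction, which is much lower.

:func:`predict_two_state` simulates the full model over the schedule;
:func:`predict_independent` gives the independence prediction;
``state_memory=False`` re-randomizes each cell's state daily, a degenerate
memoryless mode that reproduces the independent prediction and serves as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_model import ModelParameters, ParameterDomainError, as_rng

__all__ = [
    "LabelSchedule",
    "LabelOutcome",
    "cumulative_label_probability",
    "simulate_label_population",
    "predict_two_state",
    "predict_independent",
]


@dataclass(frozen=True)
class LabelSchedule:
    """Timing of the two labeling windows, in whole days."""

    first_label_days: int = 8
    interval_days: int = 8
    second_label_pulse_days: int = 1

    def __post_init__(self) -> None:
        if self.first_label_days < 1:
            raise ValueError("first_label_days must be >= 1")
        if self.interval_days < 0:
            raise ValueError("interval_days must be >= 0")
        if self.second_label_pulse_days < 1:
            raise ValueError("second_label_pulse_days must be >= 1")

    @property
    def total_days(self) -> int:
        return self.first_label_days + self.interval_days + self.second_label_pulse_days


@dataclass(frozen=True)
class LabelOutcome:
    """Population label fractions at the end of a dual-labeling schedule."""

    frac_first_pos: float
    frac_second_pos: float
    frac_double_pos_given_second: float
    n_cells: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_first_pos", "frac_second_pos", "frac_double_pos_given_second"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def standard_errors(self) -> dict[str, float]:
        """Binomial Monte Carlo standard errors (0 when n_cells unknown)."""
        if self.n_cells <= 0:
            return {k: 0.0 for k in ("frac_first_pos", "frac_second_pos",
                                     "frac_double_pos_given_second")}
        n = self.n_cells
        n2 = max(1.0, self.frac_second_pos * n)
        se = lambda f, nn: float(np.sqrt(f * (1 - f) / nn))
        return {
            "frac_first_pos": se(self.frac_first_pos, n),
            "frac_second_pos": se(self.frac_second_pos, n),
            "frac_double_pos_given_second": se(self.frac_double_pos_given_second, n2),
        }

    def as_dict(self) -> dict[str, float]:
        return {
            "frac_first_pos": self.frac_first_pos,
            "frac_second_pos": self.frac_second_pos,
            "frac_double_pos_given_second": self.frac_double_pos_given_second,
            "n_cells": self.n_cells,
        }


def cumulative_label_probability(m: float, days: int) -> float:
    """Probability that a continuously proliferative cell divides at least
    once — and hence incorporates label — during a `days`-day window.

    ``1 - (1 - m)^days``; equals m at days=1 and 0.78539 at (0.175, 8).
    """
    if not 0.0 <= m <= 1.0:
        raise ParameterDomainError(f"m={m} outside [0, 1]")
    if days < 0:
        raise ParameterDomainError(f"days={days} must be >= 0")
    return 1.0 - (1.0 - m) ** days


def simulate_label_population(
    schedule: LabelSchedule,
    params: ModelParameters,
    n_cells: int,
    rng: np.random.Generator | int,
    state_memory: bool = True,
) -> pd.DataFrame:
    """Simulate per-cell label states over the full schedule.

    Starts from `n_cells` cells (proliferative with probability ``p``) and
    runs the daily two-state kernel. A division during a label window marks
    both daughters permanently; daughters inherit their mother's earlier
    labels. Newborns are assigned their fate-drawn states, and every cell is
    lost with probability ``l`` per day.

    With ``state_memory=False`` each cell's state is re-drawn daily
    (proliferative with probability ``p``), which destroys the temporal
    correlation between the two labelings.

    Returns a DataFrame with boolean columns ``proliferative``,
    ``first_label`` and ``second_label``, one row per surviving cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = as_rng(rng)
    f = params.fates
    prolif = rng.random(n_cells) < params.p
    lab1 = np.zeros(n_cells, dtype=bool)
    lab2 = np.zeros(n_cells, dtype=bool)
    pulse_start = schedule.first_label_days + schedule.interval_days
    for day in range(schedule.total_days):
        n = prolif.size
        if n == 0:
            break
        if not state_memory:
            prolif = rng.random(n) < params.p
        in_first = day < schedule.first_label_days
        in_second = day >= pulse_start
        dividing = prolif & (rng.random(n) < params.m)
        mothers = np.nonzero(dividing)[0]
        keep = ~dividing
        u = rng.random(mothers.size)
        is_pp = u < f.prob_pp
        is_pq = ~is_pp & (u < f.prob_pp + f.prob_pq)
        d_lab1 = lab1[mothers] | in_first
        d_lab2 = lab2[mothers] | in_second
        # daughter A is proliferative for PP and PQ fates, daughter B only for PP
        prolif = np.concatenate([prolif[keep], is_pp | is_pq, is_pp])
        lab1 = np.concatenate([lab1[keep], d_lab1, d_lab1])
        lab2 = np.concatenate([lab2[keep], d_lab2, d_lab2])
        if params.l > 0:
            alive = rng.random(prolif.size) >= params.l
            prolif, lab1, lab2 = prolif[alive], lab1[alive], lab2[alive]
    return pd.DataFrame(
        {"proliferative": prolif, "first_label": lab1, "second_label": lab2}
    )


def tabulate_outcome(population: pd.DataFrame) -> LabelOutcome:
    """Reduce a per-cell label table to population fractions."""
    n = len(population)
    if n == 0:
        return LabelOutcome(0.0, 0.0, 0.0, 0)
    lab1 = population["first_label"].to_numpy()
    lab2 = population["second_label"].to_numpy()
    n2 = int(lab2.sum())
    return LabelOutcome(
        frac_first_pos=float(lab1.mean()),
        frac_second_pos=float(lab2.mean()),
        frac_double_pos_given_second=float((lab1 & lab2).sum() / n2) if n2 else 0.0,
        n_cells=n,
    )


def predict_two_state(
    schedule: LabelSchedule,
    params: ModelParameters,
    n_cells: int,
    rng: np.random.Generator | int,
    state_memory: bool = True,
) -> LabelOutcome:
    """Simulated dual-labeling outcome under the two-state model."""
    population = simulate_label_population(schedule, params, n_cells, rng, state_memory)
    return tabulate_outcome(population)


def predict_independent(frac_first_pos: float, frac_second_pos: float) -> LabelOutcome:
    """Dual-labeling outcome if the two labelings were independent events.

    Under independence the double-positive fraction among
    second-label-positive cells equals the population first-label fraction.
    """
    for name, v in (("frac_first_pos", frac_first_pos), ("frac_second_pos", frac_second_pos)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return LabelOutcome(
        frac_first_pos=frac_first_pos,
        frac_second_pos=frac_second_pos,
        frac_double_pos_given_second=frac_first_pos,
    )
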