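"""Synthetic clonal-tracing studies emulating the in vivo design.

The real study labeled under 0.2% of biliary epithelial cells, traced
colonies at 0, 2, 4, 6 and 8 weeks of injury (257, 272, 304, 307 and 310
colonies per time point, pooled from five mice each), and sized every colony
by 3D nuclear counting. This module generates complete datasets of that
shape from the growth model, so the binning, distance and fitting machinery
can be exercised — and parameter recovery measured — without any external
data.

Compartment tags are decorative metadata: the duct vs. peripheral-ductule
distinction is anatomical (luminal diameter), not mechanistic, so duct tags
are assigned by a rejection rule (duct colonies never exceed five cells,
matching the observation that large clones arise only in the ductules)
rather than by a second growth process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .growth_model import ModelParameters, as_rng
from .inference import TracingDataset, simulate_design
from .labeling_model import LabelSchedule, simulate_label_population

__all__ = ["StudyDesign", "generate_study", "generate_dual_label_population"]

DUCT_MAX_SIZE = 5


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a synthetic tracing study (defaults mirror the injury time course)."""

    weeks: tuple[float, ...] = (0, 2, 4, 6, 8)
    colonies_per_week: tuple[int, ...] = (257, 272, 304, 307, 310)
    n_animals: int = 5
    labeling_fraction: float = 0.002
    compartment_mix: dict[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.colonies_per_week):
            raise ValueError("weeks and colonies_per_week must align")
        if any(n < 1 for n in self.colonies_per_week):
            raise ValueError("each week needs at least one colony")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0 < self.labeling_fraction <= 1:
            raise ValueError("labeling_fraction must be in (0, 1]")
        if self.compartment_mix is not None:
            total = sum(self.compartment_mix.values())
            if not 0 < total <= 1 + 1e-9:
                raise ValueError("compartment_mix fractions must sum to at most 1")

    @property
    def total_colonies(self) -> int:
        return sum(self.colonies_per_week)


def generate_study(
    design: StudyDesign,
    params: ModelParameters,
    rng: np.random.Generator | int | None = None,
) -> TracingDataset:
    """Generate a full synthetic tracing dataset under the growth model.

    Colonies are drawn per week via :func:`becgrowth.inference.simulate_design`
    (lag-corrected growth days, extinct clones resampled), assigned to
    animals round-robin — mice are pooled per time point, so no animal-level
    variance is modeled — and optionally tagged with compartments. Runs with
    the same seed are byte-identical.
    """
    if rng is None:
        rng = design.seed
    rng = as_rng(rng)
    dataset = simulate_design(params, design.weeks, design.colonies_per_week, rng)
    df = dataset.df.copy()
    # round-robin animal assignment within each week
    animal = np.concatenate(
        [np.arange(n) % design.n_animals + 1 for n in design.colonies_per_week]
    )
    df["animal_id"] = [f"mouse_{a}" for a in animal]
    if design.compartment_mix:
        df["compartment"] = "ductule"
        duct_frac = design.compartment_mix.get("duct", 0.0)
        if duct_frac > 0:
            for week, n in zip(design.weeks, design.colonies_per_week):
                week_mask = df["week"] == week
                eligible = df.index[week_mask & (df["size"] <= DUCT_MAX_SIZE)]
                target = min(int(round(duct_frac * n)), eligible.size)
                if target > 0:
                    chosen = rng.choice(eligible.to_numpy(), size=target, replace=False)
                    df.loc[chosen, "compartment"] = "duct"
    metadata = {
        **dataset.metadata,
        "generator": "becgrowth.synthetic_data.generate_study",
        "version": __version__,
        "design": {
            "weeks": list(design.weeks),
            "colonies_per_week": list(design.colonies_per_week),
            "n_animals": design.n_animals,
            "labeling_fraction": design.labeling_fraction,
            "compartment_mix": design.compartment_mix,
        },
        "seed": design.seed,
        "synthetic": True,
    }
    return TracingDataset(df=df, metadata=metadata)


def generate_dual_label_population(
    schedule: LabelSchedule,
    params: ModelParameters,
    n_cells: int,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Per-cell boolean 1st/2nd label table from the dual-labeling simulation."""
    return simulate_label_population(schedule, params, n_cells, rng)


def write_metadata(metadata: dict, path) -> None:
    """Write a dataset's provenance sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)
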