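"""Shared domain types: sociodemographic categories, the spatial grid,
the agent roster and the free-parameter set.

Agents carry three sociodemographic attributes — sex (male/female), age band
(15-29, 30-59, 60-75) and education level (low/middle/high) — giving 18
categories, and occupy one 1 km-style grid cell per 8-hour time slice
(night 00:00-08:00, day 08:00-16:00, evening 16:00-24:00).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

SEXES = ("male", "female")
AGE_BANDS = ("15-29", "30-59", "60-75")
EDU_LEVELS = ("low", "middle", "high")

SLICES = ("night", "day", "evening")

#: day slice is [08:00, 16:00), evening is [16:00, 24:00), in minutes from 00:00
DAY_START, DAY_END, EVENING_END = 480, 960, 1440


class Category(NamedTuple):
    """One of the 18 sociodemographic categories (sex x age band x education)."""

    sex: str
    age_band: str
    edu_level: str


#: canonical ordering of the 18 categories (deterministic iteration order)
CATEGORIES: tuple[Category, ...] = tuple(
    Category(s, a, e) for s in SEXES for a in AGE_BANDS for e in EDU_LEVELS
)

CATEGORY_INDEX: dict[Category, int] = {c: i for i, c in enumerate(CATEGORIES)}
N_CATEGORIES = len(CATEGORIES)  # 18


def category_of(sex: str, age_band: str, edu_level: str) -> int:
    """Integer code (0..17) of a category; raises KeyError on unknown levels."""
    return CATEGORY_INDEX[Category(sex, age_band, edu_level)]


def opposite_sex_category(cat_idx: int) -> int:
    """Code of the category with the same age/education but opposite sex."""
    c = CATEGORIES[cat_idx]
    other = "female" if c.sex == "male" else "male"
    return CATEGORY_INDEX[Category(other, c.age_band, c.edu_level)]


# education rank used by rank-ordered inequality measures
EDU_RANK = {"low": 0, "middle": 1, "high": 2}


@dataclass(frozen=True)
class Grid:
    """Regular grid of cells; only populated cells may host agents.

    ``cell_id`` values are arbitrary unique integers (they survive file
    round-trips); internally populated cells are addressed by a dense index
    0..n_populated-1.
    """

    cell_ids: np.ndarray  # (n,) int
    x: np.ndarray  # (n,) int grid coordinates
    y: np.ndarray  # (n,) int
    populated: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_id values must be unique")
        coords = self.x.astype(np.int64) * (self.y.max() + 1 if len(self.y) else 1)
        if len(np.unique(coords + self.y)) != len(self.cell_ids):
            raise ValueError("(x, y) coordinates must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def populated_ids(self) -> np.ndarray:
        return self.cell_ids[self.populated]

    def id_to_dense(self) -> dict[int, int]:
        """Mapping cell_id -> dense index over populated cells."""
        return {int(cid): i for i, cid in enumerate(self.populated_ids)}

    def populated_coords(self) -> np.ndarray:
        """(n_populated, 2) array of (x, y) centroids of populated cells."""
        return np.column_stack([self.x[self.populated], self.y[self.populated]])

    @classmethod
    def regular(cls, width: int, height: int) -> "Grid":
        """Fully populated width x height grid with cell_id = y * width + x."""
        xs, ys = np.meshgrid(np.arange(width), np.arange(height))
        xs, ys = xs.ravel(), ys.ravel()
        return cls(
            cell_ids=(ys * width + xs).astype(np.int64),
            x=xs.astype(np.int64),
            y=ys.astype(np.int64),
            populated=np.ones(width * height, dtype=bool),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_index": self.x,
                "y_index": self.y,
                "populated": self.populated.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Grid":
        return cls(
            cell_ids=df["cell_id"].to_numpy(np.int64),
            x=df["x_index"].to_numpy(np.int64),
            y=df["y_index"].to_numpy(np.int64),
            populated=df["populated"].to_numpy().astype(bool),
        )


# provenance codes for day/evening cell assignment
PROVENANCE = ("observed", "interpolated", "opposite_sex_fallback", "immobile")
PROV_CODE = {p: i for i, p in enumerate(PROVENANCE)}


@dataclass
class Roster:
    """Column-oriented agent table.

    Cells are stored as dense indices over the populated cells of the owning
    grid. Opinion is a conviction in [0, 1] that eating five portions of
    fruit and vegetables a day matters; behaviour is binary (healthy =
    currently meeting the 5-a-day target).
    """

    category: np.ndarray  # (n,) int8 codes 0..17
    night: np.ndarray  # (n,) int dense cell index
    day: np.ndarray
    evening: np.ndarray
    day_prov: np.ndarray  # (n,) int8 PROVENANCE codes
    evening_prov: np.ndarray
    opinion: np.ndarray = field(default=None)  # type: ignore[assignment]
    healthy: np.ndarray = field(default=None)  # type: ignore[assignment]
    habit: np.ndarray = field(default=None)  # type: ignore[assignment]
    budget: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.category)

    @property
    def n_agents(self) -> int:
        return len(self.category)

    def copy(self) -> "Roster":
        return Roster(
            **{
                k: (v.copy() if v is not None else None)
                for k, v in self.__dict__.items()
            }
        )

    def category_totals(self) -> np.ndarray:
        """Agent counts per category code (length 18)."""
        return np.bincount(self.category, minlength=N_CATEGORIES)

    def slice_cells(self, slice_name: str) -> np.ndarray:
        if slice_name == "night":
            return self.night
        if slice_name == "day":
            return self.day
        if slice_name == "evening":
            return self.evening
        raise ValueError(f"unknown slice {slice_name!r}")

    def to_frame(self, grid: Grid) -> pd.DataFrame:
        """Export with original cell_id values and readable category levels."""
        pop_ids = grid.populated_ids
        cats = [CATEGORIES[c] for c in self.category]
        df = pd.DataFrame(
            {
                "agent_id": np.arange(len(self)),
                "sex": [c.sex for c in cats],
                "age_band": [c.age_band for c in cats],
                "edu_level": [c.edu_level for c in cats],
                "night_cell": pop_ids[self.night],
                "day_cell": pop_ids[self.day],
                "evening_cell": pop_ids[self.evening],
                "day_provenance": [PROVENANCE[p] for p in self.day_prov],
                "evening_provenance": [PROVENANCE[p] for p in self.evening_prov],
            }
        )
        if self.opinion is not None:
            df["opinion"] = self.opinion
        if self.healthy is not None:
            df["healthy"] = self.healthy.astype(int)
            df["habit_constraint"] = self.habit.astype(int)
            df["budget_constraint"] = self.budget.astype(int)
        return df


@dataclass(frozen=True)
class ParameterSet:
    """The four free parameters of the behaviour-change model.

    healthy_diet_reward (HDR): multiplicative opinion reinforcement applied to
        agents who behaved healthily in the previous step; in [0, 1].
    opinion_inertia (IC): weight of an agent's own (rewarded) opinion against
        the healthy share observed in its current cell; in [0, 1].
    max_proba_to_switch (MPS): slope ceiling of the opinion-to-switch mapping;
        in [0, 1].
    constraint_strength (CS): per-constraint reduction (or, for the budget
        constraint of a healthy agent, increase) of the switch ceiling;
        in [0, MPS].
    """

    healthy_diet_reward: float
    opinion_inertia: float
    max_proba_to_switch: float
    constraint_strength: float

    def __post_init__(self) -> None:
        for name in (
            "healthy_diet_reward",
            "opinion_inertia",
            "max_proba_to_switch",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        cs = self.constraint_strength
        if not 0.0 <= cs <= self.max_proba_to_switch:
            raise ValueError(
                f"constraint_strength={cs} outside [0, max_proba_to_switch]"
            )
        # the tighter coupled box MPS <= 1 - 2*CS is advisory only: the
        # calibrated default set falls outside it, so violations warn rather
        # than raise
        if self.max_proba_to_switch > 1 - 2 * cs:
            warnings.warn(
                "parameter set outside the advisory box "
                "max_proba_to_switch <= 1 - 2*constraint_strength; final "
                "switch probabilities are clamped to [0, 1]",
                stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.healthy_diet_reward,
                self.opinion_inertia,
                self.max_proba_to_switch,
                self.constraint_strength,
            ]
        )


#: calibrated parameter set used for the scenario experiments (an intermediate
#: reward value among the five maximally diverse acceptable sets)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    CALIBRATED_PARAMS = ParameterSet(
        healthy_diet_reward=0.153,
        opinion_inertia=0.820,
        max_proba_to_switch=0.890,
        constraint_strength=0.129,
    )
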