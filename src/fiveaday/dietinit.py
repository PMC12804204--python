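"""Initialise dietary behaviour, opinion and fixed constraints of agents from
the 18 sociodemographic group profiles of the 2002/2008 Health and Nutrition
Barometer surveys.

Behaviour is binary (healthy = ate at least five portions of fruit and
vegetables the previous day) and is drawn from the 2002 group frequency.
Opinion (conviction in [0,1] that 5-a-day matters) is drawn conditionally on
behaviour, either from supplied quintile bins or from a truncated normal
around the group's observed mean. Two fixed constraint flags (household
habits, budget) are drawn from the group prevalences and never change during
a simulation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CATEGORIES, CATEGORY_INDEX, N_CATEGORIES, Category, Roster

#: dispersion of the truncated-normal opinion fallback (declared default,
#: used when no empirical quintile distribution is supplied)
OPINION_FALLBACK_SD = 0.15


@dataclass(frozen=True)
class GroupProfile:
    """Survey-derived quantities for one sociodemographic category."""

    category: Category
    n_2002: int
    n_2008: int
    p_healthy_2002: float
    p_healthy_2008: float
    mean_opinion_healthy: float
    mean_opinion_unhealthy: float
    p_habit: float
    p_budget: float

    def __post_init__(self) -> None:
        for name in (
            "p_healthy_2002",
            "p_healthy_2008",
            "mean_opinion_healthy",
            "mean_opinion_unhealthy",
            "p_habit",
            "p_budget",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] for {self.category}")


class ProfileSet:
    """Complete, validated set of the 18 group profiles.

    ``quintiles`` optionally maps (category index, behaviour) to aligned
    arrays (bin_lo, bin_hi, mass) describing the empirical opinion
    distribution; when absent the truncated-normal fallback applies.
    """

    def __init__(
        self,
        profiles: dict[int, GroupProfile],
        quintiles: dict[tuple[int, bool], tuple[np.ndarray, np.ndarray, np.ndarray]]
        | None = None,
    ):
        missing = [CATEGORIES[i] for i in range(N_CATEGORIES) if i not in profiles]
        if missing:
            raise ValueError(f"profiles missing for categories: {missing}")
        self.profiles = profiles
        self.quintiles = quintiles or {}

    def __getitem__(self, cat_idx: int) -> GroupProfile:
        return self.profiles[cat_idx]

    def array(self, field: str) -> np.ndarray:
        """Per-category vector of one profile field, in canonical order."""
        return np.array([getattr(self.profiles[i], field) for i in range(N_CATEGORIES)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, quintiles: pd.DataFrame | None = None):
        profiles = {}
        for row in df.itertuples(index=False):
            cat = Category(row.sex, row.age_band, row.edu_level)
            profiles[CATEGORY_INDEX[cat]] = GroupProfile(
                category=cat,
                n_2002=int(row.n_2002),
                n_2008=int(row.n_2008),
                p_healthy_2002=float(row.p_healthy_2002),
                p_healthy_2008=float(row.p_healthy_2008),
                mean_opinion_healthy=float(row.mean_opinion_healthy),
                mean_opinion_unhealthy=float(row.mean_opinion_unhealthy),
                p_habit=float(row.p_habit),
                p_budget=float(row.p_budget),
            )
        qmap = None
        if quintiles is not None:
            qmap = {}
            grp = quintiles.groupby(["sex", "age_band", "edu_level", "behaviour"])
            for (sex, age, edu, beh), g in grp:
                key = (CATEGORY_INDEX[Category(sex, age, edu)], beh == "healthy")
                lo = g["bin_lo"].to_numpy(float)
                hi = g["bin_hi"].to_numpy(float)
                mass = g["mass"].to_numpy(float)
                if abs(mass.sum() - 1.0) > 1e-9:
                    raise ValueError(f"quintile masses for {key} sum to {mass.sum()}")
                qmap[key] = (lo, hi, mass / mass.sum())
        return cls(profiles, qmap)


def load_default_profiles() -> ProfileSet:
    """Load the packaged group-profile fixture (transcribed survey table)."""
    ref = importlib.resources.files("fiveaday.data") / "group_profiles.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != N_CATEGORIES:
        raise ValueError(f"profile fixture has {len(df)} rows, expected 18")
    return ProfileSet.from_frame(df)


def init_behaviour(
    roster: Roster, profiles: ProfileSet, rng: np.random.Generator
) -> Roster:
    """Draw each agent's initial behaviour ~ Bernoulli(p_healthy_2002 of its
    category)."""
    p = profiles.array("p_healthy_2002")[roster.category]
    out = roster.copy()
    out.healthy = rng.random(len(roster)) < p
    return out


def truncnorm_mean(loc: float, sd: float = OPINION_FALLBACK_SD) -> float:
    """Theoretical mean of the [0,1]-truncated normal opinion fallback."""
    a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
    return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))


def init_opinion(
    roster: Roster, profiles: ProfileSet, rng: np.random.Generator
) -> Roster:
    """Draw each agent's initial opinion conditionally on (category, behaviour).

    Quintile mode: pick a bin by its mass, then uniform within the bin.
    Fallback mode: normal(group mean, 0.15) truncated to [0, 1].
    """
    if roster.healthy is None:
        raise ValueError("behaviours must be initialised before opinions")
    out = roster.copy()
    opinion = np.empty(len(roster), float)
    for cat in range(N_CATEGORIES):
        for healthy in (False, True):
            mask = (out.category == cat) & (out.healthy == healthy)
            n = int(mask.sum())
            if n == 0:
                continue
            q = profiles.quintiles.get((cat, healthy))
            if q is not None:
                lo, hi, mass = q
                cum = np.cumsum(mass)
                cum[-1] = 1.0
                bins = np.searchsorted(cum, rng.random(n), side="right")
                opinion[mask] = lo[bins] + rng.random(n) * (hi[bins] - lo[bins])
            else:
                prof = profiles[cat]
                loc = (
                    prof.mean_opinion_healthy
                    if healthy
                    else prof.mean_opinion_unhealthy
                )
                sd = OPINION_FALLBACK_SD
                a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
                opinion[mask] = stats.truncnorm.rvs(
                    a, b, loc=loc, scale=sd, size=n, random_state=rng
                )
    out.opinion = np.clip(opinion, 0.0, 1.0)
    return out


def init_constraints(
    roster: Roster, profiles: ProfileSet, rng: np.random.Generator
) -> Roster:
    """Draw the two fixed constraint flags, independently per agent:
    habit ~ Bernoulli(p_habit), budget ~ Bernoulli(p_budget) of the
    agent's category."""
    p_habit = profiles.array("p_habit")[roster.category]
    p_budget = profiles.array("p_budget")[roster.category]
    out = roster.copy()
    out.habit = rng.random(len(roster)) < p_habit
    out.budget = rng.random(len(roster)) < p_budget
    return out


def initialise_roster(
    roster: Roster, profiles: ProfileSet, rng: np.random.Generator
) -> Roster:
    """Behaviour, then opinion (conditional on behaviour), then constraints."""
    out = init_behaviour(roster, profiles, rng)
    out = init_opinion(out, profiles, rng)
    return init_constraints(out, profiles, rng)


def expected_initial_healthy_share(roster: Roster, profiles: ProfileSet) -> float:
    """Sum over categories of (category share) x p_healthy_2002."""
    totals = roster.category_totals()
    p = profiles.array("p_healthy_2002")
    return float((totals * p).sum() / max(totals.sum(), 1))
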