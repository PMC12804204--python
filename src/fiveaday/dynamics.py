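"""The opinion/behaviour update engine.

Each simulated "day" has three time slices (night, day, evening); a run is
six days, i.e. 18 steps, one slice per step, representing the six years
between the two survey waves. Every step applies a synchronous chain of four
mechanisms to all agents:

1. reward — agents who behaved healthily entering the step reinforce their
   opinion: o <- min(1, (1 + HDR) * o);
2. exposure — each agent records the healthy share among the *other* agents
   sharing its current-slice cell (absent when the agent is alone);
3. opinion update — new opinion = IC * rewarded opinion
   + (1 - IC) * exposure; when exposure is absent the rewarded opinion keeps
   full weight;
4. behaviour switch — an unhealthy agent with new opinion o switches with
   probability max(0, y*(2o-1)) and a healthy one with max(0, y*(-2o+1)),
   where y = MPS - n*CS and n counts the agent's slowing constraints
   (unhealthy: habit + budget in {0,1,2}; healthy: habit - budget in
   {-1,0,1}, the budget constraint accelerating the switch to the cheaper
   unhealthy diet). Probabilities are clamped to [0, 1].

Updates are synchronous: exposure, reward and the switch decision all read
the behaviours/opinions as of the start of the step, so results do not
depend on agent iteration order. Behaviour switches consume one uniform
draw per agent per step, in agent-index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CATEGORIES, N_CATEGORIES, ParameterSet, Roster, SLICES


def slice_at(step: int) -> str:
    """Slice of a step index; step 0 is the night slice (agents start at
    their residence)."""
    return SLICES[step % 3]


def cell_exposure(
    cells: np.ndarray, healthy: np.ndarray, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent healthy share among the other occupants of the agent's cell.

    Returns (exposure, has_exposure); exposure is 0 where has_exposure is
    False (agent alone in its cell).
    """
    n_c = np.bincount(cells, minlength=n_cells)
    h_c = np.bincount(cells, weights=healthy.astype(float), minlength=n_cells)
    others = n_c[cells] - 1
    h_others = h_c[cells] - healthy
    has = others > 0
    exposure = np.where(has, h_others / np.maximum(others, 1), 0.0)
    return exposure, has


def update_opinion(
    opinion: np.ndarray,
    was_healthy: np.ndarray,
    exposure: np.ndarray,
    has_exposure: np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """Reward-aware inertial opinion update; result stays in [0, 1]."""
    if np.any((opinion < 0) | (opinion > 1)):
        raise ValueError("opinion outside [0, 1]")
    ic = params.opinion_inertia
    hdr = params.healthy_diet_reward
    rewarded = np.where(
        was_healthy, np.minimum(1.0, (1.0 + hdr) * opinion), opinion
    )
    return np.where(has_exposure, ic * rewarded + (1.0 - ic) * exposure, rewarded)


def switch_probability(
    healthy: np.ndarray,
    opinion: np.ndarray,
    habit: np.ndarray,
    budget: np.ndarray,
    params: ParameterSet,
) -> np.ndarray:
    """Probability of switching behaviour given the updated opinion and the
    fixed constraints; clamped to [0, 1]."""
    mps, cs = params.max_proba_to_switch, params.constraint_strength
    n_u = habit.astype(int) + budget.astype(int)
    n_h = habit.astype(int) - budget.astype(int)
    y = np.where(healthy, mps - n_h * cs, mps - n_u * cs)
    lever = np.where(healthy, -2.0 * opinion + 1.0, 2.0 * opinion - 1.0)
    return np.clip(np.maximum(0.0, y * lever), 0.0, 1.0)


@dataclass
class SimulationState:
    """Roster plus step bookkeeping for one run."""

    roster: Roster
    n_cells: int
    step_index: int = 0

    @property
    def current_slice(self) -> str:
        return slice_at(self.step_index)


def step(state: SimulationState, params: ParameterSet, rng: np.random.Generator) -> None:
    """Advance the state by one slice (in place), synchronous semantics."""
    roster = state.roster
    n = len(roster)
    if n == 0:
        state.step_index += 1
        return
    cells = roster.slice_cells(state.current_slice)
    exposure, has = cell_exposure(cells, roster.healthy, state.n_cells)
    new_opinion = update_opinion(
        roster.opinion, roster.healthy, exposure, has, params
    )
    x = switch_probability(
        roster.healthy, new_opinion, roster.habit, roster.budget, params
    )
    u = rng.random(n)
    roster.opinion = new_opinion
    roster.healthy = roster.healthy ^ (u < x)
    state.step_index += 1


def step_reference(
    state: SimulationState, params: ParameterSet, rng: np.random.Generator
) -> None:
    """Plain per-agent reference implementation of :func:`step`.

    Computes exposure, opinion and switch probability agent by agent in pure
    Python; consumes the same uniform array (one draw per agent, agent-index
    order) as the vectorised engine so trajectories are bit-identical under
    a shared seed.
    """
    roster = state.roster
    n = len(roster)
    if n == 0:
        state.step_index += 1
        return
    cells = roster.slice_cells(state.current_slice)
    ic, hdr = params.opinion_inertia, params.healthy_diet_reward
    mps, cs = params.max_proba_to_switch, params.constraint_strength

    occupants: dict[int, list[int]] = {}
    for i in range(n):
        occupants.setdefault(int(cells[i]), []).append(i)

    new_opinion = np.empty(n, float)
    probs = np.empty(n, float)
    for i in range(n):
        mates = occupants[int(cells[i])]
        others = len(mates) - 1
        o = float(roster.opinion[i])
        was_healthy = bool(roster.healthy[i])
        rewarded = min(1.0, (1.0 + hdr) * o) if was_healthy else o
        if others > 0:
            h_others = sum(
                1 for j in mates if j != i and roster.healthy[j]
            )
            exposure = h_others / others
            new_o = ic * rewarded + (1.0 - ic) * exposure
        else:
            new_o = rewarded
        new_opinion[i] = new_o
        if was_healthy:
            y = mps - (int(roster.habit[i]) - int(roster.budget[i])) * cs
            lever = -2.0 * new_o + 1.0
        else:
            y = mps - (int(roster.habit[i]) + int(roster.budget[i])) * cs
            lever = 2.0 * new_o - 1.0
        probs[i] = min(1.0, max(0.0, y * lever))

    u = rng.random(n)
    for i in range(n):
        roster.opinion[i] = new_opinion[i]
        if u[i] < probs[i]:
            roster.healthy[i] = not roster.healthy[i]
    state.step_index += 1


@dataclass
class Trajectory:
    """Per-step summaries plus the final roster.

    ``table`` is long-format with columns (step, slice, category, n,
    n_healthy, mean_opinion); category "all" rows carry the global summary.
    Step 0 rows describe the initial state; step k (k >= 1) rows describe the
    state after k slices.
    """

    table: pd.DataFrame
    final_roster: Roster

    def global_series(self, column: str = "healthy_share") -> pd.Series:
        g = self.table[self.table["category"] == "all"].set_index("step")
        if column == "healthy_share":
            return g["n_healthy"] / g["n"]
        return g[column]

    @property
    def final_healthy_share(self) -> float:
        g = self.global_series()
        return float(g.iloc[-1])


def _summarise(roster: Roster, step_index: int) -> list[dict]:
    rows = []
    n = len(roster)
    slice_name = slice_at(step_index - 1) if step_index > 0 else "initial"
    rows.append(
        {
            "step": step_index,
            "slice": slice_name,
            "category": "all",
            "n": n,
            "n_healthy": int(roster.healthy.sum()) if n else 0,
            "mean_opinion": float(roster.opinion.mean()) if n else np.nan,
        }
    )
    if n:
        totals = np.bincount(roster.category, minlength=N_CATEGORIES)
        healthy = np.bincount(
            roster.category, weights=roster.healthy.astype(float), minlength=N_CATEGORIES
        )
        op_sum = np.bincount(
            roster.category, weights=roster.opinion, minlength=N_CATEGORIES
        )
        for c in range(N_CATEGORIES):
            if totals[c] == 0:
                continue
            cat = CATEGORIES[c]
            rows.append(
                {
                    "step": step_index,
                    "slice": slice_name,
                    "category": f"{cat.sex}/{cat.age_band}/{cat.edu_level}",
                    "n": int(totals[c]),
                    "n_healthy": int(healthy[c]),
                    "mean_opinion": float(op_sum[c] / totals[c]),
                }
            )
    return rows


def run(
    state: SimulationState,
    params: ParameterSet,
    rng: np.random.Generator,
    n_days: int = 6,
    engine=step,
    record: bool = True,
) -> Trajectory:
    """Execute ``3 * n_days`` slices starting from the night slice.

    ``engine`` may be :func:`step` (vectorised, default) or
    :func:`step_reference`; both consume randomness identically.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rows = _summarise(state.roster, 0) if record else []
    for _ in range(3 * n_days):
        engine(state, params, rng)
        if record:
            rows.extend(_summarise(state.roster, state.step_index))
    if not record:
        rows = _summarise(state.roster, state.step_index)
    table = pd.DataFrame(
        rows, columns=["step", "slice", "category", "n", "n_healthy", "mean_opinion"]
    )
    return Trajectory(table=table, final_roster=state.roster)
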