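"""Scenario assembly, replication batteries, the random-mixing sweep and
bi-objective calibration.

Five spatiotemporal scenarios combine how night cells are allocated with how
agents move during the day and evening:

====  ===========  ==============================
code  night cells  daily moves (day & evening)
====  ===========  ==============================
1A    random       none (stay in the night cell)
1B    random       random
2A    observed     none
2B    observed     random
2C    observed     observed (survey-based)
====  ===========  ==============================

The mixing sweep interpolates between 2C (fraction p = 0 of random daily
moves) and 2B (p = 1). Calibration minimises (delta_health, delta_eii)
against targets built from the 2008 survey shares, on scenario 2C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dietinit, metrics, synthpop
from .core import Grid, ParameterSet, Roster
from .dynamics import SimulationState, run
from .optim import AcceptableSetResult, ParetoResult, acceptable_sets, nsga2
from .toyregion import ToyRegion, zone_cell_weights

SCENARIO_MODES = {
    "1A": ("random", "none"),
    "1B": ("random", "random"),
    "2A": ("observed", "none"),
    "2B": ("observed", "random"),
    "2C": ("observed", "observed"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    code: str
    mixing_fraction: float = 0.0  # only meaningful for the sweep on 2C

    def __post_init__(self) -> None:
        if self.code not in SCENARIO_MODES:
            raise ValueError(f"unknown scenario code {self.code!r}")
        if not 0.0 <= self.mixing_fraction <= 1.0:
            raise ValueError("mixing_fraction outside [0, 1]")

    @property
    def night_mode(self) -> str:
        return SCENARIO_MODES[self.code][0]

    @property
    def move_mode(self) -> str:
        return SCENARIO_MODES[self.code][1]


@dataclass
class PopulationInputs:
    """Everything a scenario needs: grid, zone counts, zone->cell weights and
    (for observed daily moves) trip records."""

    grid: Grid
    counts: pd.DataFrame
    zone_weights: pd.DataFrame
    trips: pd.DataFrame | None = None

    @classmethod
    def from_toy_region(cls, region: ToyRegion) -> "PopulationInputs":
        return cls(
            grid=region.grid,
            counts=region.counts,
            zone_weights=zone_cell_weights(region),
            trips=region.trips,
        )


class ScenarioEngine:
    """Builds initial simulation states for any scenario over fixed inputs.

    The presence-probability table (a deterministic function of the trip
    records) is built and interpolated once and shared across replications.
    """

    def __init__(
        self,
        inputs: PopulationInputs,
        profiles: dietinit.ProfileSet | None = None,
    ):
        self.inputs = inputs
        self.profiles = profiles or dietinit.load_default_profiles()
        self._table: synthpop.PresenceProbabilityTable | None = None

    @property
    def presence_table(self) -> synthpop.PresenceProbabilityTable:
        if self._table is None:
            if self.inputs.trips is None:
                raise ValueError(
                    "observed daily moves require trip records in the inputs"
                )
            observed = synthpop.compute_presence_probabilities(
                self.inputs.trips, self.inputs.grid
            )
            self._table = synthpop.interpolate_presence(observed)
        return self._table

    def build_allocation(
        self, scenario: ScenarioConfig, rng: np.random.Generator
    ) -> Roster:
        roster = synthpop.allocate_night_cells(
            self.inputs.counts, self.inputs.zone_weights, self.inputs.grid, rng
        )
        if scenario.night_mode == "random":
            roster = synthpop.randomize_allocation(
                roster, self.inputs.grid, "night", 1.0, rng
            )
            # agents stay put until a move mode says otherwise
            roster.day = roster.night.copy()
            roster.evening = roster.night.copy()
        if scenario.move_mode == "none":
            roster.day = roster.night.copy()
            roster.evening = roster.night.copy()
        elif scenario.move_mode == "random":
            roster.day = roster.night.copy()
            roster.evening = roster.night.copy()
            roster = synthpop.randomize_allocation(
                roster, self.inputs.grid, "day_evening", 1.0, rng
            )
        else:  # observed
            roster = synthpop.assign_slice_cells(roster, self.presence_table, rng)
            if scenario.mixing_fraction > 0:
                roster = synthpop.randomize_allocation(
                    roster,
                    self.inputs.grid,
                    "day_evening",
                    scenario.mixing_fraction,
                    rng,
                )
        return roster

    def build_state(
        self, scenario: ScenarioConfig, rng: np.random.Generator
    ) -> SimulationState:
        roster = self.build_allocation(scenario, rng)
        roster = dietinit.initialise_roster(roster, self.profiles, rng)
        n_cells = int(self.inputs.grid.populated.sum())
        return SimulationState(roster=roster, n_cells=n_cells)


@dataclass(frozen=True)
class CalibrationTarget:
    """Observed 2008 quantities: per-group healthy counts and the EII."""

    summary: pd.DataFrame  # 18 rows with expected healthy counts
    eii: float

    @classmethod
    def from_profiles(
        cls, roster: Roster, profiles: dietinit.ProfileSet
    ) -> "CalibrationTarget":
        group_n = roster.category_totals()
        p = profiles.array("p_healthy_2008")
        summary = metrics.summary_from_shares(group_n, p)
        return cls(summary=summary, eii=metrics.eii(summary))


def evaluate_final_state(
    roster: Roster, target: CalibrationTarget | None = None
) -> dict[str, float]:
    summary = metrics.population_summary(roster)
    out = {
        "healthy_share": float(roster.healthy.mean()) if len(roster) else np.nan,
        "eii": metrics.eii(summary),
        "erreygers": metrics.erreygers_for_roster(roster),
    }
    if target is not None:
        out["delta_health"] = metrics.delta_health(summary, target.summary)
        out["delta_eii"] = metrics.delta_eii(out["eii"], target.eii)
    return out


def run_replications(
    engine: ScenarioEngine,
    scenario: ScenarioConfig,
    params: ParameterSet,
    n_reps: int,
    base_seed: int,
    n_days: int = 6,
    target: CalibrationTarget | None = None,
) -> pd.DataFrame:
    """Independent seeded runs (replicate r uses seed base_seed + r); returns
    one row per replication with the final metrics."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for r in range(n_reps):
        rng = np.random.default_rng(base_seed + r)
        state = engine.build_state(scenario, rng)
        initial = evaluate_final_state(state.roster, target)
        traj = run(state, params, rng, n_days=n_days, record=False)
        final = evaluate_final_state(traj.final_roster, target)
        row = {"replication": r, "scenario": scenario.code}
        row.update({f"initial_{k}": v for k, v in initial.items()})
        row.update({f"final_{k}": v for k, v in final.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def summarise_replications(reps: pd.DataFrame) -> pd.Series:
    """Medians and quartiles of the final metrics across replications."""
    out = {}
    for col in reps.columns:
        if col.startswith(("initial_", "final_")):
            out[f"{col}_median"] = float(reps[col].median())
            out[f"{col}_q25"] = float(reps[col].quantile(0.25))
            out[f"{col}_q75"] = float(reps[col].quantile(0.75))
    return pd.Series(out)


def scenario_battery(
    engine: ScenarioEngine,
    params: ParameterSet,
    n_reps: int,
    base_seed: int,
    codes: tuple[str, ...] = ("1A", "1B", "2A", "2B", "2C"),
    n_days: int = 6,
) -> pd.DataFrame:
    """Replication batteries for several scenarios, concatenated."""
    frames = []
    for i, code in enumerate(codes):
        frames.append(
            run_replications(
                engine,
                ScenarioConfig(code),
                params,
                n_reps,
                base_seed + 100_000 * i,
                n_days=n_days,
            )
        )
    return pd.concat(frames, ignore_index=True)


def mixing_sweep(
    engine: ScenarioEngine,
    params: ParameterSet,
    p_values: tuple[float, ...],
    n_reps: int,
    base_seed: int,
    n_days: int = 6,
) -> pd.DataFrame:
    """Median final EII as a function of the fraction p of random daily
    moves applied on top of the observed allocation (p=0 is scenario 2C,
    p=1 matches 2B in distribution)."""
    rows = []
    for i, p in enumerate(p_values):
        scenario = ScenarioConfig("2C", mixing_fraction=float(p))
        reps = run_replications(
            engine, scenario, params, n_reps, base_seed + 100_000 * i, n_days=n_days
        )
        eiis = reps["final_eii"].to_numpy()
        rng = np.random.default_rng(base_seed + 7_777_777 + i)
        boot = np.median(
            rng.choice(eiis, size=(500, len(eiis)), replace=True), axis=1
        )
        rows.append(
            {
                "p": float(p),
                "median_final_eii": float(np.median(eiis)),
                "median_ci_lo": float(np.quantile(boot, 0.025)),
                "median_ci_hi": float(np.quantile(boot, 0.975)),
                "median_final_healthy_share": float(
                    reps["final_healthy_share"].median()
                ),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


# genotype box: (HDR, IC, MPS, CS as a fraction of MPS) — the last coordinate
# keeps the coupled constraint CS <= MPS satisfied for any point in the box
GENOTYPE_BOUNDS = np.array([[0.0, 1.0]] * 4)


def decode_genotype(x: np.ndarray) -> ParameterSet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ParameterSet(
            healthy_diet_reward=float(x[0]),
            opinion_inertia=float(x[1]),
            max_proba_to_switch=float(x[2]),
            constraint_strength=float(x[2] * x[3]),
        )


def make_objective(
    engine: ScenarioEngine,
    target: CalibrationTarget,
    n_reps_per_eval: int = 3,
    base_seed: int = 0,
    n_days: int = 6,
    scenario: ScenarioConfig = ScenarioConfig("2C"),
):
    """(delta_health, delta_eii) averaged over seeded replicate runs."""

    def objective(x: np.ndarray) -> np.ndarray:
        params = decode_genotype(x)
        reps = run_replications(
            engine,
            scenario,
            params,
            n_reps_per_eval,
            base_seed,
            n_days=n_days,
            target=target,
        )
        return np.array(
            [reps["final_delta_health"].mean(), reps["final_delta_eii"].mean()]
        )

    return objective


def calibrate_nsga2(
    engine: ScenarioEngine,
    target: CalibrationTarget,
    pop_size: int = 24,
    generations: int = 20,
    n_reps_per_eval: int = 3,
    seed: int = 0,
    n_days: int = 6,
) -> ParetoResult:
    """NSGA-II bi-objective calibration of the four free parameters on the
    observed-mobility scenario."""
    rng = np.random.default_rng(seed)
    objective = make_objective(
        engine, target, n_reps_per_eval=n_reps_per_eval, base_seed=seed, n_days=n_days
    )
    return nsga2(
        objective,
        GENOTYPE_BOUNDS,
        pop_size=pop_size,
        generations=generations,
        rng=rng,
    )


def calibrate_acceptable_sets(
    engine: ScenarioEngine,
    target: CalibrationTarget,
    delta_health_max: float,
    delta_eii_max: float,
    budget: int = 200,
    n_sets: int = 5,
    n_reps_per_eval: int = 3,
    seed: int = 0,
    n_days: int = 6,
) -> AcceptableSetResult:
    """Diverse parameter sets meeting good-enough fitness thresholds
    (simplified stand-in for OSE; see :mod:`fiveaday.optim`)."""
    rng = np.random.default_rng(seed)
    objective = make_objective(
        engine, target, n_reps_per_eval=n_reps_per_eval, base_seed=seed, n_days=n_days
    )
    return acceptable_sets(
        objective,
        GENOTYPE_BOUNDS,
        thresholds=np.array([delta_health_max, delta_eii_max]),
        budget=budget,
        n_sets=n_sets,
        rng=rng,
    )
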