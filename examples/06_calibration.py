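"""Bi-objective calibration demo: NSGA-II minimises the distance to the
2008 survey targets (healthy counts per group, EII) on a small toy region,
then a simplified diverse acceptable-set search (a stand-in for OSE, not
equivalent to it) looks for maximally different parameter sets that are all
good enough."""

import warnings

import numpy as np

import fiveaday as fd
from fiveaday import experiments as ex

warnings.filterwarnings("ignore", category=UserWarning)

region = fd.generate_region(fd.ToyRegionSpec(width=10, height=10, n_agents=3000, seed=5))
engine = ex.ScenarioEngine(ex.PopulationInputs.from_toy_region(region))

rng = np.random.default_rng(5)
roster = engine.build_state(ex.ScenarioConfig("2C"), rng).roster
target = ex.CalibrationTarget.from_profiles(roster, engine.profiles)
print(f"targets: EII={target.eii:.3f}, healthy counts per 18 groups")

front = ex.calibrate_nsga2(
    engine, target, pop_size=10, generations=5, n_reps_per_eval=2, seed=5
)
print(f"NSGA-II: {len(front.decisions)} non-dominated sets "
      f"after {front.n_evaluations} evaluations")
for x, f in zip(front.decisions, front.objectives):
    print(f"  HDR={x[0]:.2f} IC={x[1]:.2f} MPS={x[2]:.2f} CS={x[2]*x[3]:.2f} "
          f"-> dHealth={f[0]:.0f} agents, dEII={f[1]:.3f}")

best_h = front.objectives[:, 0].min()
acc = ex.calibrate_acceptable_sets(
    engine, target, delta_health_max=2.0 * best_h, delta_eii_max=0.5,
    budget=60, n_sets=3, n_reps_per_eval=1, seed=6,
)
print(f"acceptable-set search (simplified, not OSE): {acc.diagnostic}")
for x, f in zip(acc.decisions, acc.objectives):
    print(f"  HDR={x[0]:.2f} IC={x[1]:.2f} MPS={x[2]:.2f} CS={x[2]*x[3]:.2f} "
          f"-> dHealth={f[0]:.0f}, dEII={f[1]:.3f}")
# dHealth counts misclassified agents out of 3000; dEII is the absolute gap
# to the target inequality index.
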