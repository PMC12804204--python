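"""Sensitivity of final inequality to the fraction of random daily moves,
from fully observed mobility (p=0, scenario 2C) to fully random (p=1, 2B)."""

import warnings

import fiveaday as fd
from fiveaday import experiments as ex

warnings.filterwarnings("ignore", category=UserWarning)

region = fd.generate_region(fd.ToyRegionSpec(seed=7))
engine = ex.ScenarioEngine(ex.PopulationInputs.from_toy_region(region))

sweep = ex.mixing_sweep(
    engine, fd.CALIBRATED_PARAMS, p_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_reps=60, base_seed=7,
)
print(sweep.round(3).to_string(index=False))
# Median EII decreases as daily moves are randomised: a modest share of
# random mixing already erodes the inequality that daytime segregation
# sustains. The bootstrap CI columns quantify the Monte-Carlo error on each
# median.
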