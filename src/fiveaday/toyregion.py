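"""Synthetic toy regions with the statistical structure of a large
metropolitan input: a spatial education gradient (residential segregation),
distance-decay daily mobility toward activity hubs, and category-dependent
mobility propensities.

The generator emits exactly the inputs the population builder consumes
(grid, zone counts with zones coinciding with cells, trip records), so the
whole pipeline is exercisable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CATEGORIES, Grid

#: marginal shares of age bands among 15-75 year olds (large-city order of
#: magnitude: a wide working-age band dominates)
AGE_SHARES = {"15-29": 0.28, "30-59": 0.55, "60-75": 0.17}
EDU_SHARES = {"low": 0.40, "middle": 0.30, "high": 0.30}


@dataclass(frozen=True)
class ToyRegionSpec:
    """Specification of a synthetic region.

    education_segregation s in [0, 1] mixes a uniform residential
    distribution (s = 0) with fully sorted education bands along the x axis
    (s = 1: low-educated in the left third, middle in the centre, high in
    the right third), so s directly controls night-time Duncan segregation.
    """

    width: int = 15
    height: int = 15
    n_agents: int = 10_000
    education_segregation: float = 0.8
    n_hubs: int = 4
    hub_attraction: float = 1.0
    distance_decay: float = 0.35
    respondents_per_group_cell: int = 1
    seed: int = 0
    #: base probability of leaving home during the day; multipliers make the
    #: highly educated and the middle age band more mobile, mirroring survey
    #: mobility gradients
    base_mobility: float = 0.75
    edu_mobility: dict = field(
        default_factory=lambda: {"low": 0.85, "middle": 1.0, "high": 1.15}
    )

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.education_segregation <= 1.0:
            raise ValueError("education_segregation outside [0, 1]")


@dataclass
class ToyRegion:
    grid: Grid
    counts: pd.DataFrame  # (zone, sex, age_band, edu_level, count)
    trips: pd.DataFrame  # synthpop trip-record schema
    spec: ToyRegionSpec


def _edu_cell_weights(grid: Grid, s: float) -> dict[str, np.ndarray]:
    """Residential cell weights per education level: (1-s) * uniform +
    s * band indicator along x (low left, middle centre, high right)."""
    coords = grid.populated_coords()
    u = coords[:, 0] / max(coords[:, 0].max(), 1)
    n = len(coords)
    bands = {
        "low": (u < 1 / 3),
        "middle": (u >= 1 / 3) & (u < 2 / 3),
        "high": (u >= 2 / 3),
    }
    out = {}
    for edu, band in bands.items():
        w = (1.0 - s) / n + s * band / band.sum()
        out[edu] = w / w.sum()
    return out


def _mobility(spec: ToyRegionSpec, sex: str, age_band: str, edu: str) -> float:
    m = spec.base_mobility * spec.edu_mobility[edu]
    m *= 1.05 if sex == "male" else 0.95
    m *= {"15-29": 1.0, "30-59": 1.05, "60-75": 0.7}[age_band]
    return min(m, 1.0)


def generate_region(spec: ToyRegionSpec) -> ToyRegion:
    """Build grid, zone counts and trip records; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    grid = Grid.regular(spec.width, spec.height)
    pop_ids = grid.populated_ids
    coords = grid.populated_coords().astype(float)
    n_cells = len(pop_ids)
    s = spec.education_segregation
    edu_w = _edu_cell_weights(grid, s)

    # --- zone counts: zones coincide with cells (weight 1) ------------------
    rows = []
    cell_counts = {}
    for cat in CATEGORIES:
        share = 0.5 * AGE_SHARES[cat.age_band] * EDU_SHARES[cat.edu_level]
        total = int(round(spec.n_agents * share))
        alloc = rng.multinomial(total, edu_w[cat.edu_level])
        cell_counts[cat] = alloc
        for cell_i in np.flatnonzero(alloc):
            rows.append(
                {
                    "zone": int(pop_ids[cell_i]),
                    "sex": cat.sex,
                    "age_band": cat.age_band,
                    "edu_level": cat.edu_level,
                    "count": int(alloc[cell_i]),
                }
            )
    counts = pd.DataFrame(rows)

    # --- daily mobility: hubs with distance decay ---------------------------
    hubs = rng.choice(n_cells, size=min(spec.n_hubs, n_cells), replace=False)
    trip_rows = []
    rid = 0
    for cat in CATEGORIES:
        mob = _mobility(spec, cat.sex, cat.age_band, cat.edu_level)
        for cell_i in np.flatnonzero(cell_counts[cat]):
            for _ in range(spec.respondents_per_group_cell):
                home = int(pop_ids[cell_i])
                # day destination: a hub with distance-decayed attraction,
                # or stay home with probability 1 - mobility
                if rng.random() < mob and spec.hub_attraction > 0:
                    d = np.hypot(*(coords[hubs] - coords[cell_i]).T)
                    w = spec.hub_attraction * np.exp(-spec.distance_decay * d)
                    w = w / w.sum()
                    day_cell = int(pop_ids[hubs[rng.choice(len(hubs), p=w)]])
                else:
                    day_cell = home
                # evening: half the movers are still out, the rest back home
                evening_cell = day_cell if rng.random() < 0.5 * mob else home
                trip_rows.append(
                    {
                        "respondent_id": rid,
                        "sex": cat.sex,
                        "age_band": cat.age_band,
                        "edu_level": cat.edu_level,
                        "night_cell": home,
                        "stay_cell": day_cell,
                        "start_min": 480,
                        "end_min": 960,
                    }
                )
                trip_rows.append(
                    {
                        "respondent_id": rid,
                        "sex": cat.sex,
                        "age_band": cat.age_band,
                        "edu_level": cat.edu_level,
                        "night_cell": home,
                        "stay_cell": evening_cell,
                        "start_min": 960,
                        "end_min": 1440,
                    }
                )
                rid += 1
    trips = pd.DataFrame(trip_rows)
    return ToyRegion(grid=grid, counts=counts, trips=trips, spec=spec)


def zone_cell_weights(region: ToyRegion) -> pd.DataFrame:
    """Trivial zone -> cell weights (zones are cells, weight 1)."""
    ids = region.grid.populated_ids
    return pd.DataFrame({"zone": ids, "cell_id": ids, "weight": 1.0})


def degrade_trips(
    trips: pd.DataFrame, keep_fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomly drop respondents to exercise the interpolation and fallback
    chain; keep_fraction = 1 returns the input unchanged, 0 removes all."""
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction outside [0, 1]")
    if keep_fraction == 1.0:
        return trips
    respondents = trips["respondent_id"].unique()
    kept = respondents[rng.random(len(respondents)) < keep_fraction]
    return trips[trips["respondent_id"].isin(kept)].reset_index(drop=True)
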