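"""Around-the-clock synthetic population builder.

Builds agent locations for the three daily time slices from (i) zone-level
counts of residents per sociodemographic category and (ii) origin-destination
trip records, following a three-step procedure:

1. night cells: agents are created from zone counts and each is assigned a
   night cell drawn from its zone's cell-weight distribution (at toy scale
   zones coincide with cells, weight 1);
2. presence probabilities: for every (category, night cell, slice) the
   probability of being in a destination cell is the share of cumulative
   respondent-minutes spent there during the slice, spatially interpolated
   from nearest-neighbour night cells where the survey has no coverage;
3. day/evening cells are drawn from those probabilities, falling back to the
   opposite-sex distribution and finally to immobility (day = evening =
   night) so the assignment is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    DAY_END,
    DAY_START,
    EVENING_END,
    N_CATEGORIES,
    PROV_CODE,
    Grid,
    Roster,
    category_of,
    opposite_sex_category,
)

logger = logging.getLogger(__name__)

MOVING_SLICES = ("day", "evening")


@dataclass
class PresenceProbabilityTable:
    """Per (category code, night dense-cell index, slice) destination law.

    Each entry is a pair of aligned arrays (dense destination cell indices,
    probabilities summing to 1) plus a provenance tag.
    """

    grid: Grid
    entries: dict[tuple[int, int, str], tuple[np.ndarray, np.ndarray, str]] = field(
        default_factory=dict
    )

    def get(self, cat: int, night: int, slice_name: str):
        return self.entries.get((cat, night, slice_name))

    def validate(self) -> None:
        pop_n = int(self.grid.populated.sum())
        for key, (cells, probs, prov) in self.entries.items():
            if np.any(probs < 0):
                raise ValueError(f"negative probability in entry {key}")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"distribution for {key} sums to {probs.sum()}")
            if np.any(cells < 0) or np.any(cells >= pop_n):
                raise ValueError(f"unpopulated destination in entry {key}")

    def provenance_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, prov in self.entries.values():
            out[prov] = out.get(prov, 0) + 1
        return out


def allocate_night_cells(
    counts: pd.DataFrame,
    zone_cell_weights: pd.DataFrame,
    grid: Grid,
    rng: np.random.Generator,
) -> Roster:
    """Create the agent roster and draw a night cell for every agent.

    Parameters
    ----------
    counts
        Columns (zone, sex, age_band, edu_level, count): residents per zone
        and category.
    zone_cell_weights
        Columns (zone, cell_id, weight): relative weight of each populated
        grid cell intersecting the zone.
    """
    if (counts["count"] < 0).any():
        bad = counts.loc[counts["count"] < 0].iloc[0]
        raise ValueError(f"negative count for zone {bad['zone']}")
    id2dense = grid.id_to_dense()

    # per-zone normalised weight distributions over dense cell indices
    zone_dists: dict = {}
    for zone, g in zone_cell_weights.groupby("zone"):
        w = g["weight"].to_numpy(float)
        if (w < 0).any():
            raise ValueError(f"negative cell weight in zone {zone}")
        total = w.sum()
        if total <= 0:
            raise ValueError(f"zone {zone} has all-zero cell weights")
        try:
            cells = np.array([id2dense[int(c)] for c in g["cell_id"]])
        except KeyError as exc:
            raise ValueError(f"zone {zone} references unpopulated cell {exc}") from exc
        zone_dists[zone] = (cells, w / total)

    cat_parts: list[np.ndarray] = []
    night_parts: list[np.ndarray] = []
    # note: "count" clashes with namedtuple attributes, so iterate columns
    cols = zip(
        counts["zone"],
        counts["sex"],
        counts["age_band"],
        counts["edu_level"],
        counts["count"],
    )
    for zone, sex, age_band, edu_level, n in cols:
        n = int(n)
        if n == 0:
            continue
        if zone not in zone_dists:
            raise ValueError(f"zone {zone} has no cell weights")
        cells, probs = zone_dists[zone]
        cat_parts.append(np.full(n, category_of(sex, age_band, edu_level), np.int8))
        night_parts.append(rng.choice(cells, size=n, p=probs))

    if cat_parts:
        category = np.concatenate(cat_parts)
        night = np.concatenate(night_parts).astype(np.int64)
    else:
        category = np.empty(0, np.int8)
        night = np.empty(0, np.int64)
    immobile = np.full(len(category), PROV_CODE["immobile"], np.int8)
    return Roster(
        category=category,
        night=night,
        day=night.copy(),
        evening=night.copy(),
        day_prov=immobile,
        evening_prov=immobile.copy(),
    )


def _slice_of(start: int, end: int) -> str | None:
    """Slice containing [start, end), or None for night; errors on crossing."""
    if not (0 <= start < end <= EVENING_END):
        raise ValueError(f"stay [{start}, {end}) outside [0, 1440]")
    for lo, hi, name in (
        (0, DAY_START, None),
        (DAY_START, DAY_END, "day"),
        (DAY_END, EVENING_END, "evening"),
    ):
        if lo <= start < hi:
            if end > hi:
                raise ValueError(
                    f"stay [{start}, {end}) crosses a slice boundary; "
                    "pre-split stays at slice boundaries"
                )
            return name
    raise AssertionError("unreachable")


def split_stays_at_boundaries(trips: pd.DataFrame) -> pd.DataFrame:
    """Split stay rows so that none crosses a slice boundary (reader helper)."""
    bounds = (0, DAY_START, DAY_END, EVENING_END)
    rows = []
    for row in trips.itertuples(index=False):
        s, e = int(row.start_min), int(row.end_min)
        cuts = [s] + [b for b in bounds if s < b < e] + [e]
        for a, b in zip(cuts[:-1], cuts[1:]):
            d = row._asdict()
            d["start_min"], d["end_min"] = a, b
            rows.append(d)
    return pd.DataFrame(rows, columns=trips.columns)


def compute_presence_probabilities(
    trips: pd.DataFrame, grid: Grid
) -> PresenceProbabilityTable:
    """Cumulative-time destination probabilities per (category, night cell, slice).

    ``trips`` has columns (respondent_id, sex, age_band, edu_level, night_cell,
    stay_cell, start_min, end_min); each row is one stay, already split at
    slice boundaries, times in minutes from 00:00. Stays during the night
    slice are ignored (the night cell is the home cell by construction).
    """
    id2dense = grid.id_to_dense()
    minutes: dict[tuple[int, int, str], dict[int, int]] = {}
    for row in trips.itertuples(index=False):
        slice_name = _slice_of(int(row.start_min), int(row.end_min))
        if slice_name is None:
            continue
        try:
            night = id2dense[int(row.night_cell)]
            dest = id2dense[int(row.stay_cell)]
        except KeyError as exc:
            raise ValueError(f"stay references unknown/unpopulated cell {exc}") from exc
        cat = category_of(row.sex, row.age_band, row.edu_level)
        key = (cat, night, slice_name)
        cell_minutes = minutes.setdefault(key, {})
        cell_minutes[dest] = cell_minutes.get(dest, 0) + (
            int(row.end_min) - int(row.start_min)
        )

    table = PresenceProbabilityTable(grid=grid)
    for key, cell_minutes in minutes.items():
        cells = np.array(sorted(cell_minutes), np.int64)
        mins = np.array([cell_minutes[c] for c in cells], float)
        table.entries[key] = (cells, mins / mins.sum(), "observed")
    table.validate()
    return table


def interpolate_presence(table: PresenceProbabilityTable) -> PresenceProbabilityTable:
    """Fill missing (category, night cell, slice) entries from the nearest
    observed night cell of the same category and slice.

    Distance is Euclidean between populated-cell centroids; ties break on the
    smaller cell_id. Observed entries are never modified. Categories/slices
    with no observed donor anywhere are left missing (handled downstream by
    the fallback chain).
    """
    grid = table.grid
    coords = grid.populated_coords().astype(float)
    pop_ids = grid.populated_ids
    n_pop = len(pop_ids)
    out = PresenceProbabilityTable(grid=grid, entries=dict(table.entries))

    for cat in range(N_CATEGORIES):
        for slice_name in MOVING_SLICES:
            donors = [
                night
                for (c, night, s), (_, _, prov) in table.entries.items()
                if c == cat and s == slice_name and prov == "observed"
            ]
            if not donors:
                continue
            donors = np.array(sorted(donors))
            for night in range(n_pop):
                if (cat, night, slice_name) in out.entries:
                    continue
                d2 = np.sum((coords[donors] - coords[night]) ** 2, axis=1)
                best = d2.min()
                # tie-break: smallest cell_id among donors at minimal distance
                tied = donors[d2 == best]
                donor = int(tied[np.argmin(pop_ids[tied])])
                cells, probs, _ = table.entries[(cat, donor, slice_name)]
                out.entries[(cat, night, slice_name)] = (
                    cells,
                    probs,
                    "interpolated",
                )
    return out


def _draw_group(
    cells: np.ndarray, probs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return cells[np.searchsorted(cum, rng.random(n), side="right")]


def assign_slice_cells(
    roster: Roster,
    table: PresenceProbabilityTable,
    rng: np.random.Generator,
) -> Roster:
    """Draw day and evening cells for every agent (total fallback chain).

    Per agent: use the (category, night cell) entry if present; otherwise the
    opposite-sex entry with the same age, education and night cell; otherwise
    the agent is immobile in that slice (cell = night cell).
    """
    out = roster.copy()
    order = np.lexsort((out.night, out.category))
    for slice_name in MOVING_SLICES:
        dest = out.night.copy()
        prov = np.full(len(out), PROV_CODE["immobile"], np.int8)
        # group agents by (category, night cell) via the sorted order
        keys = out.category[order].astype(np.int64) * (out.night.max() + 1 if len(out) else 1) + out.night[order]
        starts = np.flatnonzero(np.r_[True, np.diff(keys) != 0]) if len(out) else []
        bounds = list(starts) + [len(out)]
        for i in range(len(bounds) - 1):
            idx = order[bounds[i] : bounds[i + 1]]
            cat = int(out.category[idx[0]])
            night = int(out.night[idx[0]])
            entry = table.get(cat, night, slice_name)
            if entry is not None:
                cells, probs, entry_prov = entry
                dest[idx] = _draw_group(cells, probs, len(idx), rng)
                prov[idx] = PROV_CODE[entry_prov]
                continue
            entry = table.get(opposite_sex_category(cat), night, slice_name)
            if entry is not None:
                cells, probs, _ = entry
                dest[idx] = _draw_group(cells, probs, len(idx), rng)
                prov[idx] = PROV_CODE["opposite_sex_fallback"]
            # else: immobile (already night cell)
        if slice_name == "day":
            out.day, out.day_prov = dest, prov
        else:
            out.evening, out.evening_prov = dest, prov
    return out


def randomize_allocation(
    roster: Roster,
    grid: Grid,
    which: str,
    fraction: float,
    rng: np.random.Generator,
) -> Roster:
    """Replace slice cells of a Bernoulli(fraction) subset of agents by
    uniform draws over populated cells.

    ``which`` is "night" (re-draw night cells; category totals are untouched
    by construction) or "day_evening" (independent uniform day and evening
    cells, provenance unchanged to keep the survey bookkeeping meaning).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction={fraction} outside [0, 1]")
    if which not in ("night", "day_evening"):
        raise ValueError(f"which={which!r} must be 'night' or 'day_evening'")
    n_pop = int(grid.populated.sum())
    if n_pop == 0:
        raise ValueError("grid has no populated cells")
    out = roster.copy()
    n = len(out)
    if n == 0:
        return out
    chosen = (
        np.ones(n, bool) if fraction >= 1.0 else rng.random(n) < fraction
    )
    k = int(chosen.sum())
    if k == 0:
        return out
    if which == "night":
        out.night[chosen] = rng.integers(0, n_pop, size=k)
    else:
        out.day[chosen] = rng.integers(0, n_pop, size=k)
        out.evening[chosen] = rng.integers(0, n_pop, size=k)
    return out


def provenance_shares(roster: Roster) -> pd.DataFrame:
    """Share of agents per provenance for the day and evening assignments."""
    rows = []
    for slice_name, codes in (
        ("day", roster.day_prov),
        ("evening", roster.evening_prov),
    ):
        counts = np.bincount(codes, minlength=len(PROV_CODE))
        for prov, code in PROV_CODE.items():
            rows.append(
                {
                    "slice": slice_name,
                    "provenance": prov,
                    "share": counts[code] / max(len(roster), 1),
                }
            )
    return pd.DataFrame(rows)
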