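"""Inequality and segregation statistics.

* EII — education inequality index: population-weighted sum over sex x age
  strata of the ratio of healthy shares between the most and least educated
  groups; 1 means no education gradient, > 1 means the highly educated are
  systematically healthier.
* delta_health / delta_eii — the two calibration distances (absolute
  differences in per-group healthy counts, and in EII).
* Duncan dissimilarity — half the summed absolute difference between a
  group's and its complement's spatial shares, per time slice.
* Moran's I — global spatial autocorrelation of a per-cell field on the grid
  (queen contiguity, row-standardised, by default).
* Erreygers corrected concentration index — rank-ordered (by education)
  inequality of a binary outcome, in [-1, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    AGE_BANDS,
    CATEGORIES,
    EDU_RANK,
    N_CATEGORIES,
    SEXES,
    Grid,
    Roster,
)


def population_summary(roster: Roster) -> pd.DataFrame:
    """Per-category N and N_healthy, in canonical category order."""
    totals = roster.category_totals()
    healthy = (
        np.bincount(
            roster.category,
            weights=roster.healthy.astype(float),
            minlength=N_CATEGORIES,
        ).astype(int)
        if len(roster)
        else np.zeros(N_CATEGORIES, int)
    )
    return pd.DataFrame(
        {
            "sex": [c.sex for c in CATEGORIES],
            "age_band": [c.age_band for c in CATEGORIES],
            "edu_level": [c.edu_level for c in CATEGORIES],
            "n": totals,
            "n_healthy": healthy,
        }
    )


def summary_from_shares(
    group_n: np.ndarray, p_healthy: np.ndarray
) -> pd.DataFrame:
    """Summary with expected healthy counts n * p per category (targets)."""
    return pd.DataFrame(
        {
            "sex": [c.sex for c in CATEGORIES],
            "age_band": [c.age_band for c in CATEGORIES],
            "edu_level": [c.edu_level for c in CATEGORIES],
            "n": group_n,
            "n_healthy": group_n * p_healthy,
        }
    )


def eii(summary: pd.DataFrame) -> float:
    """Education inequality index over the six sex x age strata.

    A zero healthy share in the low- (or high-) education group of a stratum
    triggers a continuity correction (+0.5 healthy in both education groups
    of the stratum), with a warning; a stratum with an empty education group
    is skipped and the stratum weights renormalised, with a warning.
    """
    s = summary.set_index(["sex", "age_band", "edu_level"])
    total_n = float(summary["n"].sum())
    if total_n == 0:
        raise ValueError("empty population summary")
    terms: list[tuple[float, float]] = []  # (ratio, stratum weight)
    for sex in SEXES:
        for age in AGE_BANDS:
            n_low = float(s.loc[(sex, age, "low"), "n"])
            n_high = float(s.loc[(sex, age, "high"), "n"])
            stratum_n = float(
                sum(s.loc[(sex, age, e), "n"] for e in ("low", "middle", "high"))
            )
            if n_low == 0 or n_high == 0:
                warnings.warn(
                    f"stratum {sex}/{age} has an empty education group; "
                    "skipped and weights renormalised",
                    stacklevel=2,
                )
                continue
            h_low = float(s.loc[(sex, age, "low"), "n_healthy"])
            h_high = float(s.loc[(sex, age, "high"), "n_healthy"])
            if h_low == 0 or h_high == 0:
                warnings.warn(
                    f"zero healthy share in stratum {sex}/{age}; "
                    "continuity correction (+0.5) applied",
                    stacklevel=2,
                )
                h_low += 0.5
                h_high += 0.5
            ratio = (h_high / n_high) / (h_low / n_low)
            terms.append((ratio, stratum_n))
    if not terms:
        raise ValueError("no stratum with both education groups present")
    # stratum weights N_{sex,age}/N; renormalised over retained strata
    weights = np.array([w for _, w in terms])
    weights = weights / weights.sum()
    ratios = np.array([r for r, _ in terms])
    return float((ratios * weights).sum())


def delta_health(sim_summary: pd.DataFrame, target_summary: pd.DataFrame) -> float:
    """Sum over the 18 groups of |simulated - observed healthy counts|."""
    key = ["sex", "age_band", "edu_level"]
    a = sim_summary.set_index(key).sort_index()
    b = target_summary.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("summaries cover different groups")
    return float(np.abs(a["n_healthy"].to_numpy() - b["n_healthy"].to_numpy()).sum())


def delta_eii(sim_eii: float, obs_eii: float) -> float:
    """Absolute difference between simulated and observed EII."""
    if not (np.isfinite(sim_eii) and np.isfinite(obs_eii)):
        raise ValueError("EII values must be finite")
    return float(abs(sim_eii - obs_eii))


def duncan(group_counts: np.ndarray, rest_counts: np.ndarray) -> float:
    """Duncan dissimilarity between a group and its complement across cells."""
    g = np.asarray(group_counts, float)
    r = np.asarray(rest_counts, float)
    if g.shape != r.shape:
        raise ValueError("count vectors must have equal length")
    if g.sum() <= 0 or r.sum() <= 0:
        raise ValueError("both the group and its complement must be non-empty")
    return float(0.5 * np.abs(g / g.sum() - r / r.sum()).sum())


def duncan_for_roster(
    roster: Roster, grid: Grid, group_mask: np.ndarray, slice_name: str
) -> float:
    """Duncan index of a subgroup vs the rest, on one time slice's cells."""
    cells = roster.slice_cells(slice_name)
    n_pop = int(grid.populated.sum())
    g = np.bincount(cells[group_mask], minlength=n_pop)
    r = np.bincount(cells[~group_mask], minlength=n_pop)
    return duncan(g, r)


def grid_weights(
    grid: Grid, scheme: str = "queen", distance_band: float | None = None
) -> list[np.ndarray]:
    """Row-standardised neighbour weights over populated cells.

    Returns, per populated cell, an (k, 2) array-like pair (neighbour
    indices, weights). Schemes: "queen" (8 adjacent cells), "rook" (4), or
    "distance" (centroid distance <= distance_band).
    """
    coords = grid.populated_coords().astype(float)
    n = len(coords)
    neighbours: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        d = coords - coords[i]
        if scheme == "queen":
            mask = (np.abs(d[:, 0]) <= 1) & (np.abs(d[:, 1]) <= 1)
        elif scheme == "rook":
            mask = np.abs(d[:, 0]) + np.abs(d[:, 1]) == 1
        elif scheme == "distance":
            if distance_band is None:
                raise ValueError("distance scheme needs distance_band")
            mask = np.hypot(d[:, 0], d[:, 1]) <= distance_band
        else:
            raise ValueError(f"unknown weight scheme {scheme!r}")
        mask[i] = False  # no self-weight
        idx = np.flatnonzero(mask)
        w = (
            np.full(len(idx), 1.0 / len(idx))
            if len(idx)
            else np.empty(0, float)
        )
        neighbours.append((idx, w))
    return neighbours


def morans_i(
    values: np.ndarray,
    grid: Grid,
    scheme: str = "queen",
    distance_band: float | None = None,
) -> float:
    """Global Moran's I of a per-populated-cell field.

    Standard statistic I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with
    row-standardised weights (S0 = number of cells with neighbours). Null
    expectation under random permutation is -1/(n-1).
    """
    z = np.asarray(values, float)
    n = len(z)
    if n < 2:
        raise ValueError("need at least 2 cells")
    z = z - z.mean()
    denom = float((z**2).sum())
    if denom == 0:
        raise ValueError("zero variance field: Moran's I undefined")
    neighbours = grid_weights(grid, scheme, distance_band)
    num = 0.0
    s0 = 0.0
    for i, (idx, w) in enumerate(neighbours):
        if len(idx) == 0:
            continue
        num += z[i] * float((w * z[idx]).sum())
        s0 += float(w.sum())
    return float(n / s0 * num / denom)


def fractional_ranks(rank_values: np.ndarray) -> np.ndarray:
    """Weighted fractional ranks in (0, 1), ties receiving the average rank."""
    x = np.asarray(rank_values)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, float)
    pos = 0
    sorted_x = x[order]
    while pos < n:
        end = pos
        while end < n and sorted_x[end] == sorted_x[pos]:
            end += 1
        # average of positions pos..end-1 (1-based), scaled to (0, 1)
        avg = (pos + end + 1) / 2.0  # mean of (pos+1) .. end
        ranks[order[pos:end]] = (avg - 0.5) / n
        pos = end
    return ranks


def erreygers(outcomes: np.ndarray, edu_ranks: np.ndarray) -> float:
    """Erreygers corrected concentration index of a binary outcome ranked by
    an ordinal education variable (low < middle < high; any ordinal coding,
    or the level names themselves, is accepted).

    E = 4 * mu * C with C the fractional-rank concentration index (ties get
    the average fractional rank); E in [-1, 1], 0 when the outcome is
    independent of education rank, positive when concentrated among the more
    educated.
    """
    y = np.asarray(outcomes, float)
    ranks_src = np.asarray(edu_ranks)
    if ranks_src.dtype.kind in "UOS":
        ranks_src = np.array([EDU_RANK[e] for e in ranks_src])
    if len(np.unique(ranks_src)) < 2:
        raise ValueError("need at least two education levels for a ranking")
    mu = y.mean()
    if mu == 0 or mu == 1:
        return 0.0
    r = fractional_ranks(ranks_src)
    c = 2.0 * np.mean((y - mu) * (r - r.mean())) / mu
    return float(4.0 * mu * c)


#: per-category education rank, aligned with the canonical category order
_CAT_EDU_RANK = np.array([EDU_RANK[c.edu_level] for c in CATEGORIES])


def erreygers_for_roster(roster: Roster) -> float:
    return erreygers(roster.healthy.astype(float), _CAT_EDU_RANK[roster.category])
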