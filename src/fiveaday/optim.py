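"""Multi-objective search utilities.

``nsga2`` is a compact real-coded NSGA-II (fast non-dominated sorting,
crowding distance, binary tournament, simulated-binary crossover and
polynomial mutation) for minimising a vector objective over a box.

``acceptable_sets`` is a deliberately simplified diverse-acceptable-set
search: rejection-filtered Latin-hypercube sampling plus local refinement,
returning parameter vectors that meet fitness thresholds while maximising
their minimum pairwise distance in normalised space. It is NOT equivalent to
the OSE (origin-space exploration) algorithm with adaptive rejection zones;
it only plays the same role at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for minimisation."""
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    """Fronts of indices, best first (Deb's fast non-dominated sort)."""
    n = len(objs)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.flatnonzero(dom_count == 0)
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(nxt, int)
    return fronts


def crowding_distance(objs: np.ndarray) -> np.ndarray:
    n, m = objs.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = objs[order[-1], k] - objs[order[0], k]
        if span <= 0 or n < 3:
            continue
        dist[order[1:-1]] += (objs[order[2:], k] - objs[order[:-2], k]) / span
    return dist


def _sbx(p1, p2, rng, eta=15.0):
    u = rng.random(len(p1))
    beta = np.where(
        u <= 0.5,
        (2 * u) ** (1 / (eta + 1)),
        (1 / (2 * (1 - u))) ** (1 / (eta + 1)),
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return c1, c2


def _poly_mutation(x, rng, eta=20.0, pm=None):
    d = len(x)
    pm = 1.0 / d if pm is None else pm
    y = x.copy()
    for i in range(d):
        if rng.random() < pm:
            u = rng.random()
            delta = (
                (2 * u) ** (1 / (eta + 1)) - 1
                if u < 0.5
                else 1 - (2 * (1 - u)) ** (1 / (eta + 1))
            )
            y[i] += delta
    return y


@dataclass
class ParetoResult:
    """Final non-dominated set: decision vectors (in original units) and
    objective values, plus the full evaluated archive."""

    decisions: np.ndarray  # (k, d)
    objectives: np.ndarray  # (k, m)
    n_evaluations: int


def nsga2(
    objective,
    bounds: np.ndarray,
    pop_size: int = 24,
    generations: int = 20,
    rng: np.random.Generator | None = None,
) -> ParetoResult:
    """Minimise a vector objective(x) -> array of shape (m,) over the box
    ``bounds`` of shape (d, 2). generations=0 evaluates the initial
    population only."""
    rng = np.random.default_rng() if rng is None else rng
    bounds = np.asarray(bounds, float)
    if np.any(bounds[:, 1] < bounds[:, 0]):
        raise ValueError("infeasible bounds: upper < lower")
    d = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]

    def evaluate(pop01: np.ndarray) -> np.ndarray:
        return np.array([objective(lo + x * (hi - lo)) for x in pop01])

    pop = rng.random((pop_size, d))
    objs = evaluate(pop)
    n_eval = pop_size

    for _ in range(generations):
        # binary tournament on (rank, crowding)
        fronts = non_dominated_sort(objs)
        rank = np.empty(pop_size, int)
        for fi, front in enumerate(fronts):
            rank[front] = fi
        crowd = np.zeros(pop_size)
        for front in fronts:
            crowd[front] = crowding_distance(objs[front])

        def better(i, j):
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < pop_size:
            cand = rng.integers(0, pop_size, size=4)
            p1 = pop[better(cand[0], cand[1])]
            p2 = pop[better(cand[2], cand[3])]
            c1, c2 = _sbx(p1, p2, rng)
            children.append(np.clip(_poly_mutation(c1, rng), 0, 1))
            children.append(np.clip(_poly_mutation(c2, rng), 0, 1))
        children = np.array(children[:pop_size])
        child_objs = evaluate(children)
        n_eval += pop_size

        # environmental selection over parents + children
        allpop = np.vstack([pop, children])
        allobjs = np.vstack([objs, child_objs])
        fronts = non_dominated_sort(allobjs)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(allobjs[front])
                order = front[np.argsort(-cd, kind="stable")]
                keep.extend(order[: pop_size - len(keep)].tolist())
                break
        pop, objs = allpop[keep], allobjs[keep]

    final_front = non_dominated_sort(objs)[0]
    return ParetoResult(
        decisions=lo + pop[final_front] * (hi - lo),
        objectives=objs[final_front],
        n_evaluations=n_eval,
    )


@dataclass
class AcceptableSetResult:
    decisions: np.ndarray  # (k, d) accepted, diversity-selected
    objectives: np.ndarray
    n_evaluations: int
    diagnostic: str
    #: always True: this search approximates, and is not equivalent to, OSE
    simplified_stand_in_for_ose: bool = True


def _greedy_maximin(points01: np.ndarray, k: int) -> np.ndarray:
    """Indices of <= k points greedily maximising the minimum pairwise
    distance, seeded with the most isolated extreme pair."""
    n = len(points01)
    if n <= k:
        return np.arange(n)
    d2 = np.sum((points01[:, None, :] - points01[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [int(i), int(j)]
    while len(chosen) < k:
        rest = [m for m in range(n) if m not in chosen]
        dmin = [min(d2[m, c] for c in chosen) for m in rest]
        chosen.append(rest[int(np.argmax(dmin))])
    return np.array(chosen)


def acceptable_sets(
    objective,
    bounds: np.ndarray,
    thresholds: np.ndarray,
    budget: int = 200,
    n_sets: int = 5,
    refine_steps: int = 3,
    rng: np.random.Generator | None = None,
) -> AcceptableSetResult:
    """Simplified diverse acceptable-set search (stand-in, not OSE).

    Latin-hypercube samples the box, rejects candidates whose objectives
    exceed ``thresholds``, locally refines near-misses by small Gaussian
    perturbations, then keeps at most ``n_sets`` accepted vectors maximising
    their minimum pairwise distance in the normalised box.
    """
    rng = np.random.default_rng() if rng is None else rng
    bounds = np.asarray(bounds, float)
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be positive")
    d = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    n_lhs = max(budget - budget // 4, n_sets)
    sampler = qmc.LatinHypercube(d=d, seed=rng)
    pts01 = sampler.random(n_lhs)
    objs = np.array([objective(lo + x * (hi - lo)) for x in pts01])
    n_eval = n_lhs
    accepted = np.all(objs <= thresholds, axis=1)

    # local refinement: perturb the best near-misses with the leftover budget
    leftover = budget - n_eval
    if leftover > 0:
        # distance to acceptance, normalised per objective
        excess = np.maximum(objs / thresholds - 1.0, 0.0).sum(axis=1)
        order = np.argsort(excess, kind="stable")
        seeds = [i for i in order if not accepted[i]][: max(leftover // max(refine_steps, 1), 1)]
        new_pts, new_objs = [], []
        for i in seeds:
            x = pts01[i].copy()
            fx = objs[i]
            for _ in range(refine_steps):
                if n_eval >= budget:
                    break
                cand = np.clip(x + rng.normal(0, 0.05, size=d), 0, 1)
                fc = objective(lo + cand * (hi - lo))
                n_eval += 1
                if np.sum(np.maximum(fc / thresholds - 1, 0)) < np.sum(
                    np.maximum(fx / thresholds - 1, 0)
                ):
                    x, fx = cand, fc
            new_pts.append(x)
            new_objs.append(fx)
        if new_pts:
            pts01 = np.vstack([pts01, new_pts])
            objs = np.vstack([objs, new_objs])
            accepted = np.all(objs <= thresholds, axis=1)

    if not accepted.any():
        return AcceptableSetResult(
            decisions=np.empty((0, d)),
            objectives=np.empty((0, objs.shape[1])),
            n_evaluations=n_eval,
            diagnostic=(
                f"no parameter set met thresholds {thresholds.tolist()} within "
                f"budget {budget}; smallest normalised excess was "
                f"{float(np.maximum(objs / thresholds - 1, 0).sum(axis=1).min()):.3g}"
            ),
        )
    acc_pts = pts01[accepted]
    acc_objs = objs[accepted]
    pick = _greedy_maximin(acc_pts, n_sets)
    return AcceptableSetResult(
        decisions=lo + acc_pts[pick] * (hi - lo),
        objectives=acc_objs[pick],
        n_evaluations=n_eval,
        diagnostic=f"{int(accepted.sum())} acceptable candidates, kept {len(pick)}",
    )
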