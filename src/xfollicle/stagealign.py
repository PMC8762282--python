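"""Cross-species developmental stage matching.

Each species/compartment contributes an ordered series of per-stage mean
expression profiles over the shared ortholog index. A query series is warped
onto a reference series by dynamic time warping (DTW) on the cost matrix
``1 - Spearman correlation``; the optimal monotone path defines, per query
stage, its best-matching reference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionSet

#: cost assigned when a correlation is undefined (constant profile)
MAX_COST = 2.0


@dataclass
class StageSeries:
    """Ordered per-stage mean profiles for one species/compartment."""

    species: str
    compartment: str
    stages: list[str]
    profiles: pd.DataFrame  # ortholog-group x stage, columns ordered as `stages`

    def __post_init__(self) -> None:
        if list(self.profiles.columns) != list(self.stages):
            raise ValueError("profile columns must follow stage order")
        if not np.isfinite(self.profiles.values).all():
            raise ValueError("profiles must be finite")

    @classmethod
    def from_expression(
        cls, es: ExpressionSet, species: str, compartment: str, log: bool = True
    ) -> "StageSeries":
        """Average replicates per stage on log2(FPKM+1), ordered by stage_order."""
        sub = es.select(species=species, compartment=compartment)
        meta = sub.sample_meta.sort_values("stage_order")
        stages = list(dict.fromkeys(meta["stage"]))
        mat = sub.log2() if log else sub.values
        cols = {st: mat.loc[:, (meta["stage"] == st).reindex(mat.columns, fill_value=False)].mean(axis=1)
                for st in stages}
        profiles = pd.DataFrame(cols)[stages]
        return cls(species, compartment, stages, profiles)


@dataclass
class WarpResult:
    """Optimal DTW warp between a query and a reference stage series."""

    path: list[tuple[int, int]]
    total_cost: float
    pair_costs: list[float]
    best_match: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "path": [list(p) for p in self.path],
            "total_cost": self.total_cost,
            "pair_costs": self.pair_costs,
            "best_match": {str(k): v for k, v in self.best_match.items()},
        }


def spearman(x, y) -> float:
    """Spearman rank correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def dtw(cost: np.ndarray) -> WarpResult:
    """Globally optimal monotone warp through a cost matrix.

    Steps are diagonal, vertical and horizontal with unit weights and full
    boundary constraints. Ties during backtracking prefer the diagonal step,
    then the vertical one, which makes the returned path deterministic.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be non-empty 2-D")
    if not np.isfinite(cost).all() or (cost < 0).any():
        raise ValueError("costs must be finite and non-negative")
    m, n = cost.shape
    acc = np.full((m, n), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(m):
        for j in range(n):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = cost[i, j] + best

    # backtrack; tie order: diagonal, vertical, horizontal
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates, key=lambda c: (c[0], c[1]))
        path.append((i, j))
    path.reverse()
    pair_costs = [float(cost[i, j]) for i, j in path]
    return WarpResult(path=path, total_cost=float(acc[m - 1, n - 1]), pair_costs=pair_costs)


def stage_cost_matrix(query: StageSeries, reference: StageSeries) -> np.ndarray:
    """Cost(i, j) = 1 - Spearman(query stage i, reference stage j).

    Undefined correlations (constant profiles) are set to the maximum
    possible cost of 2.
    """
    if list(query.profiles.index) != list(reference.profiles.index):
        raise ValueError("query and reference must share the ortholog index")
    m, n = len(query.stages), len(reference.stages)
    cost = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            rho = spearman(query.profiles.iloc[:, i], reference.profiles.iloc[:, j])
            cost[i, j] = MAX_COST if np.isnan(rho) else 1.0 - rho
    return cost


def align_stages(query: StageSeries, reference: StageSeries) -> WarpResult:
    """Warp the query stage series onto the reference and extract best matches.

    ``best_match`` maps each query stage label to the reference stage with
    the minimal pair cost among path pairs visiting that query stage; ties
    break toward the earlier reference stage.
    """
    cost = stage_cost_matrix(query, reference)
    result = dtw(cost)
    best: dict[str, str] = {}
    for qi, qstage in enumerate(query.stages):
        pairs = [(c, j) for (i, j), c in zip(result.path, result.pair_costs) if i == qi]
        _, jbest = min(pairs, key=lambda p: (p[0], p[1]))
        best[qstage] = reference.stages[jbest]
    result.best_match = best
    return result
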