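"""Pareto-ranked selection of the optimal areal-unit scale.

Aggregating point sensors into areal units makes every spatial statistic a
function of the chosen unit — the modifiable areal unit problem (MAUP).
The selection framework scores each candidate hexagon side length on two
conflicting objectives and keeps the non-dominated set:

* GM  — Global Moran's I of the aggregated values (maximize: stronger
  overall spatial association);
* LMCV — coefficient of variation of the local Moran values (minimize:
  lower structural instability across the map).

Candidates are ranked by iterative non-dominated sorting; rank 1 is the
Pareto-optimal set.  When several scales share rank 1 the choice is left
to the analyst — no automatic tiebreak is applied.  Dominance operates on
the raw objective values; any min-max rescaling for charts is cosmetic and
cannot change the ranking (monotone per-objective transforms preserve
dominance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import grid as _grid
from . import spatial_stats as _ss
from .errors import (
    DegenerateInputError,
    EmptyLayerError,
    InvalidObjectiveError,
    NoNeighborsError,
)
from .grid import PointDataset

Sense = str  # "max" | "min"


def dominates(
    a: Sequence[float], b: Sequence[float], senses: Sequence[Sense]
) -> bool:
    """True iff ``a`` Pareto-dominates ``b``.

    a dominates b when a is at least as good as b in every objective and
    strictly better in at least one, with "better" read per the sense list.
    """
    if len(a) != len(b) or len(a) != len(senses) or len(a) < 1:
        raise ValueError("objective vectors and senses must have equal length >= 1")
    if any(math.isnan(v) for v in (*a, *b)):
        raise InvalidObjectiveError("NaN objective value")
    at_least_as_good = True
    strictly_better = False
    for ai, bi, s in zip(a, b, senses):
        if s == "max":
            if ai < bi:
                at_least_as_good = False
            elif ai > bi:
                strictly_better = True
        elif s == "min":
            if ai > bi:
                at_least_as_good = False
            elif ai < bi:
                strictly_better = True
        else:
            raise ValueError(f"unknown sense: {s!r}")
    return at_least_as_good and strictly_better


@dataclass
class GranularityCandidate:
    """One areal-unit scale with its objective vector and Pareto rank."""

    scale: float
    global_moran: float
    lisa_cv: float
    n_cells: int = 0
    frontier_rank: int = 0

    @property
    def objectives(self) -> tuple[float, float]:
        return (self.global_moran, self.lisa_cv)


#: objective senses for (global Moran's I, CV of local Moran's I)
OBJECTIVE_SENSES = ("max", "min")


@dataclass
class ParetoResult:
    frontiers: list  # list of lists of GranularityCandidate
    optimal: list = field(init=False)

    def __post_init__(self) -> None:
        self.optimal = self.frontiers[0] if self.frontiers else []


def pareto_rank(
    candidates: Sequence[GranularityCandidate],
    senses: Sequence[Sense] = OBJECTIVE_SENSES,
) -> ParetoResult:
    """Iterative non-dominated sorting; sets ``frontier_rank`` in place.

    Frontier 1 is the non-dominated set of the full candidate pool; it is
    removed and the procedure repeats on the remainder, so the frontiers
    partition the candidates.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    remaining = list(candidates)
    frontiers: list = []
    rank = 1
    while remaining:
        front = [
            c for c in remaining
            if not any(
                dominates(o.objectives, c.objectives, senses)
                for o in remaining if o is not c
            )
        ]
        for c in front:
            c.frontier_rank = rank
        frontiers.append(front)
        remaining = [c for c in remaining if c not in front]
        rank += 1
    return ParetoResult(frontiers=frontiers)


def evaluate_scales(
    data: PointDataset,
    scales: Sequence[float],
    weights_style: _ss.WeightsStyle = "row-standardized",
    statistic: _grid.Statistic = "mean",
    min_count: int = 1,
    permutations: int = 0,
    seed: int | None = None,
    orientation: str = "flat-top",
) -> list:
    """Score every candidate scale and attach Pareto ranks.

    For each hexagon side length: tessellate the data bbox, aggregate the
    point values, build first-order contiguity weights over the non-empty
    cells, and compute (GM, LMCV).  Scales yielding fewer than 3 non-empty
    cells, an all-isolated graph, or constant aggregates are dropped with
    a warning rather than failing the run.
    """
    if len(scales) < 1:
        raise ValueError("need at least one candidate scale")
    if data.crs_tag == "geographic-lonlat":
        data = _grid.project_to_planar(data)
    bbox = data.bbox()
    bbox = (bbox[0], bbox[1], bbox[2], bbox[3])
    candidates: list = []
    for s in scales:
        try:
            layer = _grid.make_hex_grid(
                bbox, s, orientation=orientation, proj_origin=data.proj_origin
            )
            agg = _grid.aggregate(data, layer, statistic=statistic,
                                  min_count=min_count)
            agg = agg.nonempty()
            if agg.n_cells < 3:
                warnings.warn(
                    f"scale {s}: only {agg.n_cells} non-empty cells; dropped",
                    stacklevel=2,
                )
                continue
            W = _ss.contiguity_weights(agg, style=weights_style)
            y = agg.cell_values
            gm = _ss.global_moran(y, W, permutations=permutations, seed=seed)
            lisa = _ss.local_moran(y, W, permutations=permutations, seed=seed)
            lmcv = _ss.cv_local(lisa)
        except (EmptyLayerError, NoNeighborsError, DegenerateInputError) as e:
            warnings.warn(f"scale {s}: {e}; dropped", stacklevel=2)
            continue
        candidates.append(
            GranularityCandidate(
                scale=float(s), global_moran=gm.I, lisa_cv=lmcv,
                n_cells=agg.n_cells,
            )
        )
    if not candidates:
        raise EmptyLayerError("no candidate scale produced a usable layer")
    pareto_rank(candidates)
    return candidates


def minmax_scale_for_chart(
    candidates: Sequence[GranularityCandidate],
) -> np.ndarray:
    """LMCV rescaled into the [min GM, max GM] interval — a display-only
    transform for trade-off charts; never used for dominance."""
    gm = np.array([c.global_moran for c in candidates])
    cv = np.array([c.lisa_cv for c in candidates])
    span = cv.max() - cv.min()
    if span == 0:
        return np.full_like(cv, gm.min())
    return gm.min() + (cv - cv.min()) / span * (gm.max() - gm.min())


def candidates_to_csv(candidates: Sequence[GranularityCandidate],
                      path: str) -> None:
    with open(path, "w") as fh:
        fh.write("scale,GM,LMCV,n_cells,frontier_rank\n")
        for c in sorted(candidates, key=lambda c: c.scale):
            fh.write(
                f"{float(c.scale)!r},{float(c.global_moran)!r},"
                f"{float(c.lisa_cv)!r},{c.n_cells},{c.frontier_rank}\n"
            )
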