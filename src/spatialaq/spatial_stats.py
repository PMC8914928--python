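"""Spatial weights and global/local Moran statistics.

Global Moran's I summarises the overall spatial autocorrelation of an areal
dataset in one number in [-1, 1] (for row-standardized weights, up to minor
boundary effects): positive when neighbouring cells carry similar values,
negative when they alternate, near zero under spatial independence.

    I = n / (sum_ij w_ij) * sum_ij w_ij (y_i - ybar)(y_j - ybar)
                            / sum_i (y_i - ybar)^2

The local indicator of spatial association (LISA, local Moran's I_i)
decomposes the global index per areal unit:

    I_i = (y_i - ybar) * sum_j w_ij (y_j - ybar) / m2,   m2 = sum (y-ybar)^2 / n

so that with row-standardized weights mean_i(I_i) == I exactly.  Inference
for both uses the conditional permutation (pseudo-significance) test: the
values are randomly reallocated over the cells (holding y_i fixed in the
local case) and the observed statistic is ranked within the simulated null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, NoNeighborsError
from .grid import HexLayer

WeightsStyle = Literal["binary", "row-standardized"]

#: significance level used to label LISA quadrants
DEFAULT_ALPHA = 0.05
#: permutation count used across the pipeline unless overridden
DEFAULT_PERMUTATIONS = 999


@dataclass
class SpatialWeights:
    """Sparse symmetric-neighbour weights over ``n`` areal units.

    ``neighbors[i]`` is the array of neighbour indices of cell ``i``;
    ``weights[i]`` the matching weights.  Binary style stores 1.0 per edge,
    row-standardized style 1/deg(i).  Isolated cells have empty rows.
    """

    n: int
    neighbors: list
    weights: list
    style: WeightsStyle

    @property
    def isolated(self) -> np.ndarray:
        return np.array([len(nb) == 0 for nb in self.neighbors])

    def matrix(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb)
            vals.extend(wt)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n)
        )

    def lag(self, y: np.ndarray) -> np.ndarray:
        """Spatial lag W @ y (zero for isolated cells)."""
        return self.matrix() @ np.asarray(y, dtype=float)

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(sum(np.sum(w) for w in self.weights))

    def to_triplet_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("i,j,w\n")
            for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
                for j, w in zip(nb, wt):
                    fh.write(f"{i},{j},{float(w)!r}\n")


def weights_from_adjacency(
    adjacency: list, style: WeightsStyle = "row-standardized"
) -> SpatialWeights:
    """Build SpatialWeights from symmetric adjacency lists."""
    n = len(adjacency)
    neighbors = [np.asarray(sorted(nb), dtype=int) for nb in adjacency]
    for i, nb in enumerate(neighbors):
        if i in nb:
            raise ValueError("self-neighbours are not allowed")
        for j in nb:
            if i not in neighbors[j]:
                raise ValueError("adjacency must be symmetric")
    if style == "binary":
        weights = [np.ones(len(nb)) for nb in neighbors]
    elif style == "row-standardized":
        weights = [
            np.full(len(nb), 1.0 / len(nb)) if len(nb) else np.empty(0)
            for nb in neighbors
        ]
    else:
        raise ValueError(f"unknown weights style: {style!r}")
    return SpatialWeights(n=n, neighbors=neighbors, weights=weights, style=style)


def contiguity_weights(
    layer: HexLayer, style: WeightsStyle = "row-standardized"
) -> SpatialWeights:
    """First-order contiguity weights over the layer's non-empty cells.

    Two regular hexagons are neighbours iff they share an edge, which for
    the hexagon centre lattice means their centres sit exactly sqrt(3) * s
    apart (rook and queen contiguity coincide on hexagons).  The layer must
    already be restricted to (or carry values for) at least two cells.
    """
    if layer.cell_values is not None:
        layer = layer.nonempty()
    centers = layer.centers
    n = len(centers)
    if n < 2:
        raise NoNeighborsError("need at least 2 non-empty cells")
    r = np.sqrt(3.0) * layer.side_length
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r * (1 + 1e-9))
    adjacency = [set() for _ in range(n)]
    for i, j in pairs:
        d = np.hypot(*(centers[i] - centers[j]))
        if abs(d - r) <= 1e-6 * r:
            adjacency[i].add(j)
            adjacency[j].add(i)
    if all(len(a) == 0 for a in adjacency):
        raise NoNeighborsError("all cells are isolated at this scale")
    if any(len(a) == 0 for a in adjacency):
        warnings.warn(
            f"{sum(len(a) == 0 for a in adjacency)} isolated cell(s); their "
            "spatial lag is zero",
            stacklevel=2,
        )
    return weights_from_adjacency(adjacency, style=style)


@dataclass
class MoranResult:
    I: float
    n: int
    permutations: int
    p_pseudo: float | None
    seed: int | None


@dataclass
class LisaResult:
    Ii: np.ndarray
    p_pseudo_i: np.ndarray | None
    quadrant: list
    n: int
    permutations: int
    seed: int | None

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("cell_id,Ii,p,quadrant\n")
            for i in range(self.n):
                p = "" if self.p_pseudo_i is None else repr(float(self.p_pseudo_i[i]))
                fh.write(f"{i},{float(self.Ii[i])!r},{p},{self.quadrant[i]}\n")


def _check_y(y: np.ndarray, n_min: int = 3) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if len(y) < n_min:
        raise DegenerateInputError(f"need at least {n_min} cells, got {len(y)}")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError(
            "constant values: Moran's I is undefined (zero variance)"
        )
    return y


def _global_I(y: np.ndarray, W: SpatialWeights) -> float:
    z = y - y.mean()
    num = float(z @ W.lag(z))
    den = float(z @ z)
    return (len(y) / W.s0) * (num / den)


def global_moran(
    y: np.ndarray,
    W: SpatialWeights,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation pseudo p-value.

    The null simulation permutes the values wholesale across the cells;
    p = (1 + #{|I_perm| >= |I_obs|}) / (1 + permutations).
    """
    y = _check_y(y)
    if len(y) != W.n:
        raise ValueError("y length does not match weights")
    I_obs = _global_I(y, W)
    p = None
    if permutations and permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            I_perm = _global_I(rng.permutation(y), W)
            if abs(I_perm) >= abs(I_obs) - 1e-14:
                count += 1
        p = (1 + count) / (1 + permutations)
    return MoranResult(
        I=I_obs, n=len(y), permutations=permutations or 0, p_pseudo=p, seed=seed
    )


def _local_Ii(y: np.ndarray, W: SpatialWeights) -> np.ndarray:
    z = y - y.mean()
    m2 = float(z @ z) / len(y)
    return z * W.lag(z) / m2


def local_moran(
    y: np.ndarray,
    W: SpatialWeights,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> LisaResult:
    """Local Moran's I_i with conditional-permutation pseudo-significance.

    For each cell i, y_i is held fixed while the remaining values are
    randomly reallocated among the other cells; the observed |I_i| is
    ranked within its simulated null.  Quadrants (HH, LL, HL, LH) follow
    the signs of the deviation and the spatial lag; cells whose pseudo
    p-value exceeds ``alpha`` are labelled not-significant.
    """
    y = _check_y(y)
    if len(y) != W.n:
        raise ValueError("y length does not match weights")
    n = len(y)
    z = y - y.mean()
    m2 = float(z @ z) / n
    lag = W.lag(z)
    Ii = z * lag / m2

    p_i = None
    if permutations and permutations > 0:
        rng = np.random.default_rng(seed)
        p_i = np.ones(n)
        for i in range(n):
            k = len(W.neighbors[i])
            if k == 0:
                p_i[i] = 1.0
                continue
            others = np.delete(z, i)
            wt = np.asarray(W.weights[i])
            # draw `permutations` random k-subsets of the other cells
            draws = np.empty((permutations, k))
            for b in range(permutations):
                draws[b] = others[rng.choice(n - 1, size=k, replace=False)]
            Ii_perm = z[i] * (draws @ wt) / m2
            count = int(np.sum(np.abs(Ii_perm) >= abs(Ii[i]) - 1e-14))
            p_i[i] = (1 + count) / (1 + permutations)

    quadrant = []
    for i in range(n):
        if p_i is not None and p_i[i] > alpha:
            quadrant.append("not-significant")
        elif len(W.neighbors[i]) == 0:
            quadrant.append("not-significant")
        else:
            hi = z[i] > 0
            hl = lag[i] > 0
            quadrant.append(
                "HH" if hi and hl else "LL" if not hi and not hl
                else "HL" if hi else "LH"
            )
    return LisaResult(
        Ii=Ii, p_pseudo_i=p_i, quadrant=quadrant, n=n,
        permutations=permutations or 0, seed=seed,
    )


def cv_local(lisa: LisaResult) -> float:
    """Coefficient of variation of the local Moran values: sd / |mean|.

    Sample standard deviation (n-1 denominator) over the absolute mean;
    the absolute value keeps the objective sign-stable near zero means.
    Returns +inf (with a warning) for an exactly zero mean.
    """
    Ii = np.asarray(lisa.Ii, dtype=float)
    if len(Ii) < 2:
        raise DegenerateInputError("need at least 2 local values")
    mean = Ii.mean()
    sd = Ii.std(ddof=1)
    if mean == 0.0:
        warnings.warn("mean local Moran is zero; CV is infinite", stacklevel=2)
        return float("inf")
    return float(sd / abs(mean))
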