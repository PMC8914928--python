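"""Seeded synthetic sensor fields with known spatial structure.

Every pipeline stage is testable without external downloads: the generator
draws point locations uniformly in a planar box and samples their values
jointly from a stationary Gaussian random field with a chosen covariance —

    exponential:  C(h) = sill * exp(-h / a)
    gaussian:     C(h) = sill * exp(-(h / a)^2)
    nugget-only:  C(h) = 0 for h > 0

plus independent nugget noise and a constant mean.  Sampling is by dense
covariance factorization (Cholesky with a small jitter ladder), which caps
practical sizes at a few thousand points — ample at desk scale, and the
cap is enforced.  All randomness flows through one numpy Generator built
from the spec's seed, so identical specs reproduce bit-identical fields.

The checkerboard fixture provides a negative-autocorrelation ground truth:
alternating +/-1 values on a rook-adjacent square lattice, for which the
2x2 case is the 4-cycle with global Moran's I exactly -1 under binary
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import FieldSimulationError
from .grid import PointDataset
from .spatial_stats import SpatialWeights, weights_from_adjacency

MAX_POINTS = 4000

Covariance = Literal["exponential", "gaussian", "nugget-only"]


@dataclass
class FieldSpec:
    """Parameters of one synthetic sensor field.

    Units: bbox and range in km, sill/nugget in squared value units,
    mean in value units.
    """

    bbox: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    n_points: int = 300
    covariance: Covariance = "exponential"
    range_: float = 200.0
    sill: float = 1.0
    nugget: float = 0.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.n_points > MAX_POINTS:
            raise ValueError(
                f"n_points capped at {MAX_POINTS} (dense factorization)"
            )
        if self.sill < 0 or self.nugget < 0:
            raise ValueError("sill and nugget must be non-negative")
        if self.covariance != "nugget-only" and self.range_ <= 0:
            raise ValueError("range must be positive")


def simulate_field(spec: FieldSpec) -> PointDataset:
    """Draw one field realisation; same spec (incl. seed) -> same bits."""
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = spec.bbox
    x = rng.uniform(xmin, xmax, spec.n_points)
    y = rng.uniform(ymin, ymax, spec.n_points)
    n = spec.n_points

    if spec.covariance == "nugget-only" or spec.sill == 0.0:
        structured = np.zeros(n)
    else:
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        h = np.hypot(dx, dy)
        if spec.covariance == "exponential":
            C = spec.sill * np.exp(-h / spec.range_)
        elif spec.covariance == "gaussian":
            C = spec.sill * np.exp(-((h / spec.range_) ** 2))
        else:  # pragma: no cover
            raise ValueError(spec.covariance)
        L = None
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(C + jitter * spec.sill * np.eye(n))
                break
            except np.linalg.LinAlgError:
                continue
        if L is None:
            raise FieldSimulationError(
                "covariance matrix not positive definite even after jitter"
            )
        structured = L @ rng.standard_normal(n)

    noise = (
        np.sqrt(spec.nugget) * rng.standard_normal(n) if spec.nugget else 0.0
    )
    return PointDataset(
        x=x, y=y, values=spec.mean + structured + noise, crs_tag="planar-km"
    )


@dataclass
class CheckerLattice:
    """Square rook lattice with alternating values, ready for Moran tests."""

    centers: np.ndarray
    values: np.ndarray
    weights: SpatialWeights
    nx: int
    ny: int


def fixture_checkerboard(
    n_cells_x: int, n_cells_y: int, side: float = 1.0,
    style: str = "binary",
) -> CheckerLattice:
    """Alternating +/-1 values on an n_x by n_y rook-adjacent lattice."""
    if n_cells_x < 2 or n_cells_y < 2:
        raise ValueError("checkerboard needs at least 2 cells per axis")
    centers = []
    values = []
    idx = {}
    for j in range(n_cells_y):
        for i in range(n_cells_x):
            idx[(i, j)] = len(centers)
            centers.append((i * side, j * side))
            values.append(1.0 if (i + j) % 2 == 0 else -1.0)
    adjacency = [set() for _ in centers]
    for (i, j), k in idx.items():
        for di, dj in ((1, 0), (0, 1)):
            nb = idx.get((i + di, j + dj))
            if nb is not None:
                adjacency[k].add(nb)
                adjacency[nb].add(k)
    return CheckerLattice(
        centers=np.asarray(centers, dtype=float),
        values=np.asarray(values),
        weights=weights_from_adjacency(adjacency, style=style),
        nx=n_cells_x,
        ny=n_cells_y,
    )
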