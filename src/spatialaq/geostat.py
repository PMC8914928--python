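"""Geostatistical interpolation: normalize, model the variogram, krige.

The interpolation workflow estimates a pollutant field at unsampled
locations as a weighted sum of the observations,

    Zhat(s0) = sum_i lambda_i Z(s_i),

with ordinary-kriging weights: the best linear unbiased predictor under an
unknown constant mean, obtained by solving the semivariance system with the
unit-sum (unbiasedness) constraint through a Lagrange multiplier.  The
spatial dependence enters through a theoretical variogram gamma(h) fitted
to the empirical (Matheron) variogram of the data; the exponential model

    gamma(h) = c0 + c * (1 - exp(-h / a))

never quite reaches its sill, i.e. autocorrelation vanishes only at
infinite distance.  c0 is the nugget (micro-scale noise), c the partial
sill, a the range parameter (practical range ~ 3a).

Values are normalized before variography (skewed pollutant data violate
the implicit Gaussian assumptions badly); the best of a small family of
invertible transforms is chosen by a normality score, and point estimates
are back-transformed for mapping.  Indicator kriging runs the same
machinery on threshold indicators 1{z > t} and yields an exceedance
probability surface in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import SingularKrigingSystem, VariogramFitError
from .grid import PointDataset

ModelName = Literal["exponential", "spherical", "gaussian"]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizeTransform:
    """An invertible value transform chosen for maximum normality.

    ``kind`` is one of identity / log / sqrt / box-cox / yeo-johnson /
    ordered-quantile.  ``params`` holds whatever the inverse needs.
    """

    kind: str
    params: dict

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k, p = self.kind, self.params
        if k == "identity":
            return x.copy()
        if k == "log":
            return np.log(x + p["eps"])
        if k == "sqrt":
            return np.sqrt(x)
        if k == "box-cox":
            return stats.boxcox(x, lmbda=p["lmbda"])
        if k == "yeo-johnson":
            return stats.yeojohnson(x, lmbda=p["lmbda"])
        if k == "ordered-quantile":
            # rank-based normal scores; new values are interpolated on the
            # fitted (x, z) curve
            xs, zs = p["x_sorted"], p["z_sorted"]
            return np.interp(x, xs, zs)
        raise ValueError(f"unknown transform kind {k!r}")

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        k, p = self.kind, self.params
        if k == "identity":
            return z.copy()
        if k == "log":
            return np.exp(z) - p["eps"]
        if k == "sqrt":
            return z**2
        if k == "box-cox":
            lm = p["lmbda"]
            if abs(lm) < 1e-12:
                return np.exp(z)
            return np.power(lm * z + 1.0, 1.0 / lm)
        if k == "yeo-johnson":
            return _yeojohnson_inverse(z, p["lmbda"])
        if k == "ordered-quantile":
            xs, zs = p["x_sorted"], p["z_sorted"]
            return np.interp(z, zs, xs)
        raise ValueError(f"unknown transform kind {k!r}")


def _yeojohnson_inverse(z: np.ndarray, lm: float) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    if abs(lm) < 1e-12:
        out[pos] = np.exp(z[pos]) - 1.0
    else:
        out[pos] = np.power(lm * z[pos] + 1.0, 1.0 / lm) - 1.0
    if abs(lm - 2.0) < 1e-12:
        out[~pos] = 1.0 - np.exp(-z[~pos])
    else:
        out[~pos] = 1.0 - np.power(1.0 - (2.0 - lm) * z[~pos], 1.0 / (2.0 - lm))
    return out


def _normality_score(z: np.ndarray) -> float:
    """Shapiro-Wilk W (higher is more normal); robust to failure."""
    if np.ptp(z) == 0 or not np.all(np.isfinite(z)):
        return -np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(z[:5000]).statistic)
    except Exception:
        return -np.inf


def normalize(values: np.ndarray) -> tuple[np.ndarray, NormalizeTransform]:
    """Pick the transform that maximizes Shapiro-Wilk normality.

    Candidates: identity, log(x+eps), sqrt, Box-Cox (positive data),
    Yeo-Johnson, rank-based ordered-quantile.  Fewer than 10 values (or a
    constant sample) fall back to identity with a warning.  The returned
    descriptor inverts exactly on the observed range.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("normalize requires finite values")
    identity = NormalizeTransform("identity", {})
    if len(x) < 10:
        warnings.warn("fewer than 10 values; using identity transform",
                      stacklevel=2)
        return x.copy(), identity
    if np.ptp(x) == 0:
        warnings.warn("constant values; using identity transform", stacklevel=2)
        return x.copy(), identity

    candidates: list[NormalizeTransform] = [identity]
    if x.min() >= 0:
        candidates.append(NormalizeTransform("sqrt", {}))
        eps = 1e-6 * max(1.0, float(np.abs(x).max()))
        candidates.append(NormalizeTransform("log", {"eps": eps}))
    if x.min() > 0:
        try:
            _, lm = stats.boxcox(x)
            candidates.append(NormalizeTransform("box-cox", {"lmbda": float(lm)}))
        except Exception:
            pass
    try:
        _, lm = stats.yeojohnson(x)
        candidates.append(NormalizeTransform("yeo-johnson", {"lmbda": float(lm)}))
    except Exception:
        pass
    # ordered quantile: midrank normal scores over the unique values keep
    # the interpolation curve strictly monotone even with ties
    xs = np.unique(x)
    sorted_x = np.sort(x)
    lo = np.searchsorted(sorted_x, xs, side="left") + 1
    hi = np.searchsorted(sorted_x, xs, side="right")
    zs = stats.norm.ppf(((lo + hi) / 2.0 - 0.5) / len(x))
    candidates.append(
        NormalizeTransform("ordered-quantile", {"x_sorted": xs, "z_sorted": zs})
    )

    best, best_score = identity, -np.inf
    for t in candidates:
        try:
            z = t.forward(x)
        except Exception:
            continue
        score = _normality_score(z)
        if score > best_score:
            best, best_score = t, score
    return best.forward(x), best


# ---------------------------------------------------------------------------
# Variogram
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalVariogram:
    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    min_pairs_flag: int = 10

    def usable(self) -> np.ndarray:
        """Mask of bins with enough pairs to trust."""
        return self.pair_counts >= self.min_pairs_flag


@dataclass
class VariogramModel:
    """Theoretical variogram gamma(h) = c0 + c * g(h / a); gamma(0) = 0."""

    model: ModelName
    nugget: float
    partial_sill: float
    range_: float

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c0, c, a = self.nugget, self.partial_sill, self.range_
        if self.model == "exponential":
            g = 1.0 - np.exp(-h / a)
        elif self.model == "gaussian":
            g = 1.0 - np.exp(-((h / a) ** 2))
        elif self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        else:
            raise ValueError(f"unknown model {self.model!r}")
        out = c0 + c * g
        return np.where(h == 0.0, 0.0, out)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def to_json(self, path: str | None = None, extra: dict | None = None) -> dict:
        d = {
            "model": self.model,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range_,
            "sill": self.sill,
        }
        if extra:
            d.update(extra)
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def empirical_variogram(
    data: PointDataset,
    n_lags: int = 15,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator on equal-width lag bins.

    gammahat(h) = (1 / 2|N(h)|) * sum over pairs in the bin of (z_i - z_j)^2.
    ``max_dist`` defaults to half the maximum pairwise distance.  Empty
    bins are dropped with a warning.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 points for a variogram")
    d = pdist(data.coords)
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    dv = pdist(data.values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.digitize(d, edges) - 1
    inside = (which >= 0) & (which < n_lags) & (d > 0)
    centers, gamma, counts = [], [], []
    for b in range(n_lags):
        m = inside & (which == b)
        nb = int(m.sum())
        if nb == 0:
            warnings.warn(f"lag bin {b} has zero pairs; dropped", stacklevel=2)
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        gamma.append(float(dv[m].sum()) / (2.0 * nb))
        counts.append(nb)
    return EmpiricalVariogram(
        lag_centers=np.asarray(centers),
        semivariance=np.asarray(gamma),
        pair_counts=np.asarray(counts, dtype=int),
    )


def fit_variogram(
    emp: EmpiricalVariogram,
    model: ModelName = "exponential",
) -> VariogramModel:
    """Weighted least-squares fit of (nugget, partial sill, range).

    Bins are weighted by pair counts.  Parameters are bounded below at
    zero (a tiny floor for the range); negative unconstrained estimates
    therefore land on the bounds with a warning.
    """
    h = emp.lag_centers
    g = emp.semivariance
    w = np.sqrt(emp.pair_counts.astype(float))
    if len(h) < 3:
        raise VariogramFitError("need at least 3 usable lag bins")
    gmax = float(g.max()) if g.max() > 0 else 1.0
    hmax = float(h.max())

    def gfun(hh, c0, c, a):
        return VariogramModel(model, c0, c, a)(hh)

    p0 = (max(g[0], 1e-6 * gmax), max(gmax - g[0], 1e-6 * gmax),
          max(hmax / 3.0, 1e-6))
    lo = (0.0, 0.0, 1e-9 * max(hmax, 1.0))
    hi = (2 * gmax, 4 * gmax, 100 * hmax)
    try:
        popt, _ = optimize.curve_fit(
            gfun, h, g, p0=p0, sigma=1.0 / np.maximum(w, 1e-12),
            bounds=(lo, hi), maxfev=20000,
        )
    except Exception as e:  # noqa: BLE001
        raise VariogramFitError(f"variogram fit failed: {e}") from e
    c0, c, a = (float(v) for v in popt)
    fit = VariogramModel(model=model, nugget=c0, partial_sill=c, range_=a)
    # structured variation actually expressed over the observed lags; when
    # negligible the curve is flat and the range is unidentifiable (the
    # optimizer may park it at either bound)
    structured = float(fit(np.array([hmax]))[0]) - c0
    if structured <= 1e-3 * gmax:
        warnings.warn(
            "fitted partial sill ~ 0 over the observed lags (pure nugget); "
            "range is unidentifiable",
            stacklevel=2,
        )
        fit = VariogramModel(model=model, nugget=c0,
                             partial_sill=max(structured, 0.0), range_=a)
    return fit


# ---------------------------------------------------------------------------
# Kriging
# ---------------------------------------------------------------------------

@dataclass
class KrigingPrediction:
    targets: np.ndarray      # (m, 2)
    estimate: np.ndarray     # (m,)
    variance: np.ndarray     # (m,) on the (possibly transformed) scale
    back_transform: str = "identity"
    weights: np.ndarray | None = None  # (n, m) lambda, if requested


def _check_duplicates(coords: np.ndarray) -> None:
    if len(coords) > 1:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(1e-9)
        if pairs:
            raise SingularKrigingSystem(
                f"{len(pairs)} duplicate point location(s) make the kriging "
                "system singular; deduplicate (e.g. average co-located "
                "observations) or jitter coordinates"
            )


def ordinary_kriging(
    data: PointDataset,
    vg: VariogramModel,
    targets: np.ndarray,
    n_neighbors: int | None = None,
    return_weights: bool = False,
) -> KrigingPrediction:
    """Ordinary kriging of ``data`` at ``targets``.

    Solves, per target s0, the (N+1) semivariance system

        [Gamma 1; 1' 0] [lambda; mu] = [gamma(s_i, s0); 1]

    giving Zhat(s0) = sum lambda_i Z(s_i) and kriging variance
    sum lambda_i gamma_i0 + mu.  With ``n_neighbors`` set, each target
    uses only its k nearest observations (moving-neighbourhood kriging).
    """
    coords = data.coords
    z = data.values
    n = len(z)
    if n < 2:
        raise ValueError("ordinary kriging needs at least 2 observations")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    _check_duplicates(coords)

    if n_neighbors is not None and n_neighbors < n:
        k = max(int(n_neighbors), 2)
        tree = cKDTree(coords)
        est = np.empty(len(targets))
        var = np.empty(len(targets))
        for t, s0 in enumerate(targets):
            _, idx = tree.query(s0, k=k)
            lam, mu, g0 = _ok_weights(coords[idx], vg, s0)
            est[t] = lam @ z[idx]
            var[t] = max(float(lam @ g0 + mu), 0.0)
        return KrigingPrediction(targets=targets, estimate=est, variance=var)

    gamma = squareform(vg(pdist(coords)))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    try:
        lu = lu_factor(A)
    except Exception as e:  # noqa: BLE001
        raise SingularKrigingSystem(str(e)) from e
    g0 = vg(cdist(coords, targets))       # (n, m)
    rhs = np.vstack([g0, np.ones((1, len(targets)))])
    sol = lu_solve(lu, rhs)               # (n+1, m)
    lam = sol[:n]
    mu = sol[n]
    est = lam.T @ z
    var = np.maximum(np.einsum("it,it->t", lam, g0) + mu, 0.0)
    return KrigingPrediction(
        targets=targets, estimate=est, variance=var,
        weights=lam if return_weights else None,
    )


def simple_kriging(
    data: PointDataset,
    vg: VariogramModel,
    targets: np.ndarray,
    mean: float | None = None,
) -> KrigingPrediction:
    """Simple kriging with a known constant mean (default: data mean).

    Weights solve C lambda = c0 in covariance form (C(h) = sill - gamma(h));
    the estimate is m + sum lambda_i (Z(s_i) - m).  Unlike ordinary
    kriging the weights need not sum to one.
    """
    coords = data.coords
    z = data.values
    n = len(z)
    if n < 2:
        raise ValueError("simple kriging needs at least 2 observations")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    _check_duplicates(coords)
    m = float(z.mean()) if mean is None else float(mean)
    sill = vg.sill
    C = sill - squareform(vg(pdist(coords)))
    np.fill_diagonal(C, sill)
    c0 = sill - vg(cdist(coords, targets))
    try:
        lam = np.linalg.solve(C, c0)
    except np.linalg.LinAlgError as e:
        raise SingularKrigingSystem(str(e)) from e
    est = m + lam.T @ (z - m)
    var = np.maximum(sill - np.einsum("it,it->t", lam, c0), 0.0)
    return KrigingPrediction(targets=targets, estimate=est, variance=var)


def _ok_weights(
    coords: np.ndarray, vg: VariogramModel, s0: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    n = len(coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = squareform(vg(pdist(coords)))
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    g0 = vg(np.hypot(*(coords - s0).T))
    b = np.append(g0, 1.0)
    sol = np.linalg.solve(A, b)
    return sol[:n], float(sol[n]), g0


def prediction_grid(
    bbox: tuple[float, float, float, float], resolution: float
) -> np.ndarray:
    """Regular planar grid of target locations covering ``bbox``."""
    xmin, ymin, xmax, ymax = bbox
    xs = np.arange(xmin, xmax + resolution / 2, resolution)
    ys = np.arange(ymin, ymax + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def krige_field(
    data: PointDataset,
    targets: np.ndarray,
    model: ModelName = "exponential",
    n_lags: int = 15,
    do_normalize: bool = True,
    n_neighbors: int | None = None,
) -> tuple[KrigingPrediction, VariogramModel, NormalizeTransform]:
    """The full workflow: normalize -> variogram -> fit -> krige -> back.

    Kriging runs on the normalized scale; point estimates are inverted to
    the data scale, while the kriging variance is reported on the
    transformed scale only (the nonlinear inverse has no simple variance
    mapping) — a documented limitation.
    """
    if do_normalize:
        zn, transform = normalize(data.values)
    else:
        zn, transform = data.values.copy(), NormalizeTransform("identity", {})
    ndata = PointDataset(data.x, data.y, zn, crs_tag=data.crs_tag,
                         proj_origin=data.proj_origin)
    emp = empirical_variogram(ndata, n_lags=n_lags)
    vg = fit_variogram(emp, model=model)
    pred = ordinary_kriging(ndata, vg, targets, n_neighbors=n_neighbors)
    pred.estimate = transform.inverse(pred.estimate)
    pred.back_transform = transform.kind
    return pred, vg, transform


def indicator_kriging(
    data: PointDataset,
    threshold: float,
    targets: np.ndarray,
    model: ModelName = "exponential",
    n_lags: int = 15,
    n_neighbors: int | None = None,
) -> tuple[KrigingPrediction, VariogramModel | None]:
    """Exceedance-probability surface P[Z(s0) > threshold].

    The values are replaced by indicators 1{z > threshold}, an indicator
    variogram is fitted, and the indicators are ordinary-kriged; estimates
    are clipped into [0, 1].  If every indicator is identical the surface
    is that constant (with a warning) — there is nothing to interpolate.
    """
    ind = (data.values > threshold).astype(float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n_above = int(ind.sum())
    if n_above in (0, len(ind)):
        warnings.warn(
            "all observations on one side of the threshold; constant "
            "probability surface",
            stacklevel=2,
        )
        const = float(ind[0])
        return (
            KrigingPrediction(
                targets=targets,
                estimate=np.full(len(targets), const),
                variance=np.zeros(len(targets)),
                back_transform="indicator",
            ),
            None,
        )
    if min(n_above, len(ind) - n_above) < 2:
        warnings.warn(
            "fewer than 2 observations on one side of the threshold; the "
            "indicator variogram is poorly constrained",
            stacklevel=2,
        )
    idata = PointDataset(data.x, data.y, ind, crs_tag=data.crs_tag,
                         proj_origin=data.proj_origin)
    emp = empirical_variogram(idata, n_lags=n_lags)
    vg = fit_variogram(emp, model=model)
    pred = ordinary_kriging(idata, vg, targets, n_neighbors=n_neighbors)
    pred.estimate = np.clip(pred.estimate, 0.0, 1.0)
    pred.back_transform = "indicator"
    return pred, vg


def prediction_to_csv(pred: KrigingPrediction, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,estimate,variance\n")
        for (x, y), e, v in zip(pred.targets, pred.estimate, pred.variance):
            fh.write(f"{float(x)!r},{float(y)!r},{float(e)!r},{float(v)!r}\n")
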