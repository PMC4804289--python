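"""Ordinary-kriging isoscapes for single variables over a lon/lat grid.

An isoscape is a spatially continuous prediction of a point-sampled
measurement.  The empirical semivariogram gamma(h) — half the mean squared
difference between values at lag distance h — is fitted by weighted least
squares with a spherical, exponential or gaussian model (nugget, partial
sill, range).  Each grid cell is then predicted by ordinary kriging on its
nearest neighbors: the best linear unbiased predictor whose weights solve
the semivariogram system with a Lagrange multiplier forcing them to sum to
one.  A first-order (planar) trend can be removed before kriging and added
back, the treatment used for the alkaloids and d2H; d13C and d15N are
kriged without detrending.

Coordinates are projected to local equirectangular kilometers before any
distance computation (degrees of longitude shrink with latitude).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .dataio import DataError

EARTH_RADIUS_KM = 6371.0

#: Variables kriged with first-order trend removal by default.
DETREND_DEFAULT = {"tropacocaine": True, "trimethoxycocaine": True,
                   "truxillines": True, "d2H": True, "d13C": False, "d15N": False,
                   "d18O": True}


def project_km(lon, lat, lon0: float | None = None, lat0: float | None = None
               ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Local equirectangular projection to kilometers."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    if lon0 is None:
        lon0, lat0 = float(lon.mean()), float(lat.mean())
    x = np.radians(lon - lon0) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_KM
    return x, y, (lon0, lat0)


@dataclass
class Variogram:
    family: str
    nugget: float
    psill: float
    range_: float
    lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    npairs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.family not in ("spherical", "exponential", "gaussian"):
            raise DataError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise DataError("variogram requires nugget >= 0, psill >= 0, range > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        x = h / self.range_
        if self.family == "spherical":
            f = np.where(x < 1.0, 1.5 * x - 0.5 * x**3, 1.0)
        elif self.family == "exponential":
            f = 1.0 - np.exp(-3.0 * x)       # effective-range convention
        else:
            f = 1.0 - np.exp(-3.0 * x**2)
        g = self.nugget + self.psill * f
        return np.where(h <= 0, 0.0, g)

    def scaled(self, factor: float) -> "Variogram":
        return Variogram(self.family, self.nugget * factor, self.psill * factor,
                         self.range_, self.lags, self.gamma, self.npairs)

    def to_dict(self) -> dict:
        return {"family": self.family, "nugget": self.nugget,
                "psill": self.psill, "range": self.range_,
                "lags": self.lags.tolist(), "gamma": self.gamma.tolist(),
                "npairs": self.npairs.tolist()}


def empirical_semivariogram(x, y, values, n_lags: int = 12,
                            max_lag: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned (lag, semivariance, pair count) table."""
    pts = np.column_stack([x, y])
    n = len(pts)
    iu = np.triu_indices(n, k=1)
    d = np.sqrt(((pts[iu[0]] - pts[iu[1]]) ** 2).sum(axis=1))
    dv2 = (np.asarray(values, float)[iu[0]] - np.asarray(values, float)[iu[1]]) ** 2
    if max_lag is None:
        max_lag = d.max() / 2.0 if d.max() > 0 else 1.0
    edges = np.linspace(0, max_lag, n_lags + 1)
    lags, gam, cnt = [], [], []
    for a, b in zip(edges, edges[1:]):
        sel = (d > a) & (d <= b)
        if sel.sum() > 0:
            lags.append(d[sel].mean())
            gam.append(0.5 * dv2[sel].mean())
            cnt.append(int(sel.sum()))
    return np.array(lags), np.array(gam), np.array(cnt)


def fit_variogram(points, values, family: str = "spherical",
                  n_lags: int = 12) -> Variogram:
    """Weighted least-squares fit of the chosen family to the empirical lags.

    ``points`` is (n, 2) lon/lat; distances are in projected kilometers.
    Constant fields collapse to a pure-nugget-zero model with a warning.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 10:
        raise DataError("need at least 10 points to fit a variogram")
    x, y, _ = project_km(points[:, 0], points[:, 1])
    var = float(np.var(values))
    if np.ptp(values) == 0 or var < 1e-24 * max(1.0, float(np.mean(values)) ** 2):
        warnings.warn("constant field; pure-nugget-zero variogram")
        span = max(float(np.hypot(np.ptp(x), np.ptp(y))), 1.0)
        return Variogram(family, 0.0, 0.0, span)
    lags, gam, cnt = empirical_semivariogram(x, y, values, n_lags=n_lags)

    def resid(theta):
        nugget, psill, rng = theta
        model = Variogram(family, max(nugget, 0), max(psill, 1e-12), max(rng, 1e-6))
        g = model(lags)
        # Cressie weighting: npairs / gamma_model^2 emphasizes short lags,
        # where the nugget must be resolved
        return np.sqrt(cnt) * (g - gam) / np.maximum(g, 1e-12)

    span = max(lags.max(), 1e-6)
    x0 = np.array([min(gam[0], var) * 0.5, max(var - gam[0] * 0.5, var * 0.1), span / 2])
    sol = least_squares(resid, x0, bounds=([0, 1e-12, 1e-6],
                                           [var * 10 + 1e-9, var * 10 + 1e-9, span * 4]))
    nugget, psill, rng = sol.x
    fit = Variogram(family, float(nugget), float(psill), float(rng), lags, gam, cnt)
    return fit


def _ok_solve(coords: np.ndarray, vals: np.ndarray, target: np.ndarray,
              vgm: Variogram) -> tuple[float, float, np.ndarray]:
    """Solve one ordinary-kriging system; returns (prediction, variance, weights)."""
    n = len(coords)
    if vgm.nugget + vgm.psill <= 0:  # degenerate (constant) model
        return float(vals.mean()), 0.0, np.full(n, 1.0 / n)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vgm(d)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = vgm(np.sqrt(((coords - target) ** 2).sum(-1)))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
    w, mu = sol[:n], sol[n]
    pred = float(w @ vals)
    var = float(max(w @ b[:n] + mu, 0.0))
    return pred, var, w


def _dedupe(coords: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, inv = np.unique(np.round(coords, 9), axis=0, return_inverse=True)
    if inv.max() + 1 == len(coords):
        return coords, vals
    warnings.warn("duplicate sample locations averaged before kriging")
    k = inv.max() + 1
    c = np.zeros((k, 2))
    v = np.zeros(k)
    cnt = np.zeros(k)
    for i, g in enumerate(inv):
        c[g] += coords[i]
        v[g] += vals[i]
        cnt[g] += 1
    return c / cnt[:, None], v / cnt


@dataclass
class KrigingSurface:
    lon: np.ndarray          # grid cell centers (flattened, hull-clipped)
    lat: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    cell_size: float
    variogram: Variogram
    trend_coef: np.ndarray | None = None
    n_neighbors: int = 15
    min_neighbors: int = 13

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lon": self.lon, "lat": self.lat,
                             "prediction": self.prediction,
                             "variance": self.variance})


def _fit_trend(x, y, vals) -> tuple[np.ndarray, np.ndarray]:
    M = np.column_stack([np.ones_like(x), x, y])
    coef, *_ = np.linalg.lstsq(M, vals, rcond=None)
    return coef, vals - M @ coef


def krige_points(points, values, targets, variogram: Variogram,
                 n_neighbors: int = 15, min_neighbors: int = 13,
                 detrend: bool = False):
    """Ordinary kriging of arbitrary target lon/lat locations.

    Returns (predictions, variances, weight list).  Weights always sum to
    one (Lagrange constraint); with a nugget-free model a target coinciding
    with a datum reproduces it exactly with zero variance.
    """
    if n_neighbors < min_neighbors or min_neighbors < 1:
        raise DataError("need n_neighbors >= min_neighbors >= 1")
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    x, y, origin = project_km(points[:, 0], points[:, 1])
    coords = np.column_stack([x, y])
    coords, values = _dedupe(coords, values)
    trend_coef = None
    if detrend:
        trend_coef, values = _fit_trend(coords[:, 0], coords[:, 1], values)
    tx, ty, _ = project_km(targets[:, 0], targets[:, 1], *origin)
    tcoords = np.column_stack([tx, ty])
    tree = cKDTree(coords)
    k = min(n_neighbors, len(coords))
    preds = np.empty(len(tcoords))
    vars_ = np.empty(len(tcoords))
    weights = []
    for i, t in enumerate(tcoords):
        _, idx = tree.query(t, k=k)
        idx = np.atleast_1d(idx)
        p, v, w = _ok_solve(coords[idx], values[idx], t, variogram)
        preds[i] = p
        vars_[i] = v
        weights.append((idx, w))
    if detrend:
        preds = preds + (trend_coef[0] + trend_coef[1] * tx + trend_coef[2] * ty)
    return preds, vars_, weights, trend_coef


def krige_grid(points, values, variogram: Variogram, cell_size: float = 0.25,
               n_neighbors: int = 15, min_neighbors: int = 13,
               detrend: bool = False, buffer_deg: float = 0.25) -> KrigingSurface:
    """Krige a variable onto a lon/lat grid clipped to the sample hull.

    Neighbor defaults (15 used / 13 minimum) sit inside the 14–16 and
    12–14 search windows used for the published surfaces.
    """
    from shapely.geometry import MultiPoint, Point

    points = np.asarray(points, float)
    lo_lon, hi_lon = points[:, 0].min(), points[:, 0].max()
    lo_lat, hi_lat = points[:, 1].min(), points[:, 1].max()
    lons = np.arange(lo_lon - buffer_deg, hi_lon + buffer_deg + cell_size, cell_size)
    lats = np.arange(lo_lat - buffer_deg, hi_lat + buffer_deg + cell_size, cell_size)
    gg = np.array(np.meshgrid(lons, lats)).reshape(2, -1).T
    hull = MultiPoint([tuple(p) for p in points]).convex_hull.buffer(buffer_deg)
    keep = np.array([hull.contains(Point(*p)) or hull.touches(Point(*p)) for p in gg])
    targets = gg[keep]
    preds, vars_, _, trend_coef = krige_points(
        points, values, targets, variogram, n_neighbors=n_neighbors,
        min_neighbors=min_neighbors, detrend=detrend)
    return KrigingSurface(targets[:, 0], targets[:, 1], preds, vars_, cell_size,
                          variogram, trend_coef, n_neighbors, min_neighbors)


def cv_kriging(points, values, variogram: Variogram, n_neighbors: int = 15,
               min_neighbors: int = 13, detrend: bool = False) -> dict:
    """Leave-one-out cross-validation: RMS error and standardized RMS.

    Standardized RMS near 1 indicates the kriging variances are calibrated;
    inflating the variogram sill by a factor f scales it by 1/sqrt(f).
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 10:
        raise DataError("need at least 10 points for cross-validation")
    resid = np.empty(len(points))
    std2 = np.empty(len(points))
    for i in range(len(points)):
        mask = np.arange(len(points)) != i
        p, v, _, _ = krige_points(points[mask], values[mask], points[i][None],
                                  variogram, n_neighbors=n_neighbors,
                                  min_neighbors=min_neighbors, detrend=detrend)
        resid[i] = values[i] - p[0]
        std2[i] = resid[i] ** 2 / v[0] if v[0] > 0 else 0.0
    return {"rms": float(np.sqrt(np.mean(resid**2))),
            "standardized_rms": float(np.sqrt(np.mean(std2))),
            "n": len(points)}
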