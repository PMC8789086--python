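"""Genetics-versus-geography analyses.

Great-circle distances use the haversine formula with the IUGG mean
Earth radius (6371.0088 km). Regressions of matrix entries on matrix
entries report both the naive OLS p-value (descriptive only, since
distance-matrix entries are not independent) and a Mantel-style
permutation p-value, the latter as the primary result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fstats import DistanceMatrix

EARTH_RADIUS_KM = 6371.0088


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    p_permutation: float | None = None
    n: int = 0


def geo_regression(
    values: np.ndarray, coords: np.ndarray, axis: str = "longitude"
) -> RegressionResult:
    """OLS of a per-sample scalar on latitude or longitude.

    ``coords`` has columns (lat, lon) in degrees; returns R^2 and the
    two-sided slope t-test p-value.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if axis not in ("latitude", "longitude"):
        raise ValueError("axis must be 'latitude' or 'longitude'")
    x = coords[:, 0] if axis == "latitude" else coords[:, 1]
    if len(values) < 3:
        raise ValueError("regression needs at least 3 samples")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, values)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(values),
    )


def great_circle_matrix(
    labels: list[str], coords: np.ndarray
) -> DistanceMatrix:
    """Haversine great-circle distance matrix (km) from (lat, lon) degrees."""
    coords = np.asarray(coords, dtype=float)
    lat, lon = coords[:, 0], coords[:, 1]
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (lat [-90,90], lon [-180,180])")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d, units="km")


def isolation_by_distance(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> RegressionResult:
    """Regression of genetic on geographic distance with a Mantel permutation p.

    Upper-triangle entries are vectorized; the permutation test shuffles
    unit labels of the genetic matrix and recomputes the correlation,
    with p = (#exceeding + 1)/(n_perm + 1), reported as primary.
    """
    if list(genetic.labels) != list(geographic.labels):
        raise ValueError("genetic and geographic matrices must share labels")
    n = len(genetic.labels)
    iu = np.triu_indices(n, 1)
    y = genetic.matrix[iu]
    x = geographic.matrix[iu]
    if np.std(x) == 0:
        raise ValueError("zero-variance geographic distances")
    res = stats.linregress(x, y)
    obs_r = res.rvalue
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = genetic.matrix[np.ix_(perm, perm)][iu]
        r = np.corrcoef(x, yp)[0, 1]
        if r >= obs_r:
            exceed += 1
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        p_permutation=(exceed + 1) / (n_perm + 1),
        n=len(y),
    )
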