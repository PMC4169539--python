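"""Concordance between genetic coordinates and geography.

Population-mean PC coordinates are compared with population geographic
centres via Spearman axis correlations, a grid-searched best-alignment
bearing, the Mantel permutation test on distance matrices and the Procrustes
permutation test on the 2-D configurations. Geographic centres are projected
to local planar km (equirectangular) for Procrustes and bearings; great
circles are used for the distance matrices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeoPanel
from .pca import PCAResult
from .sim import EARTH_RADIUS_KM, equirectangular_xy


@dataclass
class PopCentroids:
    """Per-population mean PC coordinates and local-km geographic centres."""

    populations: list[str]
    pc_coords: np.ndarray  # (n_pops, m)
    geo_xy: np.ndarray     # (n_pops, 2): x east, y north, km

    def latitudes_proxy(self) -> np.ndarray:
        return self.geo_xy[:, 1]

    def longitudes_proxy(self) -> np.ndarray:
        return self.geo_xy[:, 0]


@dataclass
class ConcordanceReport:
    spearman: dict[tuple[int, str], tuple[float, float]]
    best_angle_deg: float
    best_angle_rho: float
    mantel_r: float
    mantel_p: float
    procrustes_t: float
    procrustes_p: float
    n_permutations: int


def population_centroids(
    pca: PCAResult,
    populations: list[str],
    geo: GeoPanel,
    m: int = 2,
) -> PopCentroids:
    """Mean score of each population's samples over the first ``m`` PCs,
    paired with the population's projected geographic centre. Populations
    lacking geographic coordinates are dropped with a warning."""
    if len(populations) != pca.scores.shape[0]:
        raise ValueError("need one population label per PCA sample")
    pops_avail = [p for p in dict.fromkeys(populations) if p in set(geo.populations)]
    dropped = sorted(set(populations) - set(pops_avail))
    if dropped:
        warnings.warn(f"populations without geographic centres dropped: {dropped}")
    if not pops_avail:
        raise ValueError("no population present in both the PCA and the geo panel")
    labels = np.asarray(populations)
    coords = np.vstack([pca.scores[labels == p, :m].mean(axis=0) for p in pops_avail])
    xy = equirectangular_xy(geo.subset(pops_avail))
    return PopCentroids(pops_avail, coords, xy)


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p; exact permutation null for n <= 8
    (the t-approximation is poor at the handfuls-of-populations scale)."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho = float(stats.spearmanr(a, b)[0])
    n = len(a)
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(a[list(perm)], b)[0]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(a, b)[1])


def spearman_axis(c: PopCentroids, pc_index: int, axis: str) -> tuple[float, float]:
    """Spearman rank correlation of a PC's population means against latitude
    or longitude (two-sided p)."""
    if len(c.populations) < 4:
        raise ValueError("need at least 4 populations")
    if axis == "latitude":
        g = c.latitudes_proxy()
    elif axis == "longitude":
        g = c.longitudes_proxy()
    else:
        raise ValueError("axis must be 'latitude' or 'longitude'")
    return _spearman(c.pc_coords[:, pc_index], g)


def best_alignment_angle(c: PopCentroids, pc_index: int = 0, step_deg: float = 0.5) -> tuple[float, float]:
    """Compass bearing whose geographic axis best rank-correlates with a PC.

    Grid search over bearings theta in [-90, 90) deg from north (projection
    ``y cos(theta) + x sin(theta)``); returns the bearing maximizing
    |Spearman rho| (ties broken toward smaller |theta|) with its signed rho.
    """
    if len(c.populations) < 4:
        raise ValueError("need at least 4 populations")
    pc = c.pc_coords[:, pc_index]
    if np.ptp(pc) == 0:
        raise ValueError("constant PC column")
    angles = np.arange(-90.0, 90.0, step_deg)
    rhos = np.empty(angles.size)
    for i, theta in enumerate(np.radians(angles)):
        proj = c.geo_xy[:, 1] * math.cos(theta) + c.geo_xy[:, 0] * math.sin(theta)
        rhos[i] = stats.spearmanr(pc, proj)[0]
    order = np.argsort(np.abs(angles), kind="stable")  # ties toward smaller |theta|
    best = order[int(np.argmax(np.abs(rhos)[order]))]
    return float(angles[best]), float(rhos[best])


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "pearson",
    exact: bool = False,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    The correlation (Pearson by default, Spearman optional) is computed over
    the off-diagonal upper triangle; the empirical one-sided p-value permutes
    one joint row/column relabeling of ``d2`` per iteration and uses the
    add-one formula ``p = (1 + #[r_perm >= r_obs]) / (1 + n_perm)``. With
    ``exact=True`` all relabelings are enumerated and
    ``p = #[r_perm >= r_obs] / n!`` (the identity included).
    """
    d1 = _check_distance_matrix(d1, "D1")
    d2 = _check_distance_matrix(d2, "D2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    v1 = d1[iu]
    if method == "pearson":
        corr = lambda a, b: stats.pearsonr(a, b)[0]
    elif method == "spearman":
        corr = lambda a, b: stats.spearmanr(a, b)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(v1) == 0 or np.ptp(d2[iu]) == 0:
        raise ValueError("constant off-diagonal entries: correlation undefined")
    r_obs = corr(v1, d2[iu])
    tol = 1e-12
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p_ = np.asarray(perm)
            count += corr(v1, d2[np.ix_(p_, p_)][iu]) >= r_obs - tol
            total += 1
        return float(r_obs), count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_ = rng.permutation(n)
        count += corr(v1, d2[np.ix_(p_, p_)][iu]) >= r_obs - tol
    return float(r_obs), (1 + count) / (1 + n_perm)


def _procrustes_t(x: np.ndarray, y: np.ndarray, allow_reflection: bool) -> float:
    """Procrustes congruence t = sqrt(1 - m^2) for centred unit-SS configs."""
    m = y.T @ x
    u, s, vt = np.linalg.svd(m)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] *= -1.0
    return float(np.clip(s.sum(), 0.0, 1.0))


def procrustes_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    allow_reflection: bool = False,
    exact: bool = False,
) -> tuple[float, float]:
    """Procrustes permutation test between two point configurations.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of ``Y^T X`` (reflections disallowed
    by default, since geographic orientation is meaningful) and the statistic
    is ``t = sqrt(1 - m^2)`` with ``m^2`` the minimized residual. The
    one-sided p permutes the row order of ``Y``, add-one formula as in
    :func:`mantel_test`; ``exact=True`` enumerates all row orders.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("configurations must be equal-shape with >= 3 rows")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate configuration: all points identical")
    xc /= nx
    yc /= ny
    t_obs = _procrustes_t(xc, yc, allow_reflection)
    n = x.shape[0]
    tol = 1e-12
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            count += _procrustes_t(xc, yc[list(perm)], allow_reflection) >= t_obs - tol
            total += 1
        return t_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _procrustes_t(xc, yc[rng.permutation(n)], allow_reflection) >= t_obs - tol
    return t_obs, (1 + count) / (1 + n_perm)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (haversine, R = 6371 km)."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = math.sin((la2 - la1) / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geo_distance_matrix(geo: GeoPanel, pops: list[str] | None = None) -> np.ndarray:
    """Pairwise great-circle km between population centres."""
    pops = pops if pops is not None else geo.populations
    n = len(pops)
    d = np.zeros((n, n))
    coords = [geo.latlon(p) for p in pops]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(*coords[i], *coords[j])
    return d


def concordance_report(
    c: PopCentroids,
    geo: GeoPanel,
    n_perm: int = 1000,
    seed: int = 0,
) -> ConcordanceReport:
    """Bundle the standard battery: Spearman per (PC, axis), best bearing for
    PC1, Mantel on PC-centroid vs great-circle distances, Procrustes on the
    2-D configurations."""
    spearman = {}
    for k in range(min(2, c.pc_coords.shape[1])):
        for axis in ("latitude", "longitude"):
            spearman[(k, axis)] = spearman_axis(c, k, axis)
    angle, rho = best_alignment_angle(c, 0)
    d_pc = np.linalg.norm(c.pc_coords[:, None, :] - c.pc_coords[None, :, :], axis=2)
    d_geo = geo_distance_matrix(geo, c.populations)
    mantel_r, mantel_p = mantel_test(d_pc, d_geo, n_perm=n_perm, seed=seed)
    t, p = procrustes_test(c.pc_coords[:, :2], c.geo_xy, n_perm=n_perm, seed=seed)
    return ConcordanceReport(
        spearman=spearman,
        best_angle_deg=angle,
        best_angle_rho=rho,
        mantel_r=mantel_r,
        mantel_p=mantel_p,
        procrustes_t=t,
        procrustes_p=p,
        n_permutations=n_perm,
    )
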