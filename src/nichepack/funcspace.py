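"""Reduced trait space and the two community metrics.

The species pool is embedded by classical principal coordinates analysis
(PCoA) of the Gower matrix, with a configurable negative-eigenvalue
correction (default: square-root transform of the distances). Functional
richness (FRic) is the convex-hull volume of a community's species in that
space; mean nearest-neighbour distance (MNND) is computed on the raw Gower
distances. Hull membership testing supports the constrained null model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import DimensionError
from .traits import DistanceMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10  # relative threshold for "positive" eigenvalues


@dataclass
class TraitSpace:
    """PCoA embedding of the species pool."""

    species: list[str]
    coords: np.ndarray  # (n_species, m)
    m: int
    eigenvalues: np.ndarray
    correction: str
    stress: float = math.nan
    _pool_volume: float | None = field(default=None, repr=False)

    def coords_for(self, species: Iterable[str]) -> np.ndarray:
        idx = [self.species.index(s) for s in species]
        return self.coords[idx]

    @property
    def pool_volume(self) -> float:
        if self._pool_volume is None:
            self._pool_volume = convex_hull_volume(self.coords)
        return self._pool_volume


@dataclass
class CommunityMetricValue:
    site_id: str | None
    metric: str  # {"FRic", "MNND"}
    value: float  # NaN when undefined
    richness: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


def _double_center(dsq: np.ndarray) -> np.ndarray:
    n = dsq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ dsq @ j


def _apply_correction(d: np.ndarray, correction: str) -> np.ndarray:
    off = ~np.eye(d.shape[0], dtype=bool)
    if correction == "none":
        return d
    if correction == "sqrt":
        return np.sqrt(d)
    if correction == "lingoes":
        evals = eigh(_double_center(d**2), eigvals_only=True)
        c = -evals.min()
        if c <= 0:
            return d
        out = d.copy()
        out[off] = np.sqrt(d[off] ** 2 + 2 * c)
        return out
    if correction == "cailliez":
        n = d.shape[0]
        b1 = _double_center(d**2)
        b2 = _double_center(d)
        upper = np.hstack([np.zeros((n, n)), 2 * b1])
        lower = np.hstack([-np.eye(n), -4 * b2])
        c = float(np.max(np.linalg.eigvals(np.vstack([upper, lower])).real))
        if c <= 0:
            return d
        out = d.copy()
        out[off] = d[off] + c
        return out
    raise ValueError(f"unknown correction {correction!r}")


def build_trait_space(
    d: DistanceMatrix,
    n_axes: int | str = "auto",
    correction: str = "sqrt",
    min_community_richness: int | None = None,
) -> TraitSpace:
    """Classical PCoA of a distance matrix, keeping ``m`` axes.

    With ``n_axes="auto"``, m = min(3, S_min - 1) where S_min is the
    smallest analysed community richness (3 if not given). Raises
    :class:`DimensionError` when m exceeds the number of positive
    eigenvalues after correction.
    """
    n = len(d.labels)
    if n < 4:
        raise ValueError("need >= 4 species to build a trait space")
    dc = _apply_correction(d.d, correction)
    evals, evecs = eigh(_double_center(dc**2))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > _EIG_TOL * max(evals.max(), 1.0)).sum())
    if n_axes == "auto":
        s_min = min_community_richness if min_community_richness is not None else 4
        m = min(3, s_min - 1, n_pos)
        if m < 2:
            raise DimensionError("fewer than 2 usable axes")
    else:
        m = int(n_axes)
        if m < 2 or m > n - 1:
            raise DimensionError(f"n_axes must be in [2, {n - 1}]")
        if m > n_pos:
            raise DimensionError(
                f"requested {m} axes but only {n_pos} positive eigenvalues"
            )
    coords = evecs[:, :m] * np.sqrt(evals[:m])
    coords -= coords.mean(axis=0)  # centre (already ~0 by construction)
    embedded = squareform(pdist(coords))
    mask = ~np.eye(n, dtype=bool)
    denom = (dc[mask] ** 2).sum()
    stress = math.sqrt(((embedded[mask] - dc[mask]) ** 2).sum() / denom) if denom else 0.0
    return TraitSpace(
        species=list(d.labels),
        coords=coords,
        m=m,
        eigenvalues=evals,
        correction=correction,
        stress=stress,
    )


def convex_hull_volume(points: np.ndarray) -> float:
    """Lebesgue measure of the convex hull (length/area/volume for m=1/2/3).

    Returns NaN (logged) for degenerate point sets; raises ``ValueError``
    when fewer than m+1 points are supplied.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    k, m = pts.shape
    if k < m + 1:
        raise ValueError(f"need at least m+1={m + 1} points, got {k}")
    if m == 1:
        return float(pts.max() - pts.min())
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        logger.info("degenerate point set: hull volume undefined")
        return math.nan


def fric(
    community_species: Sequence[str],
    space: TraitSpace,
    site_id: str | None = None,
    standardize: bool = True,
) -> CommunityMetricValue:
    """Convex-hull functional richness of a community in the trait space.

    Optionally standardized by the pool hull volume (in (0, 1]). Undefined
    (with a reason code) when S < m+1 or the community hull is degenerate.
    """
    comm = list(community_species)
    s = len(comm)
    if s < space.m + 1:
        return CommunityMetricValue(site_id, "FRic", math.nan, s, reason="S<m+1")
    vol = convex_hull_volume(space.coords_for(comm))
    if not math.isfinite(vol) or vol <= 0:
        return CommunityMetricValue(site_id, "FRic", math.nan, s, reason="degenerate_hull")
    if standardize:
        pool_vol = space.pool_volume
        if not math.isfinite(pool_vol) or pool_vol <= 0:
            return CommunityMetricValue(site_id, "FRic", math.nan, s, reason="degenerate_pool_hull")
        vol /= pool_vol
    return CommunityMetricValue(site_id, "FRic", vol, s)


def mnnd(
    community_species: Sequence[str],
    d: DistanceMatrix,
    site_id: str | None = None,
) -> CommunityMetricValue:
    """Mean over community members of the distance to the nearest other member.

    Computed directly on the Gower matrix, not on reduced coordinates.
    """
    comm = list(community_species)
    s = len(comm)
    if s < 2:
        return CommunityMetricValue(site_id, "MNND", math.nan, s, reason="S<2")
    sub = d.submatrix(comm).copy()
    np.fill_diagonal(sub, np.inf)
    return CommunityMetricValue(site_id, "MNND", float(sub.min(axis=1).mean()), s)


def in_hull(point: np.ndarray, hull_points: np.ndarray, tol: float = 1e-9) -> bool:
    """True iff ``point`` is a convex combination of ``hull_points`` (within tol).

    Boundary points count as inside. Degenerate hulls fall back to a
    membership test within the points' affine subspace (logged).
    """
    pts = np.asarray(hull_points, dtype=float)
    p = np.asarray(point, dtype=float)
    k, m = pts.shape
    if k < m + 1:
        raise ValueError(f"need at least m+1={m + 1} hull points, got {k}")
    if m == 1:
        return bool(pts.min() - tol <= p[0] <= pts.max() + tol)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        logger.info("degenerate hull: falling back to affine-subspace membership")
        return _in_hull_degenerate(p, pts, tol)
    return bool(np.all(hull.equations[:, :-1] @ p + hull.equations[:, -1] <= tol))


def _in_hull_degenerate(p: np.ndarray, pts: np.ndarray, tol: float) -> bool:
    """Membership test after projecting onto the points' affine span."""
    centre = pts.mean(axis=0)
    centred = pts - centre
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > max(s[0] if s.size else 0.0, 1.0) * 1e-12).sum())
    resid = (p - centre) - vt[:rank].T @ (vt[:rank] @ (p - centre))
    if np.linalg.norm(resid) > max(tol, 1e-9):
        return False
    if rank == 0:
        return True
    proj_pts = centred @ vt[:rank].T
    proj_p = vt[:rank] @ (p - centre)
    if rank == 1:
        return bool(proj_pts.min() - tol <= proj_p[0] <= proj_pts.max() + tol)
    try:
        hull = ConvexHull(proj_pts)
    except QhullError:
        return _in_hull_degenerate(proj_p, proj_pts, tol)
    return bool(np.all(hull.equations[:, :-1] @ proj_p + hull.equations[:, -1] <= tol))


def centroid_distances(space: TraitSpace) -> dict[str, float]:
    """Euclidean distance of every pool species to the pool centroid."""
    centre = space.coords.mean(axis=0)
    dists = np.linalg.norm(space.coords - centre, axis=1)
    return dict(zip(space.species, dists.astype(float)))
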