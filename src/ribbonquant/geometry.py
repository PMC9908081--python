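"""Exact 3D distance primitives for annotation geometry.

All coordinates are in nm, right-handed, z along the tomogram stacking
axis.  Surfaces are triangle meshes (vertices + faces) or point clouds;
distances to meshes use the exact point-to-triangle closest-point
computation (Ericson's barycentric-region algorithm) minimized over all
faces — not a vertex-only approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Surface",
    "closest_point_on_triangles",
    "point_surface_distance",
    "segment_intersects_sphere",
    "fit_plane",
]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point.

    Parameters
    ----------
    points : (n, 3)
    triangles : (m, 3, 3)

    Returns
    -------
    (n, m, 3) array of closest points.
    """
    p = np.asarray(points, dtype=float)[:, None, :]  # (n,1,3)
    tri = np.asarray(triangles, dtype=float)[None, :, :, :]  # (1,m,3,3)
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...k,...k", ab, ap)
    d2 = np.einsum("...k,...k", ac, ap)

    bp = p - b
    d3 = np.einsum("...k,...k", ab, bp)
    d4 = np.einsum("...k,...k", ac, bp)

    cp = p - c
    d5 = np.einsum("...k,...k", ab, cp)
    d6 = np.einsum("...k,...k", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        # interior (default)
        denom = va + vb + vc
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        out = a + ab * v[..., None] + ac * w[..., None]

        # edge BC
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        mask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        out = np.where(mask[..., None], b + (c - b) * t_bc[..., None], out)

        # edge AC
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        out = np.where(mask[..., None], a + ac * t_ac[..., None], out)

        # edge AB
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        out = np.where(mask[..., None], a + ab * t_ab[..., None], out)

    # vertex regions (highest priority)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    return out


@dataclass
class Surface:
    """A triangle mesh or point cloud annotation structure."""

    vertices: np.ndarray
    faces: np.ndarray | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
            if self.faces.size == 0:
                self.faces = None
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("surface coordinates must be finite")

    @property
    def is_mesh(self) -> bool:
        return self.faces is not None

    @property
    def is_empty(self) -> bool:
        return self.vertices.size == 0

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]  # (m,3,3)

    def centroid(self) -> np.ndarray:
        if self.is_mesh:
            tri = self.triangles
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            centers = tri.mean(axis=1)
            total = areas.sum()
            if total > 0:
                return (centers * areas[:, None]).sum(axis=0) / total
        return self.vertices.mean(axis=0)

    def closest_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(closest surface point, distance) for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.is_empty:
            raise ValueError("empty surface")
        if not self.is_mesh:
            if self._tree is None:
                self._tree = cKDTree(self.vertices)
            d, idx = self._tree.query(points)
            return self.vertices[idx], d
        # chunk over points to bound the (n, m, 3) intermediate
        tri = self.triangles
        closest = np.empty_like(points)
        dists = np.empty(points.shape[0])
        chunk = max(1, int(2_000_000 / max(1, tri.shape[0])))
        for s in range(0, points.shape[0], chunk):
            pts = points[s : s + chunk]
            cand = closest_point_on_triangles(pts, tri)  # (n,m,3)
            d2 = ((cand - pts[:, None, :]) ** 2).sum(axis=2)
            best = np.argmin(d2, axis=1)
            rows = np.arange(pts.shape[0])
            closest[s : s + chunk] = cand[rows, best]
            dists[s : s + chunk] = np.sqrt(d2[rows, best])
        return closest, dists


def point_surface_distance(point: np.ndarray, surface: Surface) -> float:
    """Euclidean distance from a point to the nearest point of a surface."""
    _, d = surface.closest_points(np.asarray(point, dtype=float)[None, :])
    return float(d[0])


def segment_intersects_sphere(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float
) -> bool:
    """True iff the segment p0→p1 passes through the (open) sphere."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    center = np.asarray(center, dtype=float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        return float(np.linalg.norm(center - p0)) < radius
    t = float(np.clip((center - p0) @ d / len2, 0.0, 1.0))
    nearest = p0 + t * d
    return float(np.linalg.norm(center - nearest)) < radius


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane through a point set.

    Returns (origin, u, v): the centroid and two orthonormal in-plane
    axes (principal components); the plane normal is u × v.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return origin, vt[0], vt[1]
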