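"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive every geometric predicate with different
algorithms from the package implementation: point-to-triangle distance
via barycentric interior test + segment distances (vs. the package's
Voronoi-region walk), segment-sphere intersection via the quadratic
discriminant, and a direct loop-based pool classifier.
"""

from __future__ import annotations

import numpy as np


def point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points p (n,3) to segment ab (broadcast over p)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def point_triangles_dist(p: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Distance from one point p (3,) to each triangle in tris (m,3,3).

    Interior case: barycentric coordinates of the plane projection via
    Cramer's rule; otherwise minimum over the three edge segments.
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = (n * n).sum(axis=1)
    ap = p - a
    # plane projection barycentric coords
    d00 = (ab * ab).sum(axis=1)
    d01 = (ab * ac).sum(axis=1)
    d11 = (ac * ac).sum(axis=1)
    d20 = (ap * ab).sum(axis=1)
    d21 = (ap * ac).sum(axis=1)
    denom = d00 * d11 - d01 * d01
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, (d11 * d20 - d01 * d21) / denom, -1.0)
        w = np.where(denom != 0, (d00 * d21 - d01 * d20) / denom, -1.0)
        plane_dist = np.where(nn > 0, np.abs((ap * n).sum(axis=1)) / np.sqrt(nn), np.inf)
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    edge = np.minimum.reduce(
        [
            point_segment_dist_batch(p, a, b),
            point_segment_dist_batch(p, a, c),
            point_segment_dist_batch(p, b, c),
        ]
    )
    return np.where(inside, plane_dist, edge)


def point_segment_dist_batch(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from one point p (3,) to each segment a[i]→b[i]."""
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    ap = p - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ap * ab).sum(axis=1) / denom, 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def surface_distance(point: np.ndarray, surface) -> float:
    """Exact distance to a Surface, oracle style."""
    point = np.asarray(point, dtype=float)
    if surface.is_mesh:
        return float(point_triangles_dist(point, surface.triangles).min())
    return float(np.linalg.norm(surface.vertices - point, axis=1).min())


def sampled_surface_points(surface, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-by-area random samples on a mesh (or the raw points)."""
    if not surface.is_mesh:
        return surface.vertices
    tris = surface.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    )
    probs = areas / areas.sum()
    idx = rng.choice(len(tris), size=n, p=probs)
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    t = tris[idx]
    return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])


def segment_hits_sphere(p0, p1, center, radius) -> bool:
    """Segment-sphere intersection via the quadratic discriminant."""
    p0, p1, center = (np.asarray(x, dtype=float) for x in (p0, p1, center))
    d = p1 - p0
    f = p0 - center
    A = float(d @ d)
    if A == 0:
        return float(np.linalg.norm(f)) < radius
    B = 2 * float(f @ d)
    C = float(f @ f) - radius**2
    disc = B * B - 4 * A * C
    if disc < 0:
        return False
    sq = np.sqrt(disc)
    t1, t2 = (-B - sq) / (2 * A), (-B + sq) / (2 * A)
    # open-ball intersection for some t in [0, 1]
    return (t1 < 1 and t2 > 0) and not (abs(disc) == 0)


def oracle_lateral_pd(vesicle, pd_surface, membrane, neighborhood_nm=150.0) -> float:
    """Lateral PD distance with the same projection convention,
    independently coded (covariance eigenvectors instead of SVD)."""
    mem = membrane.vertices
    near = mem[np.linalg.norm(mem - vesicle.center_nm, axis=1) <= neighborhood_nm]
    if near.shape[0] < 3:
        near = mem
    origin = near.mean(axis=0)
    cov = np.cov((near - origin).T)
    evals, evecs = np.linalg.eigh(cov)
    # two largest-eigenvalue directions span the plane
    axes = evecs[:, np.argsort(evals)[::-1][:2]]
    c2 = (vesicle.center_nm - origin) @ axes
    pd2 = (pd_surface.vertices - origin) @ axes
    d = float(np.linalg.norm(pd2 - c2, axis=1).min())
    return max(0.0, d - vesicle.radius_nm)


def oracle_classify(model, thresholds=None, first_row="occlusion"):
    """Direct loop evaluation of every pool predicate.

    Returns {vesicle_id: (pool, mp_subpool, ra_subpool)}.
    """
    from ribbonquant.tomo_quant import PoolThresholds

    th = thresholds or PoolThresholds()
    mem = model.az_membrane
    have_pd = model.pd is not None and not model.pd.is_empty
    have_rib = model.ribbon is not None and not model.ribbon.is_empty

    def seg_to(surface, v):
        # nearest surface point by dense evaluation
        if surface.is_mesh:
            tris = surface.triangles
            d = point_triangles_dist(v.center_nm, tris)
            k = int(np.argmin(d))
            # recover the closest point by projecting onto the best triangle
            target = _closest_on_triangle(v.center_nm, tris[k])
        else:
            idx = int(np.argmin(np.linalg.norm(surface.vertices - v.center_nm, axis=1)))
            target = surface.vertices[idx]
        dist = float(np.linalg.norm(target - v.center_nm))
        if dist <= v.radius_nm or dist == 0:
            return v.center_nm, target
        start = v.center_nm + (target - v.center_nm) * (v.radius_nm / dist)
        return start, target

    def blocked(v, surface):
        p0, p1 = seg_to(surface, v)
        for o in model.vesicles:
            if o is v:
                continue
            if segment_hits_sphere(p0, p1, o.center_nm, o.radius_nm):
                return True
        return False

    out = {}
    for v in model.vesicles:
        d_mem = max(0.0, surface_distance(v.center_nm, mem) - v.radius_nm)
        d_pd = oracle_lateral_pd(v, model.pd, mem) if have_pd else None
        d_rib = (
            max(0.0, surface_distance(v.center_nm, model.ribbon) - v.radius_nm)
            if have_rib
            else None
        )
        if v.clathrin_coated:
            out[v.id] = ("none", None, None)
            continue
        is_mp = d_mem <= th.mp_membrane_max and (
            d_pd is None or d_pd <= th.mp_pd_lateral_max
        )
        if is_mp and first_row == "occlusion":
            is_mp = not blocked(v, mem)
        if is_mp:
            if d_mem <= th.docked_max:
                sub = "docked"
            elif v.tethers:
                sub = "tethered"
            else:
                sub = "non_tethered"
            out[v.id] = ("MP", sub, None)
            continue
        is_ra = have_rib and d_rib is not None and d_rib <= th.ra_ribbon_max
        if is_ra and first_row == "occlusion":
            is_ra = not blocked(v, model.ribbon)
        if is_ra:
            targets = set(v.tethers)
            if "ribbon" in targets and "vesicle" in targets:
                sub = "attached_and_interconnected"
            elif "ribbon" in targets:
                sub = "ribbon_attached"
            elif "vesicle" in targets:
                sub = "interconnected"
            else:
                sub = "no_filaments"
            out[v.id] = ("RA", None, sub)
        else:
            out[v.id] = ("none", None, None)
    return out


def _closest_on_triangle(p, tri):
    """Closest point on one triangle (scalar oracle path)."""
    a, b, c = tri
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = float(n @ n)
    best = None
    if nn > 0:
        ap = p - a
        d00, d01, d11 = float(ab @ ab), float(ab @ ac), float(ac @ ac)
        d20, d21 = float(ap @ ab), float(ap @ ac)
        denom = d00 * d11 - d01 * d01
        if denom != 0:
            v = (d11 * d20 - d01 * d21) / denom
            w = (d00 * d21 - d01 * d20) / denom
            if v >= 0 and w >= 0 and v + w <= 1:
                return a + v * ab + w * ac
    for s, e in ((a, b), (a, c), (b, c)):
        se = e - s
        denom = float(se @ se)
        t = float(np.clip(((p - s) @ se) / denom, 0, 1)) if denom > 0 else 0.0
        cand = s + t * se
        if best is None or np.linalg.norm(p - cand) < np.linalg.norm(p - best):
            best = cand
    return best
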