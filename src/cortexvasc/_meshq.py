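"""Low-level triangle-mesh queries: closest point, ray-parity containment.

These are the geometric primitives behind the shell containment predicate.
The closest-point query is accelerated with a KD-tree on triangle centroids;
candidate triangles are re-checked exactly with the Eberly point/triangle
projection, and the candidate set is enlarged until the bound
``d_best <= d_centroid - r_max`` guarantees correctness.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each point.

    points: (n, 3); tri: (n, 3, 3) one triangle per point.
    Returns (n, 3) closest points.  Vectorized region-based projection.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    v = np.where(denom != 0, d1[m] / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    w = np.where(denom != 0, d2[m] / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    w = np.where(denom != 0, (d4[m] - d3[m]) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(denom == 0, 1.0, denom)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class TriangleQuery:
    """Exact closest point on a triangle soup, KD-tree accelerated."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.triangles = self.vertices[self.faces]  # (m, 3, 3)
        self.centroids = self.triangles.mean(axis=1)
        # max distance from a centroid to its triangle's vertices
        self.r_max = float(
            np.sqrt(
                ((self.triangles - self.centroids[:, None, :]) ** 2).sum(-1).max()
            )
        )
        self.tree = cKDTree(self.centroids)
        self._k0 = min(8, len(self.faces))

    def closest(self, points: np.ndarray):
        """Return (closest_points, distances, face_indices) for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        _, idx = self.tree.query(points, k=self._k0)
        idx = np.atleast_2d(idx)
        best_d2 = np.full(n, np.inf)
        best_cp = np.zeros((n, 3))
        best_f = np.zeros(n, dtype=np.int64)
        for j in range(idx.shape[1]):
            fj = idx[:, j]
            cp = _closest_on_triangles(points, self.triangles[fj])
            d2 = ((points - cp) ** 2).sum(-1)
            m = d2 < best_d2
            best_d2[m] = d2[m]
            best_cp[m] = cp[m]
            best_f[m] = fj[m]
        # enlarge candidate set where the centroid bound does not yet certify
        d_cent0 = np.linalg.norm(points - self.centroids[idx[:, -1]], axis=1)
        needs = np.sqrt(best_d2) > d_cent0 - self.r_max
        if needs.any() and self._k0 < len(self.faces):
            sub = np.flatnonzero(needs)
            radius = np.sqrt(best_d2[sub]) + self.r_max
            cand = self.tree.query_ball_point(points[sub], radius)
            for i, faces_i in zip(sub, cand):
                if not faces_i:
                    continue
                fi = np.asarray(faces_i, dtype=np.int64)
                cp = _closest_on_triangles(
                    np.repeat(points[i][None], len(fi), axis=0), self.triangles[fi]
                )
                d2 = ((points[i] - cp) ** 2).sum(-1)
                jbest = int(np.argmin(d2))
                if d2[jbest] < best_d2[i]:
                    best_d2[i] = d2[jbest]
                    best_cp[i] = cp[jbest]
                    best_f[i] = fi[jbest]
        return best_cp, np.sqrt(best_d2), best_f


_RAY_DIR = np.array([0.577350137, 0.211324871, 0.788675192])  # irrational-ish


def ray_parity_contains(vertices, faces, points, direction=_RAY_DIR,
                        chunk=4_000_000) -> np.ndarray:
    """Even-odd containment test by brute-force ray casting.

    Robust for closed (possibly multi-component, nested) triangle meshes as
    long as rays avoid edges; the default direction is chosen away from mesh
    symmetry axes.  O(n_points * n_faces), intended as an oracle and for
    moderate workloads.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = vertices[faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    d = direction / np.linalg.norm(direction)
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    n_pts, n_tri = len(points), len(faces)
    counts = np.zeros(n_pts, dtype=np.int64)
    rows_per_chunk = max(1, chunk // max(n_tri, 1))
    eps = 1e-12
    for s in range(0, n_pts, rows_per_chunk):
        p = points[s : s + rows_per_chunk]
        tvec = p[:, None, :] - v0[None, :, :]  # (np, nt, 3)
        u = np.einsum("ptj,tj->pt", tvec, pvec) * inv_det[None, :]
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("ptj,j->pt", qvec, d) * inv_det[None, :]
        t = np.einsum("ptj,tj->pt", qvec, e2) * inv_det[None, :]
        hit = (
            ok[None, :]
            & (u >= -eps)
            & (v >= -eps)
            & (u + v <= 1 + eps)
            & (t > eps)
        )
        counts[s : s + rows_per_chunk] = hit.sum(axis=1)
    return counts % 2 == 1


def point_segment_distance(points, seg_a, seg_b):
    """Pairwise-broadcast distance from points (n,3) to segments (m,3),(m,3).

    Returns (n, m) distances.
    """
    points = np.atleast_2d(points)
    ab = seg_b - seg_a  # (m,3)
    denom = (ab * ab).sum(-1)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - seg_a[None, :, :]  # (n,m,3)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom[None, :], 0.0, 1.0)
    closest = seg_a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=-1)
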