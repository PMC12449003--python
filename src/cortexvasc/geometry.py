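"""Perfusion shell domains over cortical surface meshes.

The pial arterial network lives in a thin shell obtained by extruding the
pial surface along its unit normals: every point of the shell is
``x = x_s + xi * n(x_s)`` with the offset ``xi`` ranging over
``[-t_in, t_out]``.  The default thickness is 0.2 cm, split 75% outward and
25% inward of the surface.  This module builds such shells, answers
containment queries, partitions the shell into vascular territories by
Boolean intersection with user-supplied territorial solids, and co-registers
seed arterial networks onto the surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._meshq import TriangleQuery, ray_parity_contains

__all__ = [
    "ShellDomain",
    "Territory",
    "build_shell",
    "point_in_shell",
    "partition_territories",
    "register_tree",
    "make_synthetic_cortex_patch",
    "load_surface",
    "vertex_normals",
    "write_surface_vtk",
    "territory_report",
]


def load_surface(path, scale: float = 1.0) -> trimesh.Trimesh:
    """Read an STL/OFF/PLY surface; coordinates multiplied by ``scale`` to cm."""
    mesh = trimesh.load(path, force="mesh", process=False)
    if scale != 1.0:
        mesh = trimesh.Trimesh(mesh.vertices * scale, mesh.faces, process=False)
    return mesh


def vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Unit vertex normals as the area-weighted mean of incident face normals."""
    fn = np.asarray(mesh.face_normals)
    fa = np.asarray(mesh.area_faces)
    vn = np.zeros_like(np.asarray(mesh.vertices))
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn * fa[:, None])
    norm = np.linalg.norm(vn, axis=1)
    norm[norm == 0] = 1.0
    return vn / norm[:, None]


def _boundary_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    """Directed edges that belong to exactly one face (open-patch rim)."""
    edges = mesh.edges  # directed, per-face winding
    und = np.sort(edges, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return edges[counts[inv] == 1]


def _check_manifold(mesh: trimesh.Trimesh) -> None:
    und = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    bad = int((counts > 2).sum())
    if bad:
        raise ValueError(
            f"surface is non-manifold: {bad} edges shared by more than two faces"
        )


@dataclass
class ShellDomain:
    """Extruded perfusion volume around a base surface.

    Containment follows the offset rule: a point is inside when its distance
    to the base surface does not exceed the admissible offset on its side of
    the surface (outward ``t_out``, inward ``t_in``).  Boundary points count
    as inside.
    """

    base: trimesh.Trimesh
    t_in: float
    t_out: float
    boundary: trimesh.Trimesh
    normals: np.ndarray  # per-vertex unit normals of the base surface
    repair_report: dict = field(default_factory=dict)
    face_subset: np.ndarray | None = None  # indices into a parent shell's faces
    _query: TriangleQuery | None = None

    @property
    def thickness(self) -> float:
        return self.t_in + self.t_out

    @property
    def query(self) -> TriangleQuery:
        if self._query is None:
            self._query = TriangleQuery(self.base.vertices, self.base.faces)
        return self._query

    @property
    def area(self) -> float:
        """Base surface area in cm^2."""
        return float(self.base.area)

    @property
    def volume(self) -> float:
        """Signed volume enclosed by the extruded boundary mesh, cm^3."""
        return float(self.boundary.volume)

    def contains(self, points, tol: float = 1e-9) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cp, dist, fid = self.query.closest(points)
        normal = self.base.face_normals[fid]
        side = np.einsum("ij,ij->i", points - cp, normal)
        allowed = np.where(side >= 0, self.t_out, self.t_in)
        return dist <= allowed + tol

    def sample(self, n: int, rng: np.random.Generator,
               faces: np.ndarray | None = None) -> np.ndarray:
        """Uniform-ish interior points: area-weighted surface point + uniform
        offset along the local face normal."""
        if faces is None:
            faces = np.arange(len(self.base.faces))
        areas = self.base.area_faces[faces]
        fidx = faces[rng.choice(len(faces), size=n, p=areas / areas.sum())]
        tri = self.base.vertices[self.base.faces[fidx]]
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        pts = (
            tri[:, 0] * (1 - r1)[:, None]
            + tri[:, 1] * (r1 * (1 - r2))[:, None]
            + tri[:, 2] * (r1 * r2)[:, None]
        )
        xi = rng.uniform(-self.t_in, self.t_out, size=n)
        return pts + xi[:, None] * self.base.face_normals[fidx]

    def subset(self, face_indices: np.ndarray) -> "ShellDomain":
        """Restriction of the shell to a subset of base faces."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        if face_indices.size == 0:
            raise ValueError("empty face subset for shell restriction")
        sub = self.base.submesh([face_indices], append=True, repair=False)
        return build_shell(sub, self.thickness, self.t_out / self.thickness,
                           _face_subset=face_indices)


def _extrude(base: trimesh.Trimesh, normals: np.ndarray, t_in: float,
             t_out: float):
    """Closed boundary mesh of the extruded shell, plus a repair report."""
    v = np.asarray(base.vertices)
    f = np.asarray(base.faces)
    nv = len(v)
    outer_v = v + t_out * normals
    inner_v = v - t_in * normals
    verts = np.vstack([outer_v, inner_v])
    faces = [f, f[:, ::-1] + nv]
    closed = len(_boundary_edges(base)) == 0
    if not closed:
        rim = _boundary_edges(base)
        a, b = rim[:, 0], rim[:, 1]
        # outward side wall: (O_a, I_b, O_b), (O_a, I_a, I_b)
        side1 = np.stack([a, b + nv, b], axis=1)
        side2 = np.stack([a, a + nv, b + nv], axis=1)
        faces.extend([side1, side2])
    faces = np.vstack(faces)
    mesh = trimesh.Trimesh(verts, faces, process=False)

    report = {}
    areas = mesh.area_faces
    degenerate = areas < 1e-14
    report["degenerate_faces_removed"] = int(degenerate.sum())
    if degenerate.any():
        mesh.update_faces(~degenerate)
    # inward extrusion can invert faces where the offset exceeds the local
    # radius of curvature; count them so the caller can warn
    fn_base = base.face_normals
    inner_fn = trimesh.Trimesh(inner_v, f, process=False).face_normals
    inverted = int((np.einsum("ij,ij->i", fn_base, inner_fn) < 0).sum())
    report["inverted_inner_faces"] = inverted
    return mesh, report


def build_shell(surface: trimesh.Trimesh, thickness: float = 0.2,
                outward_fraction: float = 0.75,
                _face_subset=None) -> ShellDomain:
    """Extrude ``surface`` into a perfusion shell.

    Parameters
    ----------
    surface:
        Manifold triangulated surface (closed or an open patch), cm.
    thickness:
        Total shell thickness in cm (default 0.2 cm).
    outward_fraction:
        Fraction of the thickness placed on the outward-normal side
        (default 0.75, i.e. 0.15 cm outward / 0.05 cm inward).
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if not 0.0 <= outward_fraction <= 1.0:
        raise ValueError("outward_fraction must be in [0, 1]")
    _check_manifold(surface)
    t_out = outward_fraction * thickness
    t_in = thickness - t_out
    normals = vertex_normals(surface)
    boundary, report = _extrude(surface, normals, t_in, t_out)
    if report.get("inverted_inner_faces"):
        warnings.warn(
            "extrusion produced %d inverted faces; they were kept but the "
            "boundary may self-intersect locally" % report["inverted_inner_faces"],
            RuntimeWarning,
            stacklevel=2,
        )
    return ShellDomain(
        base=surface,
        t_in=t_in,
        t_out=t_out,
        boundary=boundary,
        normals=normals,
        repair_report=report,
        face_subset=None if _face_subset is None else np.asarray(_face_subset),
    )


def point_in_shell(domain: ShellDomain, p) -> bool | np.ndarray:
    """True iff ``p`` lies inside the extruded shell (boundary counts inside)."""
    p = np.asarray(p, dtype=float)
    res = domain.contains(np.atleast_2d(p))
    return bool(res[0]) if p.ndim == 1 else res


@dataclass
class Territory:
    """Shell restriction to one vascular territory (e.g. ACA/MCA/PCA)."""

    label: str
    shell: ShellDomain
    q_inlet_ml_min: float

    @property
    def area(self) -> float:
        return self.shell.area

    @property
    def volume(self) -> float:
        return self.shell.volume


def partition_territories(domain: ShellDomain, solids, flows,
                          labels=None) -> list[Territory]:
    """Intersect the shell with closed territorial solids.

    Each territory keeps the base-surface triangles whose centroid falls
    inside the corresponding solid (discrete Boolean intersection).
    Overlaps between adjacent territories are allowed; the aggregate overlap
    fraction is reported on each territory's shell ``repair_report``.
    """
    if len(solids) != len(flows):
        raise ValueError("one inlet flow per territorial solid is required")
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(len(solids))]
    centroids = domain.base.triangles_center
    territories = []
    covered = np.zeros(len(centroids), dtype=np.int64)
    for label, solid, q in zip(labels, solids, flows):
        inside = ray_parity_contains(solid.vertices, solid.faces, centroids)
        if not inside.any():
            raise ValueError(f"territorial solid {label!r} does not intersect the shell")
        covered += inside
        shell = domain.subset(np.flatnonzero(inside))
        territories.append(Territory(label=label, shell=shell, q_inlet_ml_min=q))
    total = sum(t.volume for t in territories)
    overlap = max(0.0, total - domain.volume)
    for t in territories:
        t.shell.repair_report["overlap_fraction"] = overlap / domain.volume
    return territories


def _best_fit_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("landmarks are collinear; cannot fit a plane")
    return vt[2]


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def register_tree(tree, source_landmarks, target_landmarks, target_surface=None,
                  projection_warn: float = 0.5):
    """Co-register a seed network onto a target surface.

    Applies, in order: centroid translation, a Rodrigues rotation aligning
    the best-fit-plane normals of the two landmark sets, per-axis scaling by
    the ratio of coordinate standard deviations, and (when ``target_surface``
    is given) projection of every node onto the median offset surface of the
    shell (or onto the surface itself if a plain mesh is passed).
    """
    src = np.asarray(source_landmarks, dtype=float)
    tgt = np.asarray(target_landmarks, dtype=float)
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("at least 3 landmarks are required on each side")
    n_src = _best_fit_normal(src)
    n_tgt = _best_fit_normal(tgt)
    if np.dot(n_src, n_tgt) < 0:
        n_tgt = -n_tgt

    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    axis = np.cross(n_src, n_tgt)
    if np.linalg.norm(axis) < 1e-12:
        rot = np.eye(3)
    else:
        angle = float(np.arccos(np.clip(np.dot(n_src, n_tgt), -1.0, 1.0)))
        rot = _rodrigues(axis, angle)

    rot_src = (src - c_src) @ rot.T
    std_src = rot_src.std(axis=0)
    std_tgt = (tgt - c_tgt).std(axis=0)
    scale = np.where(std_src > 1e-12, std_tgt / np.where(std_src > 1e-12, std_src, 1.0), 1.0)

    def xform(points):
        return ((points - c_src) @ rot.T) * scale + c_tgt

    out = tree.copy()
    out.set_coordinates(xform(out.proximal), xform(out.distal))

    if target_surface is not None:
        if isinstance(target_surface, ShellDomain):
            offset = 0.5 * (target_surface.t_out - target_surface.t_in)
            median = trimesh.Trimesh(
                np.asarray(target_surface.base.vertices)
                + offset * target_surface.normals,
                target_surface.base.faces,
                process=False,
            )
        else:
            median = target_surface
        tq = TriangleQuery(median.vertices, median.faces)
        for attr in ("proximal", "distal"):
            pts = getattr(out, attr)
            cp, dist, _ = tq.closest(pts)
            if (dist > projection_warn).any():
                warnings.warn(
                    "projection moved %d nodes farther than %.3g cm"
                    % (int((dist > projection_warn).sum()), projection_warn),
                    RuntimeWarning,
                    stacklevel=2,
                )
            if attr == "proximal":
                new_prox = cp
            else:
                new_dist = cp
        out.set_coordinates(new_prox, new_dist)
    return out


def make_synthetic_cortex_patch(extent: float, gyrus_wavelength: float = 2.0,
                                gyrus_amplitude: float = 0.25, seed: int = 0,
                                target_edge: float = 0.1) -> trimesh.Trimesh:
    """Sinusoidally folded square patch emulating gyral/sulcal folding.

    The height field ``z = a sin(2 pi x / w + p1) sin(2 pi y / w + p2)`` uses
    random phases drawn from ``seed``; ``gyrus_amplitude = 0`` yields a flat
    patch of area ``extent**2`` exactly.
    """
    if extent <= 0 or gyrus_wavelength <= 0:
        raise ValueError("extents must be positive")
    if gyrus_amplitude < 0 or gyrus_amplitude >= gyrus_wavelength:
        raise ValueError("amplitude must be non-negative and below the wavelength")
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    n = max(8, int(round(extent / target_edge)))
    xs = np.linspace(0.0, extent, n + 1)
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    if gyrus_amplitude > 0:
        z = gyrus_amplitude * np.sin(2 * np.pi * xv / gyrus_wavelength + p1) * np.sin(
            2 * np.pi * yv / gyrus_wavelength + p2
        )
    else:
        z = np.zeros_like(xv)
    verts = np.column_stack([xv.ravel(), yv.ravel(), z.ravel()])

    def vid(i, j):
        return i * (n + 1) + j

    faces = []
    for i in range(n):
        for j in range(n):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return trimesh.Trimesh(verts, np.asarray(faces), process=False)


def write_surface_vtk(mesh: trimesh.Trimesh, path) -> None:
    """Write a triangulated surface as legacy ASCII VTK polydata."""
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncortexvasc surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write("%.17g %.17g %.17g\n" % tuple(p))
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write("3 %d %d %d\n" % tuple(tri))


def territory_report(territories, path=None):
    """Territory areas/volumes/overlap as a DataFrame (optionally CSV)."""
    import pandas as pd

    rows = [
        {
            "label": t.label,
            "area_cm2": t.area,
            "volume_cm3": t.volume,
            "overlap_fraction": t.shell.repair_report.get("overlap_fraction", 0.0),
            "q_inlet_ml_min": t.q_inlet_ml_min,
        }
        for t in territories
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
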