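"""Parametric thorax and oracle geometries for forward-ECG modelling.

Real torso meshes for this problem come from CT segmentation; here the
conductor is assembled from smooth parametric solids (ellipsoids and
elliptic cylinders) carrying the standard low-frequency tissue
conductivities: heart muscle 0.2 S/m, thoracic wall 0.1 S/m, blood
0.5 S/m, sub-diaphragm tissue 0.1 S/m and lungs 0.05 S/m.  The
coordinate frame follows the usual body convention used throughout the
package: x runs from the left to the right shoulder, y from back to
front, z from bottom to top, all lengths in metres.

Meshing is Delaunay-based: quasi-uniform points are laid out in the
interior and on every material interface, and ``scipy.spatial.Delaunay``
tetrahedralizes their convex hull (all outer solids used here are
convex).  Tetrahedra are labelled by the compartment containing their
centroid; because interface points are explicitly sampled, the labelled
interfaces converge to the parametric surfaces under refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "CompartmentSpec",
    "BoundarySurface",
    "SurfacePatch",
    "ThoraxMesh",
    "GeometryError",
    "MeshingError",
    "default_thorax_spec",
    "build_synthetic_thorax",
    "build_homogeneous_sphere",
    "extract_back_patch",
    "planar_disc_surface",
    "write_mesh_vtu",
    "write_surface_vtu",
]


class GeometryError(ValueError):
    """Invalid compartment geometry (overlap, containment, empty selection)."""


class MeshingError(RuntimeError):
    """Tetrahedralization failed or produced an invalid mesh."""


# --------------------------------------------------------------------------
# compartment specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentSpec:
    """One homogeneous tissue compartment.

    Parameters
    ----------
    name
        Compartment label, unique within a model.
    shape
        ``"ellipsoid"``, ``"cylinder"`` (elliptic cylinder with flat end
        caps, axis along z) or ``"zslab"`` (the part of the parent solid
        below ``center[2] + semi_axes[2]``; used for the sub-diaphragm
        region which shares the torso's lateral wall).
    center, semi_axes
        Centre and semi-axes in metres.  For a cylinder ``semi_axes``
        is (a, b, half-height); for a zslab only the implied top plane
        ``z_top = center[2] + semi_axes[2]`` matters.
    conductivity
        Tissue conductivity in S/m; must be positive.
    parent
        Name of the compartment this one is nested inside (``None`` for
        the outermost solid).
    """

    name: str
    shape: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    conductivity: float
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise GeometryError(f"{self.name}: conductivity must be > 0")
        if self.shape not in ("ellipsoid", "cylinder", "zslab"):
            raise GeometryError(f"{self.name}: unknown shape {self.shape!r}")
        if self.shape != "zslab" and min(self.semi_axes) <= 0:
            raise GeometryError(f"{self.name}: semi-axes must be > 0")

    # -- geometry predicates -------------------------------------------------

    @property
    def z_top(self) -> float:
        return self.center[2] + self.semi_axes[2]

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the solid, shrunk by ``margin`` m."""
        pts = np.atleast_2d(pts)
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        if self.shape == "ellipsoid":
            rho = np.linalg.norm((pts - c) / a, axis=1)
            return rho < 1.0 - margin / a.min()
        if self.shape == "cylinder":
            rho = np.hypot((pts[:, 0] - c[0]) / a[0], (pts[:, 1] - c[1]) / a[1])
            radial = rho < 1.0 - margin / min(a[0], a[1])
            axial = np.abs(pts[:, 2] - c[2]) < a[2] - margin
            return radial & axial
        # zslab: everything below the top plane (clipped by the parent solid
        # implicitly, since meshes never extend beyond the outermost solid)
        return pts[:, 2] < self.z_top - margin

    def near_surface(self, pts: np.ndarray, margin: float) -> np.ndarray:
        """Mask of points within ~``margin`` of the compartment surface."""
        pts = np.atleast_2d(pts)
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        if self.shape == "ellipsoid":
            rho = np.linalg.norm((pts - c) / a, axis=1)
            return np.abs(rho - 1.0) * a.min() < margin
        if self.shape == "cylinder":
            rho = np.hypot((pts[:, 0] - c[0]) / a[0], (pts[:, 1] - c[1]) / a[1])
            lateral = np.abs(rho - 1.0) * min(a[0], a[1]) < margin
            caps = np.abs(np.abs(pts[:, 2] - c[2]) - a[2]) < margin
            inside_r = rho < 1.0 + margin / min(a[0], a[1])
            return lateral | (caps & inside_r)
        return np.abs(pts[:, 2] - self.z_top) < margin

    @property
    def volume(self) -> float:
        """Analytic solid volume (zslab volume is parent-dependent: NaN)."""
        a, b, c = self.semi_axes
        if self.shape == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.shape == "cylinder":
            return np.pi * a * b * (2.0 * c)
        return float("nan")

    # -- surface sampling ----------------------------------------------------

    def surface_points(self, spacing: float, rng: np.random.Generator,
                       torso: "CompartmentSpec | None" = None) -> np.ndarray:
        """Quasi-uniform points on the compartment surface, ~``spacing`` apart."""
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        if self.shape == "ellipsoid":
            area = _ellipsoid_area(*a)
            n = max(48, int(round(area / spacing**2)))
            u = _fibonacci_sphere(n)
            return c + u * a
        if self.shape == "cylinder":
            return _cylinder_surface_points(c, a, spacing, rng)
        # zslab: the internal interface is the flat top plane clipped by the
        # torso cross-section
        if torso is None:
            raise GeometryError(f"{self.name}: zslab needs the torso spec")
        ta = np.asarray(torso.semi_axes)
        tc = np.asarray(torso.center)
        disc = _vogel_ellipse(ta[0], ta[1], spacing, include_rim=False)
        pts = np.column_stack([
            disc[:, 0] + tc[0], disc[:, 1] + tc[1],
            np.full(len(disc), self.z_top),
        ])
        return pts


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _vogel_ellipse(a: float, b: float, spacing: float,
                   include_rim: bool = True) -> np.ndarray:
    """Vogel-spiral points filling the ellipse x²/a²+y²/b² ≤ 1 (z omitted)."""
    area = np.pi * a * b
    n = max(16, int(round(area / spacing**2)))
    k = np.arange(n) + 0.5
    r = np.sqrt(k / n)
    th = np.pi * (3.0 - 5.0**0.5) * k
    pts = np.column_stack([a * r * np.cos(th), b * r * np.sin(th)])
    if include_rim:
        per = _ellipse_perimeter(a, b)
        m = max(8, int(round(per / spacing)))
        t = 2.0 * np.pi * np.arange(m) / m
        pts = np.vstack([pts, np.column_stack([a * np.cos(t), b * np.sin(t)])])
    return pts


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation — ample for point budgeting
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    # Thomsen's approximation (p = 1.6075)
    p = 1.6075
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _cylinder_surface_points(c: np.ndarray, a: np.ndarray, spacing: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Lateral wall, caps and rim rings of an elliptic cylinder."""
    ax, ay, hz = a
    per = _ellipse_perimeter(ax, ay)
    ntheta = max(12, int(round(per / spacing)))
    nz = max(2, int(round(2.0 * hz / spacing)))
    zs = np.linspace(-hz, hz, nz + 1)[1:-1]
    pts = []
    for i, z in enumerate(zs):
        off = 0.5 * (i % 2)  # stagger rings to avoid cocircular degeneracy
        t = 2.0 * np.pi * (np.arange(ntheta) + off) / ntheta
        t = t + rng.uniform(-0.1, 0.1, ntheta) * (2.0 * np.pi / ntheta)
        ring = np.column_stack([
            ax * np.cos(t) + c[0], ay * np.sin(t) + c[1],
            np.full(ntheta, z + c[2]),
        ])
        pts.append(ring)
    for z in (-hz, hz):
        disc = _vogel_ellipse(ax, ay, spacing)
        pts.append(np.column_stack([
            disc[:, 0] + c[0], disc[:, 1] + c[1],
            np.full(len(disc), z + c[2]),
        ]))
    return np.vstack(pts)


# --------------------------------------------------------------------------
# boundary surface and patches
# --------------------------------------------------------------------------

class BoundarySurface:
    """Oriented triangulated closed (or synthetic open) surface.

    Vertices are stored in their own index space; ``mesh_vertex_ids``
    maps them back to the parent volume mesh when one exists.  Normals
    are outward unit vectors; per-vertex normals are area-weighted
    averages of the incident triangle normals.
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray,
                 cap_mask: np.ndarray | None = None,
                 mesh_vertex_ids: np.ndarray | None = None):
        self.vertices = np.asarray(vertices, float)
        self.triangles = np.asarray(triangles, int)
        m = len(self.triangles)
        self.cap_mask = (np.zeros(m, bool) if cap_mask is None
                         else np.asarray(cap_mask, bool))
        self.mesh_vertex_ids = mesh_vertex_ids
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise MeshingError("degenerate boundary triangle")
        self.triangle_normals = cross / norm[:, None]
        self.triangle_areas = 0.5 * norm
        self.triangle_centroids = v[t].mean(axis=1)
        vn = np.zeros_like(v)
        w = (self.triangle_areas[:, None] * self.triangle_normals)
        for k in range(3):
            np.add.at(vn, t[:, k], w)
        vnorm = np.linalg.norm(vn, axis=1)
        vnorm[vnorm == 0] = 1.0
        self.vertex_normals = vn / vnorm[:, None]
        # per-vertex one-third area of the incident triangle star
        va = np.zeros(len(v))
        for k in range(3):
            np.add.at(va, t[:, k], self.triangle_areas / 3.0)
        self.vertex_areas = va

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        return float(self.triangle_areas.sum())

    def patch_from_triangles(self, tri_idx: np.ndarray) -> "SurfacePatch":
        tri_idx = np.asarray(tri_idx, int)
        if tri_idx.size == 0:
            raise GeometryError("empty surface patch")
        t = self.triangles[tri_idx]
        verts = np.unique(t)
        pos = {v: i for i, v in enumerate(verts)}
        w = np.zeros(len(verts))
        for k in range(3):
            for tid, vid in zip(tri_idx, t[:, k]):
                w[pos[vid]] += self.triangle_areas[tid] / 3.0
        return SurfacePatch(self, verts, tri_idx, w)

    def patch_within(self, center: np.ndarray, radius: float) -> "SurfacePatch":
        """Patch of triangles whose centroid lies within ``radius`` of ``center``."""
        d = np.linalg.norm(self.triangle_centroids - np.asarray(center), axis=1)
        return self.patch_from_triangles(np.flatnonzero((d <= radius) & ~self.cap_mask))


@dataclass
class SurfacePatch:
    """Subset of a boundary surface with per-vertex area weights.

    ``weights[i]`` is one third of the area of the patch triangles
    incident to vertex ``vertex_idx[i]``, so the weights sum exactly to
    the patch area.
    """

    surface: BoundarySurface
    vertex_idx: np.ndarray
    triangle_idx: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise GeometryError("non-positive patch area weight")

    @property
    def area(self) -> float:
        return float(self.weights.sum())

    @property
    def vertices(self) -> np.ndarray:
        return self.surface.vertices[self.vertex_idx]

    @property
    def centroid(self) -> np.ndarray:
        return (self.vertices * self.weights[:, None]).sum(0) / self.weights.sum()


# --------------------------------------------------------------------------
# volume mesh
# --------------------------------------------------------------------------

class ThoraxMesh:
    """Labelled tetrahedral volume conductor.

    Attributes
    ----------
    vertices : (N, 3) float
    tets : (T, 4) int — positively oriented
    labels : (T,) int — indices into ``label_names``
    label_names : list of compartment names
    conductivity_map : dict name → S/m
    boundary : BoundarySurface (closed, outward-oriented)
    boundary_owner : (M,) int — owning tet of each boundary triangle
    """

    def __init__(self, vertices, tets, labels, label_names, conductivity_map,
                 resolution: float | None = None):
        self.vertices = np.asarray(vertices, float)
        self.tets = np.asarray(tets, int)
        self.labels = np.asarray(labels, int)
        self.label_names = list(label_names)
        self.conductivity_map = dict(conductivity_map)
        self.resolution = resolution
        missing = set(self.label_names) - set(self.conductivity_map)
        if missing:
            raise GeometryError(f"labels without conductivity: {sorted(missing)}")
        self._orient()
        self._extract_boundary()
        self._tet_tree: cKDTree | None = None

    # -- construction helpers ------------------------------------------------

    def _orient(self) -> None:
        v = self.vertices
        t = self.tets
        d = np.einsum("ij,ij->i",
                      np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]),
                      v[t[:, 3]] - v[t[:, 0]])
        flip = d < 0
        self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]
        vol = np.abs(d) / 6.0
        if np.any(vol <= 0):
            raise MeshingError("zero-volume tetrahedron after orientation")
        self._volumes = vol

    def _extract_boundary(self) -> None:
        t = self.tets
        # local faces opposite each vertex, outward-oriented for positive tets
        faces = np.concatenate([
            t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]],
        ])
        owner = np.tile(np.arange(len(t)), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        key_sorted = key[order]
        dup = np.all(key_sorted[1:] == key_sorted[:-1], axis=1)
        # faces appear once (boundary) or twice (interior)
        shared = np.zeros(len(key), bool)
        shared[order[:-1][dup]] = True
        shared[order[1:][dup]] = True
        bmask = ~shared
        # sanity: no face may appear more than twice
        if len(key_sorted) > 2:
            tri_dup = dup[1:] & dup[:-1]
            if np.any(tri_dup):
                raise MeshingError("non-manifold face shared by >2 tets")
        bfaces = faces[bmask]
        bowner = owner[bmask]
        verts_used = np.unique(bfaces)
        remap = -np.ones(len(self.vertices), int)
        remap[verts_used] = np.arange(len(verts_used))
        self.boundary = BoundarySurface(
            self.vertices[verts_used], remap[bfaces],
            mesh_vertex_ids=verts_used)
        self.boundary_owner = bowner

    # -- queries --------------------------------------------------------------

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return self._volumes

    @property
    def volume(self) -> float:
        return float(self._volumes.sum())

    def tet_conductivity(self) -> np.ndarray:
        sig = np.array([self.conductivity_map[n] for n in self.label_names])
        return sig[self.labels]

    def label_volumes(self) -> dict[str, float]:
        out = {}
        for i, name in enumerate(self.label_names):
            out[name] = float(self._volumes[self.labels == i].sum())
        return out

    def tet_centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def locate(self, point: np.ndarray, k: int = 64) -> tuple[int, np.ndarray]:
        """Containing tet id and barycentric coordinates of ``point``.

        Searches the tets nearest by centroid; raises ``GeometryError``
        if the point lies outside the mesh.
        """
        if self._tet_tree is None:
            self._tet_tree = cKDTree(self.tet_centroids())
        point = np.asarray(point, float)
        k = min(k, self.n_tets)
        _, cand = self._tet_tree.query(point, k=k)
        cand = np.atleast_1d(cand)
        best = None
        for tid in cand:
            lam = self._barycentric(int(tid), point)
            if lam.min() >= -1e-10:
                return int(tid), np.clip(lam, 0.0, None)
            m = lam.min()
            if best is None or m > best[1]:
                best = (int(tid), m, lam)
        # fall back to a full scan before declaring "outside"
        for tid in range(self.n_tets):
            lam = self._barycentric(tid, point)
            if lam.min() >= -1e-10:
                return tid, np.clip(lam, 0.0, None)
        raise GeometryError(f"point {point} lies outside the mesh")

    def _barycentric(self, tid: int, point: np.ndarray) -> np.ndarray:
        verts = self.vertices[self.tets[tid]]
        mat = np.column_stack([verts[1] - verts[0], verts[2] - verts[0],
                               verts[3] - verts[0]])
        rhs = point - verts[0]
        lam123 = np.linalg.solve(mat, rhs)
        return np.concatenate([[1.0 - lam123.sum()], lam123])

    def set_cap_triangles(self, mask: np.ndarray) -> None:
        self.boundary.cap_mask = np.asarray(mask, bool)


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def default_thorax_spec() -> list[CompartmentSpec]:
    """Stylized seated-adult thorax with the five standard compartments.

    The torso is an elliptic cylinder (half-width 0.17 m, half-depth
    0.12 m, half-height 0.21 m, i.e. ~42 cm of trunk) sized so the heart
    base at (0.1, 0.03, 0) m sits inside it; lungs are dorsal ellipsoids
    flanking the heart, blood a concentric ellipsoid inside the heart
    wall, and the sub-diaphragm region everything below z = -0.10 m.
    """
    return [
        CompartmentSpec("thoracic_wall", "cylinder", (0.0, 0.0, 0.0),
                        (0.17, 0.12, 0.21), 0.1),
        CompartmentSpec("heart", "ellipsoid", (0.10, 0.03, 0.0),
                        (0.055, 0.045, 0.065), 0.2, parent="thoracic_wall"),
        CompartmentSpec("blood", "ellipsoid", (0.10, 0.03, 0.0),
                        (0.0341, 0.0279, 0.0403), 0.5, parent="heart"),
        CompartmentSpec("lung_left", "ellipsoid", (-0.08, -0.05, 0.08),
                        (0.040, 0.045, 0.115), 0.05, parent="thoracic_wall"),
        CompartmentSpec("lung_right", "ellipsoid", (0.08, -0.05, 0.08),
                        (0.040, 0.045, 0.115), 0.05, parent="thoracic_wall"),
        CompartmentSpec("abdomen", "zslab", (0.0, 0.0, -0.155),
                        (0.17, 0.12, 0.055), 0.1, parent="thoracic_wall"),
    ]


def _validate_spec(spec: Sequence[CompartmentSpec]) -> CompartmentSpec:
    by_name = {s.name: s for s in spec}
    roots = [s for s in spec if s.parent is None]
    if len(roots) != 1:
        raise GeometryError("exactly one outermost compartment required")
    torso = roots[0]
    rng = np.random.default_rng(0)

    def ancestors(s: CompartmentSpec) -> set[str]:
        out, cur = set(), s
        while cur.parent is not None:
            out.add(cur.parent)
            cur = by_name[cur.parent]
        return out

    # containment: sampled surface of each child inside its parent chain
    for s in spec:
        if s.parent is None or s.shape == "zslab":
            continue
        pts = s.surface_points(min(s.semi_axes) / 4.0, rng)
        for anc in ancestors(s):
            if not np.all(by_name[anc].contains(pts, margin=-1e-9)):
                raise GeometryError(
                    f"compartment {s.name!r} not contained in {anc!r}")
    # non-nested compartments must not overlap
    solids = [s for s in spec if s.shape != "zslab" and s.parent is not None]
    for i, a in enumerate(solids):
        for b in solids[i + 1:]:
            if a.name in ancestors(b) or b.name in ancestors(a):
                continue
            pa = a.surface_points(min(a.semi_axes) / 4.0, rng)
            pb = b.surface_points(min(b.semi_axes) / 4.0, rng)
            inter = (np.any(b.contains(pa)) or np.any(a.contains(pb))
                     or np.any(a.contains(np.atleast_2d(b.center)))
                     or np.any(b.contains(np.atleast_2d(a.center))))
            if inter:
                raise GeometryError(
                    f"compartments {a.name!r} and {b.name!r} overlap "
                    "without a declared nesting")
    return torso


def _interior_grid(torso: CompartmentSpec, spec: Sequence[CompartmentSpec],
                   h: float, surf_margin: float,
                   rng: np.random.Generator) -> np.ndarray:
    c = np.asarray(torso.center)
    a = np.asarray(torso.semi_axes)
    lo, hi = c - a, c + a
    axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    g = g + rng.uniform(-0.15 * h, 0.15 * h, g.shape)
    keep = torso.contains(g, margin=surf_margin)
    for s in spec:
        keep &= ~s.near_surface(g, surf_margin)
    return g[keep]


def _label_order(spec: Sequence[CompartmentSpec]) -> list[CompartmentSpec]:
    by_name = {s.name: s for s in spec}

    def depth(s: CompartmentSpec) -> int:
        d, cur = 0, s
        while cur.parent is not None:
            d += 1
            cur = by_name[cur.parent]
        return d

    return sorted(spec, key=depth, reverse=True)


def _mesh_from_points(points: np.ndarray, spec: Sequence[CompartmentSpec],
                      resolution: float) -> ThoraxMesh:
    points = np.unique(np.round(points / 1e-9) * 1e-9, axis=0)
    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover - qhull failure path
        raise MeshingError(f"Delaunay tetrahedralization failed: {exc}") from exc
    tets = tri.simplices
    v = points
    d = np.einsum(
        "ij,ij->i",
        np.cross(v[tets[:, 1]] - v[tets[:, 0]], v[tets[:, 2]] - v[tets[:, 0]]),
        v[tets[:, 3]] - v[tets[:, 0]])
    vol = np.abs(d) / 6.0
    # drop numerically flat hull slivers (cocircular degeneracies)
    keep = vol > max(vol.max() * 1e-12, 1e-18)
    tets = tets[keep]
    cent = v[tets].mean(axis=1)
    ordered = _label_order(spec)
    names = [s.name for s in spec]
    labels = np.full(len(tets), names.index(ordered[-1].name))
    assigned = np.zeros(len(tets), bool)
    for s in ordered[:-1]:
        inside = s.contains(cent) & ~assigned
        labels[inside] = names.index(s.name)
        assigned |= inside
    cond = {s.name: s.conductivity for s in spec}
    return ThoraxMesh(v, tets, labels, names, cond, resolution=resolution)


def build_synthetic_thorax(spec: Sequence[CompartmentSpec] | None = None,
                           resolution: float = 0.015,
                           surface_resolution: float | None = None,
                           seed: int = 0) -> ThoraxMesh:
    """Build the labelled synthetic thorax mesh.

    Parameters
    ----------
    spec
        Compartment list; defaults to :func:`default_thorax_spec`.
        Must contain exactly one outermost solid.
    resolution
        Target interior edge length in metres.  Element count scales
        roughly as ``resolution**-3``.
    surface_resolution
        Target edge length on material interfaces and the outer
        boundary; defaults to ``resolution / 2`` (a graded mesh: finer
        where electrodes live and interfaces bend).
    seed
        Seed for the deterministic point jitter that prevents
        degenerate (cocircular) Delaunay configurations.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if spec is None:
        spec = default_thorax_spec()
    torso = _validate_spec(spec)
    hs = surface_resolution if surface_resolution is not None else resolution / 2.0
    rng = np.random.default_rng(seed)
    pts = [_interior_grid(torso, spec, resolution, 0.4 * min(resolution, 2 * hs), rng)]
    for s in spec:
        try:
            pts.append(s.surface_points(hs, rng, torso=torso))
        except Exception as exc:
            raise MeshingError(f"surface sampling failed for {s.name!r}: {exc}") from exc
    mesh = _mesh_from_points(np.vstack(pts), spec, resolution)
    if torso.shape == "cylinder":
        bc = mesh.boundary.triangle_centroids
        bn = mesh.boundary.triangle_normals
        z_top = torso.center[2] + torso.semi_axes[2]
        z_bot = torso.center[2] - torso.semi_axes[2]
        caps = (np.abs(bn[:, 2]) > 0.9) & (
            (np.abs(bc[:, 2] - z_top) < 0.05 * torso.semi_axes[2])
            | (np.abs(bc[:, 2] - z_bot) < 0.05 * torso.semi_axes[2]))
        mesh.set_cap_triangles(caps)
    return mesh


def build_homogeneous_sphere(radius: float = 0.1, conductivity: float = 0.2,
                             resolution: float = 0.008,
                             surface_resolution: float | None = None,
                             refine_radius: float | None = None,
                             refine_spacing: float | None = None,
                             seed: int = 0) -> ThoraxMesh:
    """Single-compartment ball mesh centred at the origin (analytic oracle).

    ``refine_radius``/``refine_spacing`` optionally grade the mesh with a
    finer point lattice inside a central ball — useful when a discrete
    source (monopole pair) must be resolved by elements much smaller
    than the bulk resolution.
    """
    if radius <= 0 or conductivity <= 0 or resolution <= 0:
        raise ValueError("radius, conductivity and resolution must be > 0")
    hs = surface_resolution if surface_resolution is not None else 0.75 * resolution
    rng = np.random.default_rng(seed)
    sphere = CompartmentSpec("sphere", "ellipsoid", (0.0, 0.0, 0.0),
                             (radius, radius, radius), conductivity)
    grid = _interior_grid(sphere, [sphere], resolution, 0.4 * min(resolution, 2 * hs), rng)
    pts = [grid]
    if refine_radius is not None:
        h2 = refine_spacing if refine_spacing is not None else resolution / 4.0
        ax = np.arange(-refine_radius, refine_radius + h2 / 2, h2)
        g2 = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        g2 = g2 + rng.uniform(-0.15 * h2, 0.15 * h2, g2.shape)
        g2 = g2[np.linalg.norm(g2, axis=1) < refine_radius]
        # thin out bulk points inside the refined ball
        pts = [grid[np.linalg.norm(grid, axis=1) >= refine_radius], g2]
    n_surf = max(64, int(round(4.0 * np.pi * radius**2 / hs**2)))
    surf = radius * _fibonacci_sphere(n_surf)
    return _mesh_from_points(np.vstack(pts + [surf]), [sphere], resolution)


def extract_back_patch(mesh: ThoraxMesh, y_fraction: float = 0.35,
                       z_band: tuple[float, float] | None = None) -> SurfacePatch:
    """Patch of the outer boundary on the subject's back.

    Selects boundary triangles (end caps excluded) whose centroid lies in
    the lowest ``y_fraction`` quantile of boundary y-coordinates — the
    back is the low-y side of the body frame, where backrest-embedded
    electrodes sit.  ``z_band`` optionally clips the patch to a height
    range, emulating the vertical extent of an armchair backrest.
    """
    if not 0.0 < y_fraction <= 0.5:
        raise ValueError("y_fraction must be in (0, 0.5]")
    b = mesh.boundary
    tri_cap = b.cap_mask
    vert_on_cap = np.zeros(b.n_vertices, bool)
    for k in range(3):
        vert_on_cap[b.triangles[tri_cap][:, k]] = True
    ys = b.vertices[~vert_on_cap, 1]
    if ys.size == 0:
        raise GeometryError("no non-cap boundary vertices")
    thresh = np.quantile(ys, y_fraction)
    sel_mask = ~tri_cap & (b.triangle_centroids[:, 1] <= thresh)
    if z_band is not None:
        cz = b.triangle_centroids[:, 2]
        sel_mask &= (cz >= z_band[0]) & (cz <= z_band[1])
    sel = np.flatnonzero(sel_mask)
    if sel.size == 0:
        raise GeometryError("back-patch selection is empty")
    return b.patch_from_triangles(sel)


def planar_disc_surface(radius: float, spacing: float) -> BoundarySurface:
    """Flat triangulated disc in the z=0 plane (synthetic test surface).

    Not derived from any volume mesh — a stand-alone surface used to
    exercise electrode operations on a controlled, nearly uniform
    triangulation with +z normals.
    """
    pts2 = _vogel_ellipse(radius, radius, spacing)
    tri = Delaunay(pts2)
    t = tri.simplices
    # enforce counter-clockwise orientation → +z normals
    v = pts2
    e1 = v[t[:, 1]] - v[t[:, 0]]
    e2 = v[t[:, 2]] - v[t[:, 0]]
    cr = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    flip = cr < 0
    t[flip] = t[flip][:, [0, 2, 1]]
    verts3 = np.column_stack([pts2, np.zeros(len(pts2))])
    return BoundarySurface(verts3, t)


# --------------------------------------------------------------------------
# VTK output
# --------------------------------------------------------------------------

def _vtu_array(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data)
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    if np.issubdtype(data.dtype, np.integer):
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.10g"
    body = "\n".join(" ".join(fmt % x for x in np.atleast_1d(row))
                     for row in data)
    return (f'{indent}<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n'
            f"{indent}</DataArray>\n")


def _write_vtu(path, points, cells, cell_type, point_data=None, cell_data=None):
    npts, ncells = len(points), len(cells)
    nodes_per = cells.shape[1]
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n'
                '<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncells}">\n')
        f.write("<Points>\n")
        f.write(_vtu_array("Points", points, ""))
        f.write("</Points>\n<Cells>\n")
        f.write(_vtu_array("connectivity", cells.ravel(), ""))
        f.write(_vtu_array("offsets", nodes_per * (np.arange(ncells) + 1), ""))
        f.write(_vtu_array("types", np.full(ncells, cell_type), ""))
        f.write("</Cells>\n")
        if point_data:
            f.write("<PointData>\n")
            for name, arr in point_data.items():
                f.write(_vtu_array(name, arr, ""))
            f.write("</PointData>\n")
        if cell_data:
            f.write("<CellData>\n")
            for name, arr in cell_data.items():
                f.write(_vtu_array(name, arr, ""))
            f.write("</CellData>\n")
        f.write("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def write_mesh_vtu(mesh: ThoraxMesh, path: str,
                   point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the tet mesh as ASCII .vtu plus a JSON conductivity sidecar."""
    _write_vtu(path, mesh.vertices, mesh.tets, 10,
               point_data=point_data, cell_data={"compartment": mesh.labels})
    sidecar = {
        "label_names": mesh.label_names,
        "conductivity_map": mesh.conductivity_map,
        "resolution": mesh.resolution,
    }
    with open(str(path) + ".json", "w") as f:
        json.dump(sidecar, f, indent=1)


def write_surface_vtu(surface: BoundarySurface, path: str,
                      point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a boundary surface (triangles) as ASCII .vtu."""
    _write_vtu(path, surface.vertices, surface.triangles, 5,
               point_data=point_data,
               cell_data={"is_cap": surface.cap_mask.astype(int)})
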