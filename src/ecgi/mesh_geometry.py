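"""Triangulated-surface geometry for the heart-torso model.

All meshes are closed, consistently oriented triangle surfaces.  The module
provides the synthetic phantom (torso, lungs, blood cavity and a thick-walled
half-ellipsoid ventricular "cup"), per-vertex areas, a cotangent
Laplace-Beltrami operator used by the timing regularizer, and surface
geodesic distances used by the fastest-route activation estimate.

Units: vertex coordinates are in meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TriSurface",
    "TorsoPhantom",
    "InvalidGeometryError",
    "make_sphere",
    "make_ellipsoid",
    "make_ventricle",
    "make_torso_phantom",
    "default_phantom_config",
    "surface_laplacian",
    "cotangent_weights",
    "geodesic_distances",
    "subdivide",
    "farthest_point_sample",
    "read_surface",
    "write_surface",
]

# vertex label codes used in PLY export and in the AccuracyReport splits
LABELS = ("epicardial", "endocardial", "basal")


class InvalidGeometryError(ValueError):
    """Raised when a surface or phantom violates a geometric invariant."""


@dataclass
class TriSurface:
    """A closed, consistently oriented triangle mesh.

    Attributes
    ----------
    vertices : (n, 3) float array, positions in meters.
    faces : (m, 3) int array, counter-clockwise seen from outside.
    labels : optional (n,) array of strings from :data:`LABELS`, used on the
        ventricular surface to split error metrics into endo/epi classes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area2 = np.linalg.norm(cross, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / area2[:, None]
        return normals, 0.5 * area2

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area a_i: one third of the incident face areas (m^2)."""
        _, fa = self.face_normals_areas()
        a = np.zeros(self.n_vertices)
        np.add.at(a, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return a

    def total_area(self) -> float:
        return float(self.face_normals_areas()[1].sum())

    def signed_volume(self) -> float:
        v = self.vertices
        f = self.faces
        return float(
            np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
            / 6.0
        )

    def edges_unique(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check closedness, manifoldness, orientation and non-degeneracy.

        Raises :class:`InvalidGeometryError` on the first violated invariant.
        """
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise InvalidGeometryError("face indices out of range")
        _, fa = self.face_normals_areas()
        if np.any(fa <= 0) or not np.all(np.isfinite(fa)):
            raise InvalidGeometryError("zero-area or degenerate faces present")
        # every directed edge must occur exactly once (closed + consistent)
        de = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = de[:, 0] * self.n_vertices + de[:, 1]
        if len(np.unique(key)) != len(key):
            raise InvalidGeometryError("duplicated directed edge (non-manifold)")
        rev = de[:, 1] * self.n_vertices + de[:, 0]
        if not np.isin(key, rev).all():
            raise InvalidGeometryError("boundary edge found: surface is not closed")
        if self.signed_volume() <= 0:
            raise InvalidGeometryError("inconsistent orientation (signed volume <= 0)")
        if self.labels is not None and len(self.labels) != self.n_vertices:
            raise InvalidGeometryError("label array length mismatch")


@dataclass
class TorsoPhantom:
    """Nested piecewise-homogeneous volume conductor with an EDL source surface.

    ``surfaces`` maps compartment names to closed surfaces; ``tissue`` maps
    each surface to the conductivity-set field that applies *inside* it
    (``thorax``, ``lungs``, ``blood``, ``heart``).  The ventricular cup
    (``heart``) doubles as the equivalent-dipole-layer source surface.
    ``electrodes`` are indices into the torso surface vertices.
    """

    surfaces: dict[str, TriSurface]
    tissue: dict[str, str]
    electrodes: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def torso(self) -> TriSurface:
        return self.surfaces["torso"]

    @property
    def heart(self) -> TriSurface:
        return self.surfaces["heart"]

    @property
    def electrode_positions(self) -> np.ndarray:
        return self.torso.vertices[self.electrodes]

    def validate(self) -> None:
        for name, s in self.surfaces.items():
            try:
                s.validate()
            except InvalidGeometryError as exc:
                raise InvalidGeometryError(f"surface {name!r}: {exc}") from exc
        inner = [n for n in self.surfaces if n != "torso"]
        for name in inner:
            if not contains_points(self.torso, self.surfaces[name].vertices).all():
                raise InvalidGeometryError(f"surface {name!r} is not inside the torso")
        # pairwise separation of the inner surfaces (none of our compartments
        # are nested inside each other apart from the torso envelope; the
        # blood cavity sits in the ventricular lumen, outside the wall solid)
        for i, a in enumerate(inner):
            for b in inner[i + 1 :]:
                if (
                    contains_points(self.surfaces[a], self.surfaces[b].vertices).any()
                    or contains_points(self.surfaces[b], self.surfaces[a].vertices).any()
                ):
                    raise InvalidGeometryError(f"surfaces {a!r} and {b!r} intersect")
        if self.electrodes.min() < 0 or self.electrodes.max() >= self.torso.n_vertices:
            raise InvalidGeometryError("electrode index outside torso surface")


def contains_points(surface: TriSurface, points: np.ndarray, block: int = 256) -> np.ndarray:
    """Point-in-closed-surface test by the generalized winding number.

    Exact for points away from the surface; robust to any convexity.
    """
    v, f = surface.vertices, surface.faces
    t = v[f]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    wind = np.empty(len(pts))
    for s in range(0, len(pts), block):
        x = pts[s : s + block]
        r = t[None, :, :, :] - x[:, None, None, :]
        n = np.linalg.norm(r, axis=3)
        r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        n1, n2, n3 = n[:, :, 0], n[:, :, 1], n[:, :, 2]
        num = np.einsum("bmi,bmi->bm", r1, np.cross(r2, r3))
        den = (
            n1 * n2 * n3
            + np.einsum("bmi,bmi->bm", r1, r2) * n3
            + np.einsum("bmi,bmi->bm", r1, r3) * n2
            + np.einsum("bmi,bmi->bm", r2, r3) * n1
        )
        wind[s : s + block] = 2.0 * np.arctan2(num, den).sum(axis=1)
    return wind > 2.0 * np.pi


# ---------------------------------------------------------------------------
# primitive surfaces


def make_sphere(radius: float, refinement: int = 2) -> TriSurface:
    """Icosphere with ``10 * 4**refinement + 2`` vertices."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_ellipsoid(
    semi_axes, center=(0.0, 0.0, 0.0), refinement: int = 2
) -> TriSurface:
    """Ellipsoid by anisotropic scaling of a unit icosphere."""
    s = make_sphere(1.0, refinement)
    v = s.vertices * np.asarray(semi_axes, dtype=float)
    return TriSurface(v + np.asarray(center, dtype=float), s.faces)


def make_ventricle(
    outer_semi_axes=(0.033, 0.033, 0.055),
    wall_thickness: float = 0.010,
    base_height: float = 0.0,
    target_vertices: int = 1500,
    center=(0.0, 0.0, 0.0),
) -> TriSurface:
    """Closed thick-walled half-ellipsoid cup modelling the ventricular surface.

    The cup consists of an outer (epicardial) half-ellipsoid shell with the
    apex pointing in -z, an inner (endocardial) shell offset by
    ``wall_thickness``, and an annular basal cap joining the two rims at
    ``z = base_height`` above the ellipsoid center.  Vertex labels partition
    into ``epicardial`` / ``endocardial`` / ``basal``.

    Representing endo + epi as a single closed surface makes the
    equivalent-dipole-layer null property exact: a spatially uniform source
    strength on this surface produces no external field.
    """
    a, b, c = (float(x) for x in outer_semi_axes)
    w = float(wall_thickness)
    if w >= min(a, b, c):
        raise InvalidGeometryError("wall thickness must be smaller than every semi-axis")
    ai, bi, ci = a - w, b - w, c - w
    zb = float(base_height)
    if not (0.0 <= zb < ci):
        raise InvalidGeometryError("base height must lie in [0, inner apex depth)")

    # ring/segment counts from the vertex budget: ~2 * (rings*segments + 1)
    seg = max(8, int(round(np.sqrt(1.5 * target_vertices))))
    rings = max(3, int(round((target_vertices / 2.0 - 1.0) / seg)))

    def shell(sa, sb, sc):
        """Half-ellipsoid point grid: apex + ``rings`` rings of ``seg`` points."""
        phi_base = np.arccos(np.clip(-zb / sc, -1.0, 1.0))  # polar angle of rim
        phis = np.linspace(np.pi, phi_base, rings + 1)[1:]  # apex (pi) -> rim
        az = np.linspace(0.0, 2.0 * np.pi, seg, endpoint=False)
        pts = [np.array([0.0, 0.0, -sc])]
        for p in phis:
            r = np.sin(p)
            ring = np.stack(
                [sa * r * np.cos(az), sb * r * np.sin(az), np.full(seg, sc * np.cos(p))],
                axis=1,
            )
            pts.append(ring)
        return np.vstack(pts)

    n_shell = rings * seg + 1
    outer = shell(a, b, c)
    inner = shell(ai, bi, ci)
    verts = np.vstack([outer, inner])
    inner_off = n_shell

    def ring_idx(shell_off, k):  # ring k in 0..rings-1
        return shell_off + 1 + k * seg + np.arange(seg)

    faces: list[tuple[int, int, int]] = []

    def cap(shell_off, flip):
        apex = shell_off
        r0 = ring_idx(shell_off, 0)
        for j in range(seg):
            tri = (apex, r0[j], r0[(j + 1) % seg])
            faces.append(tri[::-1] if flip else tri)
        for k in range(rings - 1):
            ra, rb = ring_idx(shell_off, k), ring_idx(shell_off, k + 1)
            for j in range(seg):
                jn = (j + 1) % seg
                quads = [(ra[j], rb[j], rb[jn]), (ra[j], rb[jn], ra[jn])]
                for tri in quads:
                    faces.append(tri[::-1] if flip else tri)

    # outer shell: outward normals point away from the wall solid; inner shell
    # normals point into the lumen (outward of the wall), hence flipped winding
    cap(0, flip=False)
    cap(inner_off, flip=True)

    # basal annulus between the two rims
    ro = ring_idx(0, rings - 1)
    ri = ring_idx(inner_off, rings - 1)
    for j in range(seg):
        jn = (j + 1) % seg
        faces.append((ro[j], ri[j], ri[jn]))
        faces.append((ro[j], ri[jn], ro[jn]))

    labels = np.empty(len(verts), dtype=object)
    labels[:n_shell] = "epicardial"
    labels[inner_off:] = "endocardial"
    labels[ring_idx(0, rings - 1)] = "basal"
    labels[ring_idx(inner_off, rings - 1)] = "basal"

    surf = TriSurface(verts + np.asarray(center, dtype=float), np.asarray(faces), labels)
    if surf.signed_volume() < 0:
        surf = TriSurface(surf.vertices, surf.faces[:, ::-1], labels)
    surf.validate()
    return surf


def default_phantom_config() -> dict:
    """Desk-scale study phantom: torso, two lungs, ventricular cup, blood cavity.

    Compartment list mirrors a human thorax model (thorax, lungs, myocardium,
    intracavitary blood); the geometry itself is stylized.  The ventricular
    cup is deliberately coarse (~400 nodes) to keep repeated inverse solves
    fast; the gold-standard simulator refines it by subdivision.
    """
    return {
        "torso": {"center": [0.0, 0.0, 0.0], "semi_axes": [0.14, 0.11, 0.30], "refinement": 3},
        "lung_left": {"center": [0.085, 0.0, 0.05], "semi_axes": [0.042, 0.065, 0.16], "refinement": 2},
        "lung_right": {"center": [-0.085, 0.0, 0.05], "semi_axes": [0.042, 0.065, 0.16], "refinement": 2},
        "heart": {
            "center": [0.0, -0.035, 0.06],
            "outer_semi_axes": [0.033, 0.033, 0.055],
            "wall_thickness": 0.010,
            "base_height": 0.0,
            "target_vertices": 400,
        },
        "blood": {"center": [0.0, -0.035, 0.038], "semi_axes": [0.013, 0.013, 0.016], "refinement": 2},
        "n_electrodes": 120,
    }


def make_torso_phantom(config: dict | None = None) -> TorsoPhantom:
    """Build and validate the nested torso phantom from a config mapping.

    The config follows :func:`default_phantom_config`; unknown compartments
    are rejected.  Electrodes are spread quasi-uniformly over the torso
    surface by farthest-point sampling.
    """
    cfg = default_phantom_config()
    if config:
        for k, v in config.items():
            if k not in cfg:
                raise ValueError(f"unknown phantom config key {k!r}")
            if isinstance(v, dict):
                cfg[k] = {**cfg[k], **v}
            else:
                cfg[k] = v

    h = cfg["heart"]
    surfaces = {
        "torso": make_ellipsoid(**cfg["torso"]),
        "lung_left": make_ellipsoid(**cfg["lung_left"]),
        "lung_right": make_ellipsoid(**cfg["lung_right"]),
        "heart": make_ventricle(
            outer_semi_axes=h["outer_semi_axes"],
            wall_thickness=h["wall_thickness"],
            base_height=h["base_height"],
            target_vertices=h["target_vertices"],
            center=h["center"],
        ),
        "blood": make_ellipsoid(**cfg["blood"]),
    }
    tissue = {
        "torso": "thorax",
        "lung_left": "lungs",
        "lung_right": "lungs",
        "heart": "heart",
        "blood": "blood",
    }
    electrodes = farthest_point_sample(surfaces["torso"].vertices, int(cfg["n_electrodes"]))
    phantom = TorsoPhantom(surfaces, tissue, electrodes, cfg)
    phantom.validate()
    return phantom


def farthest_point_sample(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subset of ``points`` (indices)."""
    if k > len(points):
        raise ValueError("cannot sample more points than available")
    idx = np.empty(k, dtype=np.int64)
    idx[0] = int(np.argmax(points[:, 1]))  # start on the anterior chest wall
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for i in range(1, k):
        idx[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[idx[i]], axis=1))
    return idx


# ---------------------------------------------------------------------------
# differential operators


def cotangent_weights(surface: TriSurface) -> sp.csr_matrix:
    """Symmetric cotangent weight matrix W (off-diagonal w_ij, zero diagonal)."""
    v, f = surface.vertices, surface.faces
    n = surface.n_vertices
    # half-cotangent of the angle opposite each directed edge, symmetrized
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    o = np.concatenate([f[:, 2], f[:, 0], f[:, 1]])
    u = v[i] - v[o]
    w = v[j] - v[o]
    cot = 0.5 * np.einsum("ij,ij->i", u, w) / np.linalg.norm(np.cross(u, w), axis=1)
    W = sp.coo_matrix((cot, (i, j)), shape=(n, n))
    W = (W + W.T).tocsr()
    return W


def surface_laplacian(surface: TriSurface) -> sp.csr_matrix:
    """Area-normalized cotangent Laplace-Beltrami operator L (units 1/m^2).

    ``(L f)_i = (1/a_i) * sum_j w_ij (f_j - f_i)`` approximates the surface
    Laplacian of f at vertex i; rows sum to zero by construction.
    """
    surface.validate()
    W = cotangent_weights(surface)
    a = surface.vertex_areas()
    d = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(1.0 / a) @ (W - sp.diags(d))
    return L.tocsr()


# ---------------------------------------------------------------------------
# geodesics


def _shortcut_edges(surface: TriSurface) -> tuple[np.ndarray, np.ndarray]:
    """One-ring shortcut edges: for every interior mesh edge, connect the two
    opposite vertices with the length of the straight segment in the unfolded
    pair of triangles (only when that segment actually crosses the shared
    edge).  This markedly reduces the metrication error of edge-graph
    Dijkstra on irregular meshes."""
    v, f = surface.vertices, surface.faces
    # map sorted edge -> (opposite vertices)
    edges = {}
    for tri in f:
        for k in range(3):
            a, b, o = tri[k], tri[(k + 1) % 3], tri[(k + 2) % 3]
            key = (min(a, b), max(a, b))
            edges.setdefault(key, []).append(o)
    src, dst, lens = [], [], []
    for (a, b), opp in edges.items():
        if len(opp) != 2:
            continue
        c, d = opp
        ab = np.linalg.norm(v[b] - v[a])
        # planar unfold: a=(0,0), b=(ab,0)
        def unfold(p, sign):
            la = np.linalg.norm(v[p] - v[a])
            lb = np.linalg.norm(v[p] - v[b])
            x = (la * la - lb * lb + ab * ab) / (2.0 * ab)
            y2 = max(la * la - x * x, 0.0)
            return x, sign * np.sqrt(y2)
        xc, yc = unfold(c, +1.0)
        xd, yd = unfold(d, -1.0)
        if yc <= 0 or -yd <= 0:
            continue
        xcross = xc + (xd - xc) * yc / (yc - yd)
        if 0.0 <= xcross <= ab:
            src.append(c)
            dst.append(d)
            lens.append(np.hypot(xd - xc, yd - yc))
    return np.array([src, dst], dtype=np.int64), np.asarray(lens)


def _transmural_links(surface: TriSurface) -> tuple[np.ndarray, np.ndarray]:
    """Wall-crossing edges between each endocardial vertex and its nearest
    epicardial counterpart (and vice versa), with euclidean length.

    On the ventricular cup these links let propagation cross the wall the
    way 3-D myocardial activation does, instead of detouring around the
    basal rim."""
    from scipy.spatial import cKDTree

    lab = surface.labels
    endo = np.nonzero(lab == "endocardial")[0]
    epi = np.nonzero(lab == "epicardial")[0]
    if len(endo) == 0 or len(epi) == 0:
        return np.zeros((2, 0), dtype=np.int64), np.zeros(0)
    src, dst = [], []
    for a, b in ((endo, epi), (epi, endo)):
        d, k = cKDTree(surface.vertices[b]).query(surface.vertices[a])
        src.append(a)
        dst.append(b[k])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    lens = np.linalg.norm(surface.vertices[src] - surface.vertices[dst], axis=1)
    return np.stack([src, dst]), lens


def _geodesic_graph(surface: TriSurface, transmural: bool = False) -> sp.csr_matrix:
    e = surface.edges_unique()
    el = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    (sc, dc), sl = _shortcut_edges(surface)
    i = np.concatenate([e[:, 0], sc])
    j = np.concatenate([e[:, 1], dc])
    w = np.concatenate([el, sl])
    if transmural and surface.labels is not None:
        (ts, td), tl = _transmural_links(surface)
        i = np.concatenate([i, ts])
        j = np.concatenate([j, td])
        w = np.concatenate([w, tl])
    n = surface.n_vertices
    # deduplicate parallel edges keeping the shortest length
    key = np.minimum(i, j) * n + np.maximum(i, j)
    order = np.lexsort((w, key))
    key, i, j, w = key[order], i[order], j[order], w[order]
    keep = np.concatenate([[True], key[1:] != key[:-1]])
    i, j, w = i[keep], j[keep], w[keep]
    g = sp.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    return g.tocsr()


def geodesic_distances(surface: TriSurface, source_vertices, transmural: bool = False) -> np.ndarray:
    """Geodesic distance (m) from the nearest source vertex to every vertex.

    Dijkstra on the mesh edge graph augmented with one-ring shortcut edges;
    with ``transmural`` (labelled ventricular surfaces only) wall-crossing
    endo-epi links are added so the metric behaves like myocardial
    propagation rather than pure surface distance.  Unreachable vertices
    (disconnected components) come back as ``inf``.
    """
    src = np.atleast_1d(np.asarray(source_vertices, dtype=np.int64))
    if src.size == 0:
        raise ValueError("at least one source vertex required")
    g = _geodesic_graph(surface, transmural=transmural)
    d = dijkstra(g, directed=False, indices=src)
    return d.min(axis=0) if d.ndim == 2 else d


def all_pairs_geodesics(surface: TriSurface, transmural: bool = False) -> np.ndarray:
    """Full vertex-to-vertex geodesic distance matrix (used by fastest-route)."""
    g = _geodesic_graph(surface, transmural=transmural)
    return dijkstra(g, directed=False)


# ---------------------------------------------------------------------------
# refinement


def subdivide(surface: TriSurface) -> TriSurface:
    """Midpoint (1-to-4) subdivision; the parent vertices are preserved as the
    leading block, so the result is a strict refinement of the input.

    Labels propagate to edge midpoints (the non-basal endpoint label wins so
    the basal band does not widen under refinement).
    """
    v, f = surface.vertices, surface.faces
    e = surface.edges_unique()
    mid = 0.5 * (v[e[:, 0]] + v[e[:, 1]])
    edge_id = {(int(a), int(b)): k for k, (a, b) in enumerate(e)}
    nv = len(v)

    def mid_idx(a, b):
        return nv + edge_id[(min(a, b), max(a, b))]

    new_faces = []
    for a, b, c in f:
        ab, bc, ca = mid_idx(a, b), mid_idx(b, c), mid_idx(c, a)
        new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    labels = None
    if surface.labels is not None:
        lab = surface.labels
        mlab = np.empty(len(e), dtype=object)
        for k, (a, b) in enumerate(e):
            la, lb = lab[a], lab[b]
            if la == lb:
                mlab[k] = la
            else:
                mlab[k] = la if la != "basal" else lb
        labels = np.concatenate([lab, mlab])
    out = TriSurface(np.vstack([v, mid]), np.asarray(new_faces), labels)
    out.validate()
    return out


def is_refinement_of(fine: TriSurface, coarse: TriSurface) -> bool:
    """True when ``fine`` was produced by subdividing ``coarse``."""
    if fine.n_faces % coarse.n_faces != 0 or fine.n_vertices <= coarse.n_vertices:
        return False
    if fine.n_vertices < coarse.n_vertices:
        return False
    return bool(
        np.allclose(fine.vertices[: coarse.n_vertices], coarse.vertices, atol=1e-12)
    )


# ---------------------------------------------------------------------------
# I/O: ASCII PLY (with labels as a vertex property) and ASCII OFF

_LABEL_CODE = {name: i for i, name in enumerate(LABELS)}


def write_surface(path, surface: TriSurface) -> None:
    """Write an ASCII PLY (``.ply``, with an integer ``label`` vertex property
    when labels are present) or an ASCII OFF (``.off``, geometry only)."""
    path = str(path)
    if path.endswith(".off"):
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{surface.n_vertices} {surface.n_faces} 0\n")
            for p in surface.vertices:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for f in surface.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        return
    if not path.endswith(".ply"):
        raise ValueError("unsupported mesh format (use .ply or .off)")
    has_labels = surface.labels is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write("comment label codes: 0=epicardial 1=endocardial 2=basal\n")
        fh.write(f"element vertex {surface.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_labels:
            fh.write("property int label\n")
        fh.write(f"element face {surface.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, p in enumerate(surface.vertices):
            line = f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            if has_labels:
                line += f" {_LABEL_CODE[surface.labels[i]]}"
            fh.write(line + "\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_surface(path) -> TriSurface:
    """Read an ASCII PLY or OFF surface written by :func:`write_surface`."""
    path = str(path)
    if path.endswith(".off"):
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError("not an OFF file")
        nv, nf = int(tokens[1]), int(tokens[2])
        data = np.asarray(tokens[4 : 4 + 3 * nv], dtype=float).reshape(nv, 3)
        rest = tokens[4 + 3 * nv :]
        faces = []
        k = 0
        for _ in range(nf):
            cnt = int(rest[k])
            faces.append([int(x) for x in rest[k + 1 : k + 1 + cnt]])
            k += 1 + cnt
        return TriSurface(data, np.asarray(faces))
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    nv = nf = 0
    vprops: list[str] = []
    i = 1
    element = None
    while lines[i].strip() != "end_header":
        t = lines[i].split()
        if t[0] == "element":
            element = t[1]
            if t[1] == "vertex":
                nv = int(t[2])
            elif t[1] == "face":
                nf = int(t[2])
        elif t[0] == "property" and element == "vertex" and t[1] != "list":
            vprops.append(t[-1])
        i += 1
    body = lines[i + 1 :]
    vdata = np.array([ln.split() for ln in body[:nv]], dtype=float)
    verts = vdata[:, :3]
    labels = None
    if "label" in vprops:
        codes = vdata[:, vprops.index("label")].astype(int)
        labels = np.asarray([LABELS[c] for c in codes], dtype=object)
    faces = np.array([ln.split()[1:4] for ln in body[nv : nv + nf]], dtype=np.int64)
    return TriSurface(verts, faces, labels)
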