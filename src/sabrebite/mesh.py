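"""Tetrahedral mesh container and in-repo meshers.

All solid models are unstructured meshes of four-noded (tet4) constant-strain
tetrahedra with an integer region label per element (cortical bone, dentine,
enamel).  Three meshing routes are provided, all deterministic:

* structured subdivision of boxes (solver-validation bar/cantilever fixtures),
* extrusion of a 2-D lateral profile polygon along the mediolateral axis
  (cranium and mandible blanks, which are prismatic in the synthetic skulls),
* Delaunay tetrahedralisation of seeded points in a convex body (canine cones).

Coordinates are millimetres throughout; the frame is right-handed with
+x anterior, +y dorsal, +z left lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

# Region labels (also the integer cell-data values written to VTK).
REGION_BONE = 0
REGION_DENTINE = 1
REGION_ENAMEL = 2
REGION_NAMES = {REGION_BONE: "bone", REGION_DENTINE: "dentine", REGION_ENAMEL: "enamel"}

# Faces of tet (0,1,2,3) wound so normals point outward when the tet has
# positive signed volume.
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@dataclass
class TetMesh:
    """Volumetric tet4 mesh with per-element region labels and named node sets."""

    nodes: np.ndarray            # (n_nodes, 3) float64, mm
    tets: np.ndarray             # (n_tets, 4) int
    regions: np.ndarray          # (n_tets,) int
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    _surface_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.regions = np.ascontiguousarray(self.regions, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (n, 4)")
        if len(self.regions) != len(self.tets):
            raise ValueError("one region label per tet required")

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes; positive for correctly oriented tets."""
        v = self.nodes[self.tets]
        return np.linalg.det(v[:, 1:] - v[:, :1]) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def orient_positive(self) -> "TetMesh":
        """Swap two nodes of any negatively oriented tet (in place)."""
        neg = self.tet_volumes() < 0
        self.tets[neg] = self.tets[neg][:, [0, 2, 1, 3]]
        self._surface_cache = None
        return self

    def validate(self, min_volume: float = 1e-12) -> None:
        """Raise if any tet is inverted/degenerate or any node is orphaned."""
        vols = self.tet_volumes()
        if (vols <= min_volume).any():
            bad = int(np.argmin(vols))
            raise ValueError(
                f"tet {bad} has non-positive volume {vols[bad]:.3g} mm^3"
            )
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.tets.ravel()] = True
        if not used.all():
            raise ValueError(f"{int((~used).sum())} orphan node(s), first at "
                             f"index {int(np.argmin(used))}")

    # -- surface extraction ------------------------------------------------
    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces used by exactly one tet)."""
        if self._surface_cache is not None:
            return self._surface_cache[0]
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        boundary = faces[counts[inv] == 1]
        self._surface_cache = (boundary,)
        return boundary

    def surface_trimesh(self):
        """Extracted boundary surface as a trimesh.Trimesh (process disabled)."""
        import trimesh

        return trimesh.Trimesh(vertices=self.nodes.copy(),
                               faces=self.boundary_faces().copy(),
                               process=False)

    def region_histogram(self) -> dict[str, int]:
        labels, counts = np.unique(self.regions, return_counts=True)
        return {REGION_NAMES.get(int(k), str(int(k))): int(c)
                for k, c in zip(labels, counts)}

    # -- transforms --------------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TetMesh":
        """Rigidly transformed copy (node sets preserved by index)."""
        nodes = self.nodes.copy()
        if rotation is not None:
            nodes = nodes @ np.asarray(rotation).T
        if translation is not None:
            nodes = nodes + np.asarray(translation)
        return TetMesh(nodes, self.tets.copy(), self.regions.copy(),
                       {k: v.copy() for k, v in self.node_sets.items()})

    def copy(self) -> "TetMesh":
        return self.transformed()


# ---------------------------------------------------------------------------
# structured box meshing (validation fixtures)
# ---------------------------------------------------------------------------

# Decomposition of a unit cube (corner indices in binary zyx order) into six
# tets sharing the main diagonal 0-7: conforming across identical neighbours.
_CUBE_TETS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7],
])


def make_box_mesh(lengths, divisions) -> TetMesh:
    """Structured tet mesh of a box at the origin corner.

    lengths: (lx, ly, lz) mm;  divisions: (nx, ny, nz) cells per axis.
    """
    lx, ly, lz = lengths
    nx, ny, nz = (int(d) for d in divisions)
    if min(lx, ly, lz) <= 0:
        raise ValueError("box dimensions must be positive")
    if min(nx, ny, nz) < 1:
        raise ValueError("divisions must be >= 1")
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([nid(i + (c >> 0 & 1), j + (c >> 1 & 1), k + (c >> 2 & 1))
                        for c in range(8)], axis=1)
    tets = corners[:, _CUBE_TETS].reshape(-1, 4)
    mesh = TetMesh(nodes, tets, np.full(len(tets), REGION_BONE))
    mesh.orient_positive()
    return mesh


def _face_nodes(mesh: TetMesh, axis: int, value: float, tol: float = 1e-9):
    return np.flatnonzero(np.abs(mesh.nodes[:, axis] - value) < tol)


def make_bar_fixture(length: float, side: float, n_divisions: int) -> TetMesh:
    """Rectangular bar for axial solver validation.

    ``length`` along x with a ``side`` x ``side`` cross-section; ``n_divisions``
    cells across the section (length divided proportionally).  End faces tagged
    ``fixed`` (x=0) and ``loaded`` (x=length).
    """
    if length <= 0 or side <= 0:
        raise ValueError("bar dimensions must be positive")
    n_divisions = int(n_divisions)
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    nx = max(1, round(n_divisions * length / side))
    mesh = make_box_mesh((length, side, side), (nx, n_divisions, n_divisions))
    mesh.node_sets["fixed"] = _face_nodes(mesh, 0, 0.0)
    mesh.node_sets["loaded"] = _face_nodes(mesh, 0, length)
    return mesh


def make_cantilever_fixture(length: float, side: float, n_divisions: int) -> TetMesh:
    """Cantilever beam fixture: root face ``fixed``, tip face ``loaded``.

    Same geometry as the bar; the tip set is intended for transverse loading
    and deflection checks against Euler-Bernoulli theory.
    """
    mesh = make_bar_fixture(length, side, n_divisions)
    return mesh


# ---------------------------------------------------------------------------
# 2-D profile extrusion meshing
# ---------------------------------------------------------------------------

def _triangulate_polygon(profile_xy: np.ndarray, target_edge: float):
    """Constrained-quality triangulation of a (possibly non-convex) polygon.

    Seeds the boundary at ~target_edge spacing plus an interior grid, Delaunay
    triangulates the points and keeps triangles whose centroid lies inside the
    polygon (shapely point-in-polygon).
    """
    from shapely.geometry import Point, Polygon

    poly = Polygon(profile_xy)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("profile polygon is degenerate or self-intersecting")

    # adaptive boundary seeding: the step along each edge shrinks where the
    # polygon is locally thin (e.g. inside a narrow process spike), so the
    # triangulation cannot pinch across the feature
    n = len(profile_xy)
    segs = [(profile_xy[a], profile_xy[(a + 1) % n]) for a in range(n)]

    def _dist_to_other_edges(pt, skip):
        best = np.inf
        for j, (p, q) in enumerate(segs):
            if j == skip:
                continue
            d = q - p
            L2 = d @ d
            t = 0.0 if L2 == 0 else np.clip((pt - p) @ d / L2, 0.0, 1.0)
            best = min(best, float(np.linalg.norm(pt - (p + t * d))))
        return best

    floor = max(0.1 * target_edge, 0.2)
    pts = []
    for a, (p, q) in enumerate(segs):
        seg = np.linalg.norm(q - p)
        d = (q - p) / seg
        s = 0.0
        while s < seg - 1e-9:
            pt = p + s * d
            pts.append(pt)
            width = _dist_to_other_edges(pt + 0.5 * floor * d, a)
            step = float(np.clip(0.8 * width, floor, target_edge))
            s += step
    boundary = np.array(pts)
    # weld near-duplicate boundary seeds (edge endpoints may nearly repeat)
    keep = np.ones(len(boundary), dtype=bool)
    tree_b = cKDTree(boundary)
    for i, grp in enumerate(tree_b.query_ball_point(boundary, 1e-6)):
        for j in grp:
            if j > i:
                keep[j] = False
    boundary = boundary[keep]

    xmin, ymin, xmax, ymax = poly.bounds
    gx = np.arange(xmin + 0.5 * target_edge, xmax, target_edge)
    gy = np.arange(ymin + 0.5 * target_edge, ymax, target_edge)
    GX, GY = np.meshgrid(gx, gy)
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    if len(grid):
        # keep interior points clear of the boundary so no sliver triangles
        keep = np.array([poly.buffer(-0.35 * target_edge).contains(Point(p))
                         for p in grid])
        grid = grid[keep]
    points = np.vstack([boundary, grid]) if len(grid) else boundary
    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    inside = np.array([poly.contains(Point(c)) for c in cent])
    faces = tri.simplices[inside]
    # drop degenerate (collinear) triangles, then repair the T-junctions the
    # drop leaves behind: a removed sliver's middle point sits on an edge of
    # a kept triangle, which must be split for the mesh to conform
    v = points[faces]
    e1, e2 = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]
    area2 = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    faces = faces[np.abs(area2) > 1e-10 * target_edge**2]
    faces = _repair_tjunctions(points, faces)
    return points, faces


def _repair_tjunctions(points: np.ndarray, faces: np.ndarray,
                       max_passes: int = 6) -> np.ndarray:
    """Split triangles whose edges contain another mesh point (within a
    relative tolerance), so the triangulation conforms."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    for _ in range(max_passes):
        out = []
        changed = False
        for f in faces:
            split = None
            for k in range(3):
                a, c = f[k], f[(k + 1) % 3]
                pa, pc = points[a], points[c]
                mid = 0.5 * (pa + pc)
                half = 0.5 * np.linalg.norm(pc - pa)
                cand = tree.query_ball_point(mid, half * 1.0001)
                for b in cand:
                    if b in (f[0], f[1], f[2]):
                        continue
                    pb = points[b]
                    d = pc - pa
                    t = (pb - pa) @ d / (d @ d)
                    if not (1e-9 < t < 1 - 1e-9):
                        continue
                    off = pb - (pa + t * d)
                    if np.linalg.norm(off) < 1e-7 * half:
                        split = (k, b)
                        break
                if split:
                    break
            if split is None:
                out.append(f)
            else:
                k, b = split
                a, c, o = f[k], f[(k + 1) % 3], f[(k + 2) % 3]
                out.append(np.array([a, b, o]))
                out.append(np.array([b, c, o]))
                changed = True
        faces = np.array(out)
        if not changed:
            break
    return faces


def _split_prism(pr: np.ndarray) -> list:
    """Split prism (bottom a,b,c / top d,e,f with verticals a-d,b-e,c-f) into
    three tets with quad-face diagonals chosen from the lowest global index,
    so adjacent prisms produce conforming faces."""
    pr = list(pr)
    # rotate so the smallest index of the prism sits at local vertex 0 or 3
    m = int(np.argmin(pr))
    rot = m % 3
    if rot:
        pr = [pr[rot], pr[(rot + 1) % 3], pr[(rot + 2) % 3],
              pr[3 + rot], pr[3 + (rot + 1) % 3], pr[3 + (rot + 2) % 3]]
    if min(pr[0:3]) > min(pr[3:6]):
        # mirror top/bottom, reversing winding to keep orientation
        pr = [pr[3], pr[5], pr[4], pr[0], pr[2], pr[1]]
        m = int(np.argmin(pr))
        rot = m % 3
        if rot:
            pr = [pr[rot], pr[(rot + 1) % 3], pr[(rot + 2) % 3],
                  pr[3 + rot], pr[3 + (rot + 1) % 3], pr[3 + (rot + 2) % 3]]
    i0, i1, i2, i3, i4, i5 = pr
    if min(i1, i5) < min(i2, i4):
        return [[i0, i1, i2, i5], [i0, i1, i5, i4], [i0, i4, i5, i3]]
    return [[i0, i1, i2, i4], [i0, i4, i2, i5], [i0, i4, i5, i3]]


def extrude_profile(profile_xy, z_half_width: float, target_edge: float) -> TetMesh:
    """Tet-mesh the prismatic solid obtained by extruding a lateral-view
    profile polygon (x anterior, y dorsal) symmetrically along z.

    The z direction is the mediolateral (jaw-joint) axis; layer thickness
    approximately matches ``target_edge``.
    """
    profile_xy = np.asarray(profile_xy, dtype=float)
    points2d, faces = _triangulate_polygon(profile_xy, target_edge)
    nz = max(1, int(np.ceil(2 * z_half_width / target_edge)))
    zs = np.linspace(-z_half_width, z_half_width, nz + 1)
    n2 = len(points2d)
    nodes = np.column_stack([
        np.tile(points2d, (nz + 1, 1)),
        np.repeat(zs, n2),
    ])
    tets = []
    for layer in range(nz):
        lo, hi = layer * n2, (layer + 1) * n2
        for (a, b, c) in faces:
            tets.extend(_split_prism([lo + a, lo + b, lo + c,
                                      hi + a, hi + b, hi + c]))
    mesh = TetMesh(nodes, np.array(tets), np.full(len(tets), REGION_BONE))
    mesh.orient_positive()
    return mesh


# ---------------------------------------------------------------------------
# Delaunay meshing of seeded convex bodies (canine cones)
# ---------------------------------------------------------------------------

def delaunay_mesh(points: np.ndarray, region: int = REGION_BONE,
                  min_volume_frac: float = 1e-9) -> TetMesh:
    """Delaunay tetrahedralisation of a convex point cloud.

    Near-degenerate slivers (volume below ``min_volume_frac`` of the mean) are
    discarded; the caller is responsible for convexity.
    """
    points = np.asarray(points, dtype=float)
    tri = Delaunay(points)
    mesh = TetMesh(points, tri.simplices.copy(),
                   np.full(len(tri.simplices), region))
    mesh.orient_positive()
    vols = mesh.tet_volumes()
    keep = vols > min_volume_frac * max(vols.mean(), 1e-30)
    mesh = TetMesh(mesh.nodes, mesh.tets[keep], mesh.regions[keep],
                   mesh.node_sets)
    _drop_orphans(mesh)
    return mesh


def _drop_orphans(mesh: TetMesh) -> None:
    used = np.zeros(mesh.n_nodes, dtype=bool)
    used[mesh.tets.ravel()] = True
    if used.all():
        return
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(used.sum())
    mesh.nodes = mesh.nodes[used]
    mesh.tets = remap[mesh.tets]
    mesh.node_sets = {k: remap[v][remap[v] >= 0] for k, v in mesh.node_sets.items()}
    mesh._surface_cache = None


def merge_meshes(meshes: list, tol: float = 1e-8) -> tuple:
    """Concatenate meshes, welding coincident nodes (within tol).

    Returns (merged mesh, per-input node index offsets *after* welding maps)
    — the second element is a list of arrays mapping each input mesh's node
    indices to merged indices, so callers can relocate node sets/landmarks.
    """
    all_nodes = np.vstack([m.nodes for m in meshes])
    key = np.round(all_nodes / tol).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True,
                              return_inverse=True)
    nodes = all_nodes[first]
    maps, tets, regions, offset = [], [], [], 0
    for m in meshes:
        mp = inv[offset:offset + m.n_nodes]
        maps.append(mp)
        tets.append(mp[m.tets])
        regions.append(m.regions)
        offset += m.n_nodes
    merged = TetMesh(nodes, np.vstack(tets), np.concatenate(regions))
    for m, mp in zip(meshes, maps):
        for name, idx in m.node_sets.items():
            merged.node_sets[name] = np.unique(mp[idx])
    return merged, maps


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

def find_enclosing_tet(mesh: TetMesh, point, max_outside: float = 1.0,
                       n_candidates: int = 32):
    """Index of the tet containing ``point``; nearest-centroid fallback for
    points up to ``max_outside`` mm outside the mesh, else None.

    Candidate tets are ranked by centroid distance (KD-tree) and tested with
    barycentric coordinates.
    """
    point = np.asarray(point, dtype=float)
    cents = mesh.tet_centroids()
    tree = cKDTree(cents)
    k = min(n_candidates, mesh.n_tets)
    dists, cand = tree.query(point, k=k)
    cand = np.atleast_1d(cand)
    for ti in cand:
        v = mesh.nodes[mesh.tets[ti]]
        T = (v[1:] - v[0]).T
        try:
            lam = np.linalg.solve(T, point - v[0])
        except np.linalg.LinAlgError:
            continue
        b = np.array([1 - lam.sum(), *lam])
        if (b > -1e-9).all():
            return int(ti)
    # outside: fall back to the nearest surface distance test
    from sabrebite.geometry import SurfaceDistance

    sd = SurfaceDistance(mesh.nodes, mesh.boundary_faces())
    dist, _, _ = sd.closest(point[None, :])
    if dist[0] <= max_outside:
        return int(np.atleast_1d(cand)[0])
    return None
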