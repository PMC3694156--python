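"""Seeded parametric skull models for exercising the biting pipeline.

Real saber-tooth crania only exist as CT meshes that cannot be redistributed,
so every downstream stage here runs on stylised synthetic skulls: a wedge
cranium and bar mandible (extruded lateral profiles), conical upper canines
with dentine cores and enamel shells, a cylindrical condyle knob articulating
on a cranial shelf, and named landmarks and muscle-attachment patches.  The
geometry is deliberately non-anatomical; what matters is that it *plants
ground truth* every analysis stage can recover:

* the upper-canine distal-margin points lie exactly on a circular arc whose
  centre sits at a configured fraction of the fulcrum-to-circumference
  distance (the canine arc-centre ratio);
* the jaw reaches bone-bone contact at an exactly computable gape angle,
  realised by an angular-process stop placed by back-rotating the planted
  contact point about the joint axis;
* articular cartilage layers (1 mm by default) touch exactly at the rest
  pose, so seating is near-identity and the contact-derived rotation axis
  coincides with the analytic touch line.

Frame: +x anterior, +y dorsal, +z left; mm; jaw-joint axis parallel to z.
All generation is deterministic for a fixed parameter set and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import LineString, Polygon

from sabrebite.mesh import (
    REGION_BONE,
    REGION_DENTINE,
    REGION_ENAMEL,
    TetMesh,
    delaunay_mesh,
    extrude_profile,
    merge_meshes,
)

LANDMARK_NAMES_REQUIRED = (
    "upper_mesial_incisor", "lower_mesial_incisor",
    "jaw_joint_left", "jaw_joint_right",
    "canine_tip_left", "canine_tip_right",
    "lower_canine_left", "lower_canine_right",
    "occipital_condyle",
)

PATCH_NAMES_REQUIRED = (
    "temporalis_origin", "temporalis_insertion",
    "masseter_origin", "masseter_insertion",
    "mastoid_region", "condyle_plate", "cotyle_plate",
)


@dataclass(frozen=True)
class SkullParams:
    """Parameters of the synthetic skull generator.

    Lengths in mm; the canine arc is planted in the lateral (x, y) plane with
    its centre at ``canine_arc_ratio`` of the fulcrum-to-circumference
    distance (the jaw joint is the fulcrum).  ``bone_contact_gape_deg`` is the
    gape angle (upper incisor - joint - lower incisor) at which the angular
    process first meets the cranium.
    """

    skull_length: float = 300.0
    body_mass: float = 259.0           # kg, an input to scaling only
    canine_length: float | None = None  # default 0.30 x skull_length
    canine_arc_ratio: float = 0.17
    bone_contact_gape_deg: float = 90.0
    condyle_radius: float = 1.0
    cotyle_clearance: float = 2.0       # bone-bone gap at the joint, mm
    cartilage_mm: float = 1.0           # design cartilage thickness, mm
    target_tets: int = 5000
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        L = self.skull_length
        if L <= 0 or self.body_mass <= 0:
            raise ValueError("skull_length and body_mass must be positive")
        cl = self.canine_length if self.canine_length is not None else 0.30 * L
        if cl <= 0:
            raise ValueError("canine_length must be positive")
        if cl >= L:
            raise ValueError("canine longer than the skull is infeasible")
        if not (0 < self.canine_arc_ratio < 1):
            raise ValueError("canine_arc_ratio must lie in (0, 1)")
        if self.condyle_radius <= 0 or self.cotyle_clearance <= 0:
            raise ValueError("joint dimensions must be positive")
        if self.cartilage_mm < 0:
            raise ValueError("cartilage thickness must be non-negative")
        if not (10.0 < self.bone_contact_gape_deg < 130.0):
            raise ValueError("bone_contact_gape_deg outside the buildable range")
        if self.target_tets < 500:
            raise ValueError("target tet count must be >= 500")

    @property
    def canine_length_mm(self) -> float:
        return (self.canine_length if self.canine_length is not None
                else 0.30 * self.skull_length)


@dataclass
class ArcSpec:
    """Circular arc in the lateral (x, y) plane (the canine insertion path)."""

    center: np.ndarray      # (2,)
    radius: float
    phi_start_deg: float
    phi_end_deg: float

    def points(self, n: int = 25, noise_sd: float = 0.0,
               seed: int | None = None) -> np.ndarray:
        span = self.phi_end_deg - self.phi_start_deg
        return make_canine_arc_points(self.center, self.radius, span, n,
                                      noise_sd, seed,
                                      start_angle_deg=self.phi_start_deg)

    def at(self, phi_deg: float) -> np.ndarray:
        phi = math.radians(phi_deg)
        return self.center + self.radius * np.array([math.cos(phi),
                                                     math.sin(phi)])


@dataclass
class Patch:
    """Named surface-triangle set on one of the two meshes."""

    mesh: str               # "cranium" | "mandible"
    faces: np.ndarray       # (n, 3) vertex indices into that mesh

    @property
    def nodes(self) -> np.ndarray:
        return np.unique(self.faces)


@dataclass
class SkullModel:
    """Paired cranium/mandible tet meshes with landmarks and patches."""

    cranium: TetMesh
    mandible: TetMesh
    landmarks: dict
    attachment_patches: dict            # name -> Patch
    element_sets: dict                  # cranium tet-index sets by name
    canine_spiders: list                # (master cranium node, slave array)
    arcs: dict                          # side -> ArcSpec
    canine_arc_points: dict             # side -> (n, 2) lateral-plane points
    joint_axis_point: np.ndarray        # on the rest-pose cartilage touch line
    joint_axis_dir: np.ndarray
    skull_length: float
    body_mass: float
    params: SkullParams
    rest_gape_deg: float
    planted_rotation_deg: float         # jaw rotation at bone contact
    stress_landmarks: list = field(default_factory=list)

    def mesh_of(self, which: str) -> TetMesh:
        return self.cranium if which == "cranium" else self.mandible

    def patch(self, name: str) -> Patch:
        try:
            return self.attachment_patches[name]
        except KeyError:
            raise KeyError(f"attachment patch '{name}' missing from model "
                           f"(have {sorted(self.attachment_patches)})") from None

    def jaw_joint_mid(self) -> np.ndarray:
        return 0.5 * (self.landmarks["jaw_joint_left"]
                      + self.landmarks["jaw_joint_right"])

    def copy(self) -> "SkullModel":
        import copy as _copy

        return _copy.deepcopy(self)


def make_canine_arc_points(center, radius: float, angular_span: float, n: int,
                           noise_sd: float = 0.0, seed: int | None = None,
                           start_angle_deg: float = 0.0) -> np.ndarray:
    """Sample ``n`` points on a lateral-plane circle arc plus isotropic noise.

    Supports the canine arc-centre analysis: with zero noise every point is at
    ``radius`` from ``center`` to machine precision.
    """
    if n < 3:
        raise ValueError("need at least 3 arc points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    phi = np.radians(start_angle_deg + np.linspace(0.0, angular_span, n))
    pts = center + radius * np.column_stack([np.cos(phi), np.sin(phi)])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def _cranium_profile(p: SkullParams) -> np.ndarray:
    L, Rc, cl = p.skull_length, p.condyle_radius, p.cotyle_clearance
    ys = -(Rc + cl)                 # articular shelf (cotyle) level
    led = 0.75 * Rc                 # shelf-stub thickness
    post = 2.0 * Rc + 0.02 * L      # retro-articular post, structurally stout
    return np.array([
        (-0.20 * L, 0.0),                       # rear underside corner
        (-post, 0.0),                           # post outer top
        (-post, ys - led),                      # post outer bottom
        (0.80 * Rc, ys - led),                  # ledge front bottom
        (0.80 * Rc, ys),                        # shelf front edge
        (-2.00 * Rc, ys),                       # shelf rear (post inner foot)
        (-2.00 * Rc, Rc + cl),                  # post inner top (overhead)
        (max(3.0 * Rc, 0.02 * L), Rc + cl),     # overhead front
        (0.15 * L, 0.04 * L),                   # palate rear
        (0.78 * L, 0.04 * L),                   # palate front / incisor
        (0.78 * L, 0.10 * L),                   # snout top
        (0.53 * L, 0.20 * L),
        (0.20 * L, 0.30 * L),                   # braincase apex
        (-0.20 * L, 0.25 * L),                  # occiput top
    ])


def _knob_arc(Rc: float, start_deg=60.0, end_deg=330.0, step_deg=22.5):
    ang = np.radians(np.arange(start_deg, end_deg + 0.5 * step_deg, step_deg))
    return Rc * np.column_stack([np.cos(ang), np.sin(ang)])


def _mandible_profile(p: SkullParams, apex_xy) -> np.ndarray:
    L, Rc = p.skull_length, p.condyle_radius
    yt = -1.5 * Rc                  # corpus dorsal (tooth-row) level
    yb = -0.053 * L                 # corpus ventral level
    pts = [tuple(q) for q in _knob_arc(Rc)]     # condyle knob, 60..330 deg
    pts += [
        # the ramus posterior face bulges out so that, sweeping about the
        # joint axis, it clears the cranial ledge front corners
        (2.8 * Rc, -1.3 * Rc),
        (4.0 * Rc, -8.0 * Rc),      # ramus posterior face foot
        tuple(apex_xy),             # angular-process apex (planted stop)
        # corpus junction stays anterior of the apex for wide planted gapes
        (max(3.0 * Rc, apex_xy[0] + 0.015 * L), yb),
        (0.74 * L, yb),             # corpus underside
        (0.74 * L, yt),             # incisor corner
        (6.0 * Rc, yt),             # corpus top edge
    ]
    return np.array(pts)


def _mid_height(poly: Polygon, x: float) -> float:
    cut = poly.intersection(LineString([(x, -1e4), (x, 1e4)]))
    if cut.is_empty:
        raise ValueError(f"profile has no material at x={x:.1f}")
    if cut.geom_type == "MultiLineString":
        cut = max(cut.geoms, key=lambda g: g.length)
    ys = [c[1] for c in cut.coords]
    return 0.5 * (min(ys) + max(ys))


def _opening_rotation(theta_deg: float):
    """In-plane map of jaw opening by theta about +z through the origin:
    anterior (+x) points move ventrally."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, s], [-s, c]])


def _gape_after_rotation(upper, lower, joint, axis_xy, theta_deg: float) -> float:
    M = _opening_rotation(theta_deg)
    lo = np.asarray(axis_xy) + M @ (np.asarray(lower) - axis_xy)
    v1 = np.asarray(upper) - joint
    v2 = lo - joint
    cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                     -1.0, 1.0)
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# canine construction
# ---------------------------------------------------------------------------

def _plant_canine_arc(p: SkullParams) -> ArcSpec:
    """Solve the arc centre/radius so that the centre sits at the requested
    fulcrum ratio while the canine occupies its anatomical station."""
    L = p.skull_length
    rho = p.canine_arc_ratio
    y_pal = 0.04 * L
    y_tip = y_pal - p.canine_length_mm
    x_c = 0.65 * L
    u = np.array([x_c, 0.5 * (y_pal + y_tip)])
    u = u / np.linalg.norm(u)
    # centre C = d*u with d = rho*r/(1-rho); easternmost point at x ~ x_c
    r = x_c * (1 - rho) / (1 - rho + rho * u[0])
    d = rho * r / (1 - rho)
    C = d * u
    phi_top = math.degrees(math.asin(np.clip((y_pal - C[1]) / r, -1, 1)))
    phi_bot = math.degrees(math.asin(np.clip((y_tip - C[1]) / r, -1, 1)))
    return ArcSpec(center=C, radius=r, phi_start_deg=phi_bot,
                   phi_end_deg=phi_top)


def _canine_mesh(p: SkullParams, arc: ArcSpec, z0: float,
                 n_ring: int = 10, n_levels: int = 8) -> TetMesh:
    L = p.skull_length
    y_pal = 0.04 * L
    y_root_top = 0.08 * L
    rb = 0.03 * L
    lo = arc.at(arc.phi_start_deg)
    hi = arc.at(arc.phi_end_deg)
    tip = np.array([lo[0], lo[1], z0])      # phi_start = tooth tip
    base = np.array([hi[0] - 0.5 * rb, y_root_top, z0])
    axis = base - tip
    # crown tapers linearly tip->palate, root is cylindrical above the palate
    t_pal = (y_pal - tip[1]) / (base[1] - tip[1])
    pts = [tip[None, :]]
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    d1 = np.array([1.0, 0, 0])
    d1 = d1 - (d1 @ axis) * axis / (axis @ axis)
    d1 /= np.linalg.norm(d1)
    d2 = np.cross(axis / np.linalg.norm(axis), d1)
    for t in np.linspace(0.12, 1.0, n_levels):
        r = rb * min(1.0, t / max(t_pal, 1e-6))
        c = tip + t * axis
        ring = c + r * (np.outer(np.cos(ang), d1) + np.outer(np.sin(ang), d2))
        pts.append(c[None, :])
        pts.append(ring)
    cloud = np.vstack(pts)
    mesh = delaunay_mesh(cloud, region=REGION_DENTINE)

    cent = mesh.tet_centroids()
    axis_len = np.linalg.norm(axis)
    axis_n = axis / axis_len
    t_c = (cent - tip) @ axis_n / axis_len
    radial = cent - (tip + np.outer(t_c, axis))
    r_loc = rb * np.minimum(1.0, t_c / max(t_pal, 1e-6))
    s = np.linalg.norm(radial, axis=1) / np.maximum(r_loc, 1e-9)
    enamel = (cent[:, 1] < y_pal) & (s > 0.6)
    mesh.regions[enamel] = REGION_ENAMEL

    tip_node = int(np.argmin(np.linalg.norm(mesh.nodes - tip, axis=1)))
    root_nodes = np.flatnonzero(
        mesh.nodes[:, 1] > y_pal + 0.25 * (y_root_top - y_pal))
    mesh.node_sets["tip"] = np.array([tip_node])
    mesh.node_sets["root"] = root_nodes
    return mesh


# ---------------------------------------------------------------------------
# patch selection helpers
# ---------------------------------------------------------------------------

def _mirror_z(mesh: TetMesh) -> TetMesh:
    """Exact sagittal mirror image (z -> -z, orientation restored)."""
    out = TetMesh(mesh.nodes * np.array([1.0, 1.0, -1.0]),
                  mesh.tets[:, [0, 2, 1, 3]].copy(), mesh.regions.copy(),
                  {k: v.copy() for k, v in mesh.node_sets.items()})
    return out


def _select_faces(mesh: TetMesh, predicate) -> np.ndarray:
    faces = mesh.boundary_faces()
    v = mesh.nodes[faces]
    cent = v.mean(axis=1)
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    n = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
    keep = predicate(cent, n)
    return faces[keep]


def _nearest_node(mesh: TetMesh, point) -> int:
    return int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(point), axis=1)))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _mesh_budgeted(profile, half_width, budget):
    """Extrude with a target edge calibrated once against the tet budget."""
    poly = Polygon(profile)
    volume = poly.area * 2 * half_width
    h = (6.0 * volume / max(budget, 1)) ** (1.0 / 3.0)
    mesh = extrude_profile(profile, half_width, h)
    for _ in range(3):
        ratio = mesh.n_tets / max(budget, 1)
        if 0.85 <= ratio <= 1.15:
            break
        # thin-feature refinement adds an h-independent tet floor, so damp
        # the correction to avoid overshoot
        h *= ratio ** 0.25
        mesh = extrude_profile(profile, half_width, h)
    return mesh


def make_skull_pair(params: SkullParams) -> SkullModel:
    """Generate the paired cranium/mandible model with planted ground truth.

    Deterministic for a fixed parameter set; see the module docstring for the
    planted quantities and how they are realised.
    """
    p = params
    L, Rc, cl, cart = (p.skull_length, p.condyle_radius, p.cotyle_clearance,
                       p.cartilage_mm)
    W = 0.18 * L
    Wm = 0.52 * W
    yt = -1.5 * Rc
    y_pal = 0.04 * L

    # --- planted articulation geometry ---------------------------------
    # rest-pose cartilage touch line: shelf level + one cartilage thickness
    y_axis = -(Rc + cl) + cart
    axis_xy = np.array([0.0, y_axis])
    upper_inc = np.array([0.78 * L, y_pal])
    lower_inc = np.array([0.74 * L, yt])
    joint2 = np.zeros(2)
    rest_gape = _gape_after_rotation(upper_inc, lower_inc, joint2, axis_xy, 0.0)

    def gape_err(theta):
        return (_gape_after_rotation(upper_inc, lower_inc, joint2, axis_xy,
                                     theta) - p.bone_contact_gape_deg)

    theta_star = brentq(gape_err, 0.5, 145.0, xtol=1e-10)

    # angular-process apex: back-rotate the planted contact point (on the
    # posterior cranial underside, y = 0) about the touch-line axis
    a_stop = 0.12 * L
    contact_pt = np.array([-a_stop, 0.0])
    Minv = _opening_rotation(-theta_star)
    apex = axis_xy + Minv @ (contact_pt - axis_xy)

    # --- meshes ---------------------------------------------------------
    arc = _plant_canine_arc(p)
    z_can = 0.80 * W
    left_canine = _canine_mesh(p, arc, z_can)
    canines = {"left": left_canine, "right": _mirror_z(left_canine)}

    remaining = max(600, p.target_tets - 2 * left_canine.n_tets)
    cran_profile = _cranium_profile(p)
    mand_profile = _mandible_profile(p, apex)
    cranium_body = _mesh_budgeted(cran_profile, W, int(0.70 * remaining))
    mandible = _mesh_budgeted(mand_profile, Wm, int(0.30 * remaining))

    cranium, maps = merge_meshes([cranium_body, canines["left"],
                                  canines["right"]])
    cranium.node_sets["body"] = np.sort(maps[0])
    spiders = []
    for side, mp in (("left", maps[1]), ("right", maps[2])):
        cm = canines[side]
        tip_node = int(mp[cm.node_sets["tip"][0]])
        root = np.asarray(mp[cm.node_sets["root"]])
        anchor_pt = cm.nodes[cm.node_sets["root"]].mean(axis=0)
        anchor_pt[1] = y_pal
        master = maps[0][_nearest_node(cranium_body, anchor_pt)]
        spiders.append((int(master), root))
        cranium.node_sets[f"canine_tip_{side}"] = np.array([tip_node])
        cranium.node_sets[f"canine_root_{side}"] = root

    occ_lm = np.array([-0.20 * L, 0.12 * L, 0.0])
    # the band must span several node rows at every mesh resolution: fixing
    # a collinear node set would leave a free rigid rotation about it
    occ_nodes = np.flatnonzero(
        (cranium.nodes[:, 0] < -0.18 * L)
        & (cranium.nodes[:, 1] > 0.02 * L)
        & (cranium.nodes[:, 1] < 0.24 * L))
    cranium.node_sets["occipital_condyle"] = occ_nodes

    for side, z0 in (("left", 0.8 * Wm), ("right", -0.8 * Wm)):
        n = _nearest_node(mandible, [0.70 * L, yt, z0])
        mandible.node_sets[f"lower_canine_{side}"] = np.array([n])

    # --- landmarks ------------------------------------------------------
    tip2 = arc.at(arc.phi_start_deg)
    landmarks = {
        "upper_mesial_incisor": np.array([0.78 * L, y_pal, 0.0]),
        "lower_mesial_incisor": np.array([0.74 * L, yt, 0.0]),
        "jaw_joint_left": np.array([0.0, 0.0, Wm]),
        "jaw_joint_right": np.array([0.0, 0.0, -Wm]),
        "canine_tip_left": np.array([tip2[0], tip2[1], z_can]),
        "canine_tip_right": np.array([tip2[0], tip2[1], -z_can]),
        "lower_canine_left": np.array([0.70 * L, yt, 0.8 * Wm]),
        "lower_canine_right": np.array([0.70 * L, yt, -0.8 * Wm]),
        "occipital_condyle": occ_lm,
    }
    cran_poly = Polygon(cran_profile)
    stress_landmarks = []
    for i, xf in enumerate((-0.12, 0.02, 0.15, 0.30, 0.45, 0.58, 0.68, 0.75)):
        x = xf * L
        name = f"cranial_lm_{i + 1:02d}"
        landmarks[name] = np.array([x, _mid_height(cran_poly, x), 0.0])
        stress_landmarks.append(name)
    mand_poly = Polygon(mand_profile)
    for i, xf in enumerate((0.30, 0.55)):
        x = xf * L
        name = f"mandible_lm_{i + 1:02d}"
        landmarks[name] = np.array([x, _mid_height(mand_poly, x), 0.0])
        stress_landmarks.append(name)

    # --- attachment patches --------------------------------------------
    ys = -(Rc + cl)
    patches = {
        "temporalis_origin": Patch("cranium", _select_faces(
            cranium, lambda c, n: (n[:, 1] > 0.6) & (c[:, 0] > 0.0)
            & (c[:, 0] < 0.30 * L) & (c[:, 1] > 0.15 * L))),
        "temporalis_insertion": Patch("mandible", _select_faces(
            mandible, lambda c, n: (n[:, 1] > 0.9) & (c[:, 0] > 5 * Rc)
            & (c[:, 0] < 0.16 * L))),
        "masseter_origin": Patch("cranium", _select_faces(
            cranium, lambda c, n: (np.abs(n[:, 2]) > 0.9)
            & (c[:, 0] > 0.05 * L) & (c[:, 0] < 0.30 * L)
            & (c[:, 1] > 0.02 * L) & (c[:, 1] < 0.16 * L))),
        "masseter_insertion": Patch("mandible", _select_faces(
            mandible, lambda c, n: (np.abs(n[:, 2]) > 0.9)
            & (c[:, 0] > 0.05 * L) & (c[:, 0] < 0.25 * L))),
        "mastoid_region": Patch("cranium", _select_faces(
            cranium, lambda c, n: ((n[:, 0] < -0.6) & (c[:, 1] < 0.12 * L)
                                   & (c[:, 0] < -0.18 * L))
            | ((n[:, 1] < -0.6) & (c[:, 0] < -0.10 * L)
               & (c[:, 1] > -1.0)))),
        # narrow ventral band of the knob: the cartilage-bearing facet must
        # project inside the shelf so ICP seating is symmetric
        "condyle_plate": Patch("mandible", _select_faces(
            mandible, lambda c, n: (
                np.linalg.norm(c[:, :2], axis=1) < 1.05 * Rc)
            & (c[:, 1] < -0.90 * Rc))),
        "cotyle_plate": Patch("cranium", _select_faces(
            cranium, lambda c, n: (np.abs(c[:, 1] - ys) < 0.15 * Rc)
            & (c[:, 0] > -2.0 * Rc) & (c[:, 0] < 0.80 * Rc)
            & (n[:, 1] > 0.9))),
    }
    for name, patch in patches.items():
        if len(patch.faces) == 0:
            raise RuntimeError(f"generator produced empty patch '{name}'")

    # --- element sets ---------------------------------------------------
    cent = cranium.tet_centroids()
    zyg = np.flatnonzero((cranium.regions == REGION_BONE)
                         & (cent[:, 0] > 0.05 * L) & (cent[:, 0] < 0.30 * L)
                         & (cent[:, 1] < 0.16 * L)
                         & (np.abs(cent[:, 2]) > 0.5 * W))
    element_sets = {"zygomatic_arch": zyg}

    model = SkullModel(
        cranium=cranium, mandible=mandible, landmarks=landmarks,
        attachment_patches=patches, element_sets=element_sets,
        canine_spiders=spiders, arcs={"left": arc, "right": arc},
        canine_arc_points={s: arc.points(n=25) for s in ("left", "right")},
        joint_axis_point=np.array([0.0, y_axis, 0.0]),
        joint_axis_dir=np.array([0.0, 0.0, 1.0]),
        skull_length=L, body_mass=p.body_mass, params=p,
        rest_gape_deg=rest_gape, planted_rotation_deg=theta_star,
        stress_landmarks=stress_landmarks,
    )
    cranium.validate()
    mandible.validate()
    return model
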