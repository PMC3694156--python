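"""Jaw articulation and maximum-gape estimation.

The maximum-gape algorithm mirrors how it is done on CT-derived skull
surfaces:

1. the articular surfaces of condyle and cotyle are offset outward by a
   cartilage thickness (1 mm by default, a median carnivoran value);
2. the mandible cartilage is seated against the cranium cartilage by rigid
   iterative-closest-point registration, then backed off along the mean
   articular normal until the two cartilage layers just touch;
3. cartilage contact points (signed gap below a small tolerance) are averaged
   per side; the two per-side points define the rotation axis;
4. the mandible is rotated open about that axis until the first bone-bone
   contact anywhere outside the cartilage-covered articular facets, located
   by bisection to 0.01 degrees;
5. a soft-tissue back-off is subtracted to give the final maximum gape,
   reported through the 2-D gape metric: the interior angle upper mesial
   incisor - jaw joint - lower mesial incisor.

The same module holds the hinge assembly used by the static bite solves and
the canine arc-centre geometry (least-squares circle fit through the distal
canine margin, and the fulcrum-to-circumference centre ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from sabrebite.geometry import SurfaceDistance, kabsch, rotation_about_axis
from sabrebite.synthetic import SkullModel

_MANDIBLE_LANDMARK_PREFIXES = ("lower_", "mandible_")


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def gape_angle(upper_incisor, joint, lower_incisor) -> float:
    """Interior angle (degrees) at the jaw joint between the two incisor
    landmarks; the study's 2-D gape metric."""
    u = np.asarray(upper_incisor, dtype=float) - joint
    l = np.asarray(lower_incisor, dtype=float) - joint
    nu, nl = np.linalg.norm(u), np.linalg.norm(l)
    if nu < 1e-12 or nl < 1e-12:
        raise ValueError("gape angle undefined for coincident points")
    c = np.clip(u @ l / (nu * nl), -1.0, 1.0)
    return math.degrees(math.acos(c))


def model_gape_angle(skull: SkullModel) -> float:
    return gape_angle(skull.landmarks["upper_mesial_incisor"],
                      skull.jaw_joint_mid(),
                      skull.landmarks["lower_mesial_incisor"])


def rotate_mandible(skull: SkullModel, angle_deg: float,
                    axis_point=None, axis_dir=None) -> SkullModel:
    """Rigidly open the jaw by ``angle_deg`` about the hinge axis.

    Positive angles open the jaw (anterior mandible moves ventrally); the
    cranium, its landmarks and the axis are untouched.  The stored hinge axis
    is used unless an explicit axis is given.
    """
    if not (-10.0 < angle_deg < 150.0):
        raise ValueError("rotation angle outside the sane gape range "
                         "(-10, 150) degrees")
    p = skull.joint_axis_point if axis_point is None else np.asarray(axis_point)
    d = skull.joint_axis_dir if axis_dir is None else np.asarray(axis_dir)
    # opening = negative rotation about +z in the +x-anterior/+y-dorsal frame
    R, t = rotation_about_axis(p, d, -angle_deg)
    return transform_mandible(skull, R, t)


def transform_mandible(skull: SkullModel, R, t) -> SkullModel:
    """Apply an arbitrary rigid transform to the mandible and its landmarks."""
    out = skull.copy()
    out.mandible = skull.mandible.transformed(rotation=R, translation=t)
    for name, lm in skull.landmarks.items():
        if name.startswith(_MANDIBLE_LANDMARK_PREFIXES):
            out.landmarks[name] = np.asarray(R) @ lm + np.asarray(t)
    return out


# ---------------------------------------------------------------------------
# cartilage offset
# ---------------------------------------------------------------------------

def patch_surface(skull: SkullModel, name: str):
    """(vertices, faces, vertex_areas) of an attachment patch as a compact
    re-indexed triangle surface."""
    patch = skull.patch(name)
    mesh = skull.mesh_of(patch.mesh)
    nodes = patch.nodes
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    verts = mesh.nodes[nodes]
    faces = remap[patch.faces]
    v = verts[faces]
    fa = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                              axis=1)
    va = np.zeros(len(verts))
    for k in range(3):
        np.add.at(va, faces[:, k], fa / 3.0)
    return verts, faces, va


def _vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = verts[faces]
    fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])   # area-weighted
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(norm, 1e-30)


def extrude_cartilage(surface, thickness: float = 1.0):
    """Offset an oriented patch by ``thickness`` along area-weighted vertex
    normals, emulating the articular cartilage layer.

    ``surface`` is a ``(vertices, faces)`` pair or a trimesh; the result is a
    ``(vertices, faces)`` pair with the same connectivity.  Warns (but does
    not fail) if the offset folds the patch onto itself.
    """
    if hasattr(surface, "vertices"):
        verts, faces = (np.asarray(surface.vertices, dtype=float),
                        np.asarray(surface.faces, dtype=np.int64))
    else:
        verts, faces = (np.asarray(surface[0], dtype=float),
                        np.asarray(surface[1], dtype=np.int64))
    if thickness == 0.0:
        return verts.copy(), faces.copy()
    vn = _vertex_normals(verts, faces)
    out = verts + thickness * vn
    if len(faces):
        sd = SurfaceDistance(verts, faces)
        d, _, _ = sd.closest(out)
        if (d < 0.5 * abs(thickness)).any():
            warnings.warn("cartilage offset self-intersects the source patch",
                          RuntimeWarning, stacklevel=2)
    return out, faces.copy()


# ---------------------------------------------------------------------------
# iterative closest point
# ---------------------------------------------------------------------------

def icp_register(source: np.ndarray, target: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-8):
    """Rigid ICP of ``source`` points onto ``target`` points.

    Alternates nearest-neighbour correspondence with a least-squares rigid
    fit (SVD); the RMS correspondence distance is non-increasing.  Returns
    ``(R, t, rms_history)`` with ``x_registered = R x + t``.
    """
    from scipy.spatial import cKDTree

    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    for pts, name in ((source, "source"), (target, "target")):
        if len(pts) < 3:
            raise ValueError(f"{name} needs at least 3 points")
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise ValueError(f"{name} points are collinear")
    tree = cKDTree(target)
    R = np.eye(3)
    t = np.zeros(3)
    cur = source.copy()
    rms_hist = []
    for _ in range(max_iter):
        d, idx = tree.query(cur)
        rms = float(np.sqrt(np.mean(d**2)))
        rms_hist.append(rms)
        Ri, ti = kabsch(cur, target[idx])
        cur = cur @ Ri.T + ti
        R = Ri @ R
        t = Ri @ t + ti
        if len(rms_hist) > 1 and abs(rms_hist[-2] - rms) < tol:
            break
    d, _ = tree.query(cur)
    rms_hist.append(float(np.sqrt(np.mean(d**2))))
    return R, t, rms_hist


def _icp_to_surface(source: np.ndarray, target_sd: SurfaceDistance,
                    max_iter: int = 30, tol: float = 1e-9,
                    rotation: bool = True):
    """ICP variant with point-to-surface correspondences (closest points on
    the target triangles rather than its vertices); used for seating, where
    the target surface is sparsely meshed relative to the source.

    With ``rotation=False`` only the translation is estimated.  Seating an
    already-articulated jaw uses this mode: the rotational freedom of a
    condyle in its fossa is the hinge DOF itself, which the gape search
    explores separately, so letting ICP drift along it would silently
    pre-rotate the jaw.
    """
    R = np.eye(3)
    t = np.zeros(3)
    cur = np.asarray(source, dtype=float).copy()
    rms_hist = []
    for _ in range(max_iter):
        d, cp, fi = target_sd.closest(cur)
        rms = float(np.sqrt(np.mean(d**2)))
        rms_hist.append(rms)
        if rotation:
            Ri, ti = kabsch(cur, cp)
        else:
            # point-to-plane translation: minimise sum(((p + t - cp).n)^2);
            # the minimal-norm lstsq solution carries no tangential drift on
            # flat contact (where sliding is unobservable)
            n = target_sd._normals[fi]
            A = n.T @ n
            b = n.T @ np.einsum("ij,ij->i", cp - cur, n)
            ti = np.linalg.lstsq(A, b, rcond=1e-8)[0]
            Ri = np.eye(3)
        cur = cur @ Ri.T + ti
        R = Ri @ R
        t = Ri @ t + ti
        if len(rms_hist) > 1 and abs(rms_hist[-2] - rms) < tol:
            break
    return R, t, rms_hist


# ---------------------------------------------------------------------------
# circle fit / arc-centre ratio
# ---------------------------------------------------------------------------

@dataclass
class ArcFit:
    """Least-squares circle through lateral-plane canine margin points."""

    center: np.ndarray
    radius: float
    rms_residual: float
    fulcrum: np.ndarray | None = None
    center_ratio: float | None = None


def fit_canine_arc(points) -> ArcFit:
    """Geometric least-squares circle fit (algebraic Kasa initialisation,
    Levenberg-Marquardt refinement); order-invariant."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 lateral-plane (x, y) points")
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; no circle fit exists")
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[:2]
    r0 = math.sqrt(max(sol[2] + cx**2 + cy**2, 1e-30))

    def resid(q):
        return np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1]) - q[2]

    out = least_squares(resid, x0=[cx, cy, r0], method="lm")
    cx, cy, r = out.x
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return ArcFit(center=np.array([cx, cy]), radius=float(abs(r)),
                  rms_residual=rms)


def arc_center_ratio(fit: ArcFit, fulcrum) -> float:
    """Distance of the arc centre from the fulcrum as a fraction of the
    fulcrum-to-circumference distance along the ray through the centre.

    The far intersection of that ray with the circle lies at
    ``|fulcrum - centre| + radius`` from the fulcrum, so the ratio is
    ``d / (d + r)``: 0 when the fulcrum is the centre, 0.5 when the fulcrum
    lies on the circle.
    """
    fulcrum = np.asarray(fulcrum, dtype=float)
    d = float(np.linalg.norm(fulcrum - fit.center))
    ratio = d / (d + fit.radius)
    fit.fulcrum = fulcrum
    fit.center_ratio = ratio
    return ratio


# ---------------------------------------------------------------------------
# hinge assembly
# ---------------------------------------------------------------------------

@dataclass
class HingeAssembly:
    """Description of the TMJ hinge mechanism for the static solves.

    Per side: the articular plate nodes of condyle (mandible) and cotyle
    (cranium) connect to a node on the joint axis; a fine beam network along
    the plate triangle edges spreads the attachment (minimising the stress
    singularity a single-node pivot would cause); the two coincident axis
    nodes per side are coupled by a revolute joint releasing only the
    rotation about the axis; a stiff axle beam joins the two sides.
    """

    axis_points: dict                  # side -> (3,)
    axis_dir: np.ndarray
    cranium_plate_nodes: dict          # side -> cranium node indices
    mandible_plate_nodes: dict         # side -> mandible node indices
    cranium_attach_nodes: dict         # side -> subset receiving rigid links
    mandible_attach_nodes: dict
    cranium_edges: np.ndarray          # (n, 2) plate-edge beam network
    mandible_edges: np.ndarray
    spread: bool = True


def _plate_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def build_tmj_hinge(skull: SkullModel, spread: bool = True) -> HingeAssembly:
    """Build the hinge description from the condyle/cotyle plates.

    With ``spread=False`` each side attaches through a single plate node
    (the historical single-node pivot); with ``spread=True`` the attachment
    is distributed over the whole plate plus an edge beam network.
    """
    cond = skull.patch("condyle_plate")
    coty = skull.patch("cotyle_plate")
    if len(cond.faces) == 0 or len(coty.faces) == 0:
        raise ValueError("articular plates are missing or degenerate")
    mand = skull.mandible
    cran = skull.cranium
    axis_p = skull.joint_axis_point
    axis_d = skull.joint_axis_dir / np.linalg.norm(skull.joint_axis_dir)

    half = 0.5 * np.abs(mand.nodes[:, 2]).max()
    axis_points = {"left": axis_p + half * axis_d,
                   "right": axis_p - half * axis_d}
    cran_nodes, mand_nodes, cran_at, mand_at = {}, {}, {}, {}
    for side, sign in (("left", 1.0), ("right", -1.0)):
        cn = coty.nodes[np.sign(cran.nodes[coty.nodes, 2]) == sign]
        mn = cond.nodes[np.sign(mand.nodes[cond.nodes, 2]) == sign]
        if len(cn) == 0 or len(mn) == 0:
            raise ValueError(f"articular plates empty on the {side} side")
        cran_nodes[side] = cn
        mand_nodes[side] = mn
        if spread:
            cran_at[side] = cn
            mand_at[side] = mn
        else:
            ap = axis_points[side]
            cran_at[side] = cn[[int(np.argmin(
                np.linalg.norm(cran.nodes[cn] - ap, axis=1)))]]
            mand_at[side] = mn[[int(np.argmin(
                np.linalg.norm(mand.nodes[mn] - ap, axis=1)))]]
    return HingeAssembly(
        axis_points=axis_points, axis_dir=axis_d,
        cranium_plate_nodes=cran_nodes, mandible_plate_nodes=mand_nodes,
        cranium_attach_nodes=cran_at, mandible_attach_nodes=mand_at,
        cranium_edges=(_plate_edges(coty.faces) if spread
                       else np.empty((0, 2), int)),
        mandible_edges=(_plate_edges(cond.faces) if spread
                        else np.empty((0, 2), int)),
        spread=spread,
    )


# ---------------------------------------------------------------------------
# maximum gape
# ---------------------------------------------------------------------------

@dataclass
class GapeResult:
    """Output of the maximum-gape search."""

    rotation_axis_points: np.ndarray     # (2, 3): left / right contact points
    max_gape_deg: float
    bone_contact_gape_deg: float
    soft_tissue_backoff_deg: float
    cartilage_mm: float
    rotation_to_contact_deg: float       # jaw rotation at bone contact
    contact_points: np.ndarray           # cartilage contact points (n, 3)
    seating_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    seating_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    icp_rms: list = field(default_factory=list)

    @property
    def axis_dir(self) -> np.ndarray:
        d = self.rotation_axis_points[0] - self.rotation_axis_points[1]
        return d / np.linalg.norm(d)


def _mandible_contact_samples(skull: SkullModel,
                              articular_margin_mm: float = 1.0) -> np.ndarray:
    """Mandible surface sample points for bone-contact detection.

    The cartilage-covered articular facet plus a collar of
    ``articular_margin_mm`` around it is excluded: the condylar head cannot
    make bone-bone contact through its cartilage, and rotation about a
    surface-contact axis would otherwise graze the facet's own shoulders
    immediately.
    """
    mand = skull.mandible
    faces = mand.boundary_faces()
    plate = skull.patch("condyle_plate")
    plate_v, plate_f, _ = patch_surface(skull, "condyle_plate")
    plate_sd = SurfaceDistance(plate_v, plate_f)
    plate_keys = {tuple(sorted(f)) for f in plate.faces}
    keep = np.array([tuple(sorted(f)) not in plate_keys for f in faces])
    faces = faces[keep]
    verts = np.unique(faces)
    samples = np.vstack([mand.nodes[verts], mand.nodes[faces].mean(axis=1)])
    dist, _, _ = plate_sd.closest(samples)
    return samples[dist > articular_margin_mm]


def find_max_gape(skull: SkullModel, cartilage_mm: float = 1.0,
                  backoff_deg: float = 2.0, contact_tol: float = 0.05,
                  angle_res_deg: float = 0.01, max_angle_deg: float = 150.0,
                  icp_max_iter: int = 30) -> GapeResult:
    """Estimate the maximum gape angle of an articulated skull model.

    Implements cartilage extrusion, ICP seating with a just-touch back-off,
    the contact-derived rotation axis, bisection to the first bone-bone
    contact outside the articular facets, and soft-tissue back-off.  Raises
    if no bone contact occurs within ``max_angle_deg``.
    """
    if backoff_deg < 0 or cartilage_mm < 0:
        raise ValueError("cartilage and backoff must be non-negative")

    # 1. cartilage layers
    cond_v, cond_f, _ = patch_surface(skull, "condyle_plate")
    coty_v, coty_f, _ = patch_surface(skull, "cotyle_plate")
    cart_cond_v, _ = extrude_cartilage((cond_v, cond_f), cartilage_mm)
    cart_coty_v, cart_coty_f = extrude_cartilage((coty_v, coty_f), cartilage_mm)

    # 2. ICP seating of mandible cartilage onto cranium cartilage
    # (translation-only: the rotational freedom is the hinge DOF itself)
    target_sd = SurfaceDistance(cart_coty_v, cart_coty_f)
    R, t, rms = _icp_to_surface(cart_cond_v, target_sd, max_iter=icp_max_iter,
                                rotation=False)

    # back off along the mean cranial articular normal until just touching
    coty_n = _vertex_normals(cart_coty_v, cart_coty_f)
    n_mean = coty_n.mean(axis=0)
    n_mean /= np.linalg.norm(n_mean)

    def signed_gaps(extra_shift):
        pts = cart_cond_v @ R.T + t + extra_shift
        d, cp, fi = target_sd.closest(pts)
        v = pts - cp
        face_n = target_sd._normals[fi]
        return np.where(np.einsum("ij,ij->i", v, face_n) >= 0, d, -d), pts

    shift = np.zeros(3)
    for _ in range(4):
        gaps, _ = signed_gaps(shift)
        h = gaps.min()
        if abs(h) < 1e-9:
            break
        shift = shift - h * n_mean
    t = t + shift

    # 3. contact points -> rotation axis (widen the tolerance if contact is
    # so localised that one side has no points)
    gaps, seated_pts = signed_gaps(np.zeros(3))
    zmid = float(np.median(seated_pts[:, 2]))
    left = right = None
    for tol_k in (1.0, 2.0, 4.0, 8.0):
        contact = seated_pts[gaps <= contact_tol * tol_k]
        if len(contact) == 0:
            continue
        left = contact[contact[:, 2] >= zmid]
        right = contact[contact[:, 2] < zmid]
        if len(left) and len(right):
            break
    if left is None or len(left) == 0 or right is None or len(right) == 0:
        raise RuntimeError("cartilage contact is not bilateral")
    ax_l = left.mean(axis=0)
    ax_r = right.mean(axis=0)
    axis_point = 0.5 * (ax_l + ax_r)
    axis_dir = ax_l - ax_r
    axis_dir = axis_dir / np.linalg.norm(axis_dir)

    # 4. bisection to first bone-bone contact (articular facets excluded).
    # Contact is "unsigned surface distance below a touch threshold": the
    # first touch is what the search brackets, so penetration never needs a
    # signed test (which is fragile at grazing corner features).
    bone_touch = max(0.25 * contact_tol, 1e-3)
    seated = transform_mandible(skull, R, t)
    samples0 = _mandible_contact_samples(seated)
    cran_faces = skull.cranium.boundary_faces()
    cran_sd = SurfaceDistance(skull.cranium.nodes, cran_faces)

    def bone_dists(theta):
        Rr, tr = rotation_about_axis(axis_point, axis_dir, -theta)
        pts = samples0 @ Rr.T + tr
        return cran_sd.closest(pts)[0]

    # per-sample approach-rate bound: a point at radius rho about the axis
    # moves at most rho * pi/180 mm per degree, so stepping by
    # 0.8 * min(d / rate) can never skip the first touch (Lipschitz march)
    rel = samples0 - axis_point
    rel -= np.outer(rel @ axis_dir, axis_dir)
    rates = np.maximum(np.linalg.norm(rel, axis=1), 1e-6) * np.pi / 180.0

    theta_contact = None
    theta = 0.0
    d = bone_dists(theta)
    if d.min() <= bone_touch:
        raise RuntimeError("bone-bone contact already present at the seated "
                           "pose; geometry invalid for gape search")
    while theta < max_angle_deg:
        step = float(max(angle_res_deg, (0.8 * d / rates).min()))
        theta += step
        d = bone_dists(theta)
        if d.min() <= bone_touch:
            theta_contact = theta
            break
    if theta_contact is None:
        raise RuntimeError(f"no bone-bone contact within {max_angle_deg} deg "
                           "of jaw opening")

    # 5. gape metric at contact and after soft-tissue back-off
    at_contact = rotate_mandible(seated, theta_contact,
                                 axis_point=axis_point, axis_dir=axis_dir)
    bone_gape = model_gape_angle(at_contact)
    max_gape = bone_gape - backoff_deg
    return GapeResult(
        rotation_axis_points=np.vstack([ax_l, ax_r]),
        max_gape_deg=max_gape,
        bone_contact_gape_deg=bone_gape,
        soft_tissue_backoff_deg=backoff_deg,
        cartilage_mm=cartilage_mm,
        rotation_to_contact_deg=theta_contact,
        contact_points=contact,
        seating_rotation=R,
        seating_translation=t,
        icp_rms=rms,
    )
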