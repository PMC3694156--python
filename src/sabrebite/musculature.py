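"""Muscle systems: jaw-adductor truss fans and head-depressor web assemblies.

Two muscle systems drive the bite simulations:

* jaw adductors (temporalis and the masseter complex) as fans of pretensioned
  truss elements running from cranial origin patches to mandibular insertion
  patches, with force magnitudes from the dry-skull method (projected muscle
  chamber area x specific tension, 0.3 MPa by default — a deliberate
  underestimate since pennation is ignored);
* head depressors (M. sternomastoideus, 40 trusses; M. obliquus capitis, 30
  trusses; 25 N pretension each) pulling the mastoid/occipital region toward
  two rigid-link attachment webs — an ellipse and a circle, mutually
  perpendicular, whose centre nodes are fixed in all six degrees of freedom.

Muscle tension is held constant with gape throughout (pretension force pairs
do not depend on element length), so performance at wide gapes is, if
anything, overestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sabrebite.synthetic import SkullModel

ADDUCTOR_GROUPS = ("temporalis", "masseter_complex")
DEPRESSOR_GROUPS = ("sternomastoideus", "obliquus_capitis")
DEFAULT_SPECIFIC_TENSION = 0.3      # MPa (300 kPa)


@dataclass
class MuscleGroup:
    """One named muscle group discretised into trusses."""

    name: str
    origin_patch: str
    insertion_patch: str
    n_trusses: int
    force_per_truss: float          # N (adductor force or depressor pretension)
    via_point: np.ndarray | None = None

    def __post_init__(self):
        if self.n_trusses < 1:
            raise ValueError("n_trusses must be >= 1")
        if self.force_per_truss < 0:
            raise ValueError("per-truss force must be non-negative")

    @property
    def total_force(self) -> float:
        return self.n_trusses * self.force_per_truss


@dataclass
class MuscleTruss:
    """Geometric description of one muscle truss (before FE attachment)."""

    origin: np.ndarray              # on the cranium
    insertion: np.ndarray           # on the mandible (or a web rim point)
    force: float                    # N, applied as pretension
    group: str = ""
    via: np.ndarray | None = None   # optional frictionless via-point ("hinge")


@dataclass
class AttachmentWeb:
    """Rigid-link attachment web for the head depressors.

    A planar ellipse or circle of rim points rigid-linked to a centre node
    that is fixed in all six degrees of freedom.
    """

    shape: str                      # "ellipse" | "circle"
    center: np.ndarray
    normal: np.ndarray
    rim_points: np.ndarray          # (n, 3)
    semi_axes: tuple                # (a, b) mm; a == b for circles

    def __post_init__(self):
        if self.shape not in ("ellipse", "circle"):
            raise ValueError("web shape must be 'ellipse' or 'circle'")
        if min(self.semi_axes) <= 0:
            raise ValueError("web dimensions must be positive")
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))


@dataclass
class DepressorSystem:
    webs: list
    trusses: list                   # MuscleTruss with insertion = rim point
    n_sterno: int
    n_obliquus: int
    pretension: float

    @property
    def force_budget(self) -> float:
        """Scalar pretension budget: element count x per-element pretension."""
        return (self.n_sterno + self.n_obliquus) * self.pretension


@dataclass
class DryskullSpec:
    """Dry-skull muscle force estimation inputs.

    ``areas`` maps adductor group names to projected cross-sectional areas
    (mm^2); forces are area x specific tension.  The method underestimates
    true forces because pennation is not corrected for.
    """

    areas: dict
    specific_tension: float = DEFAULT_SPECIFIC_TENSION

    def __post_init__(self):
        if self.specific_tension <= 0:
            raise ValueError("specific tension must be positive")
        for g, a in self.areas.items():
            if a <= 0:
                raise ValueError(f"area for '{g}' must be positive")

    def force(self, group: str) -> float:
        return dry_skull_force(self.areas[group], self.specific_tension)


def write_muscle_csv(trusses, path) -> None:
    """Dump truss endpoints and forces (mm, N) to CSV."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["group", "ox_mm", "oy_mm", "oz_mm",
                    "ix_mm", "iy_mm", "iz_mm", "force_n"])
        for t in trusses:
            w.writerow([t.group] + [f"{v:.9g}" for v in (*t.origin,
                                                         *t.insertion)]
                       + [f"{t.force:.9g}"])


def dry_skull_force(area: float, specific_tension: float) -> float:
    """Muscle force (N) = projected cross-sectional area (mm^2) x specific
    tension (MPa)."""
    if area <= 0:
        raise ValueError("area must be positive")
    if specific_tension <= 0:
        raise ValueError("specific tension must be positive")
    return area * specific_tension


def projected_patch_area(surface, projection_normal) -> float:
    """Silhouette area (mm^2) of a triangle patch projected along ``normal``.

    Overlapping triangles are not double-counted: the projected triangles are
    unioned as polygons in the projection plane (shapely).  ``surface`` is a
    ``(vertices, faces)`` pair or trimesh.
    """
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    if hasattr(surface, "vertices"):
        verts, faces = np.asarray(surface.vertices), np.asarray(surface.faces)
    else:
        verts, faces = np.asarray(surface[0], float), np.asarray(surface[1])
    if len(faces) == 0:
        raise ValueError("patch is empty")
    n = np.asarray(projection_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate projection normal")
    n = n / norm
    # orthonormal basis of the projection plane
    ref = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    p2 = verts @ np.column_stack([u, v])
    polys = []
    for f in faces:
        tri = Polygon(p2[f])
        if tri.is_valid and tri.area > 1e-12:
            polys.append(tri)
    if not polys:
        return 0.0
    return float(unary_union(polys).area)


# ---------------------------------------------------------------------------
# anchor sampling
# ---------------------------------------------------------------------------

def sample_patch_points(verts: np.ndarray, faces: np.ndarray, n: int,
                        seed: int) -> np.ndarray:
    """Reproducible, approximately uniform anchor points on a patch.

    Stratified by area: faces are picked at evenly spaced quantiles of the
    cumulative area distribution (with a seeded jitter) and a seeded
    barycentric point is drawn in each.
    """
    rng = np.random.default_rng(seed)
    if len(faces) == 0:
        raise ValueError("cannot sample an empty patch")
    w = np.linalg.norm(np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                                verts[faces[:, 2]] - verts[faces[:, 0]]),
                       axis=1)
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    q = (np.arange(n) + rng.uniform(0, 1, n)) / n
    idx = np.searchsorted(cdf, q)
    r1, r2 = rng.uniform(0, 1, (2, n))
    s = np.sqrt(r1)
    b = np.column_stack([1 - s, s * (1 - r2), s * r2])
    tri = verts[faces[idx]]
    return np.einsum("nk,nkd->nd", b, tri)


def sample_patch_points_bilateral(verts: np.ndarray, faces: np.ndarray,
                                  n: int, seed: int) -> np.ndarray:
    """Mirror-symmetric anchor sampling: n/2 seeded points on the left
    (z > 0) half of the patch, reflected across the sagittal plane.

    Muscles are bilateral; sampling one side and mirroring keeps the loading
    symmetric, so symmetric models produce symmetric bite reactions.  Falls
    back to plain sampling for patches confined to one side.
    """
    if n % 2:
        raise ValueError("bilateral sampling needs an even truss count")
    cent_z = verts[faces].mean(axis=1)[:, 2]
    left = faces[cent_z > 0]
    if len(left) == 0:
        return sample_patch_points(verts, faces, n, seed)
    pts = sample_patch_points(verts, left, n // 2, seed)
    return np.vstack([pts, pts * np.array([1.0, 1.0, -1.0])])


# ---------------------------------------------------------------------------
# adductor fans
# ---------------------------------------------------------------------------

def default_adductor_groups(skull: SkullModel,
                            spec: DryskullSpec | dict | None = None,
                            n_trusses: int = 10,
                            via_points: dict | None = None) -> list:
    """Temporalis and masseter-complex groups with dry-skull force magnitudes.

    ``spec`` may be a DryskullSpec, an explicit ``{group: total force N}``
    mapping, or None (areas are then measured from the skull's own origin
    patches, projected along the mean muscle line of action)."""
    from sabrebite.gape import patch_surface

    groups = []
    for name, opatch, ipatch in (
            ("temporalis", "temporalis_origin", "temporalis_insertion"),
            ("masseter_complex", "masseter_origin", "masseter_insertion")):
        if isinstance(spec, dict):
            total = float(spec[name])
        elif isinstance(spec, DryskullSpec):
            total = spec.force(name)
        else:
            # face-on silhouette of the origin chamber: project along the
            # patch's dominant normal (the dry-skull chamber-area analogue)
            overt, ofac, _ = patch_surface(skull, opatch)
            v = overt[ofac]
            fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
            dom = np.abs(fn.sum(axis=0))
            if dom.max() < 1e-9:       # bilateral patch: normals cancel
                dom = np.abs(fn).sum(axis=0)
            normal = np.zeros(3)
            normal[int(np.argmax(dom))] = 1.0
            area = projected_patch_area((overt, ofac), normal)
            total = dry_skull_force(area, DEFAULT_SPECIFIC_TENSION)
        groups.append(MuscleGroup(
            name=name, origin_patch=opatch, insertion_patch=ipatch,
            n_trusses=n_trusses, force_per_truss=total / n_trusses,
            via_point=(via_points or {}).get(name)))
    return groups


def build_adductor_fans(skull: SkullModel, groups=None,
                        spec: DryskullSpec | dict | None = None,
                        n_trusses: int = 10, seed: int = 0) -> list:
    """Build the jaw-adductor truss fans.

    Returns MuscleTruss records spanning seeded anchor points on the origin
    (cranium) and insertion (mandible) patches; per-truss force is the group
    total divided by the truss count, so the budget is conserved exactly.
    """
    from sabrebite.gape import patch_surface

    if groups is None:
        groups = default_adductor_groups(skull, spec, n_trusses)
    trusses = []
    for gi, g in enumerate(groups):
        opatch = skull.patch(g.origin_patch)
        ipatch = skull.patch(g.insertion_patch)
        if opatch.mesh != "cranium" or ipatch.mesh != "mandible":
            raise ValueError(f"group '{g.name}': origin must lie on the "
                             "cranium and insertion on the mandible")
        overt, ofac, _ = patch_surface(skull, g.origin_patch)
        ivert, ifac, _ = patch_surface(skull, g.insertion_patch)
        opts = sample_patch_points_bilateral(overt, ofac, g.n_trusses,
                                             seed + 101 * gi)
        ipts = sample_patch_points_bilateral(ivert, ifac, g.n_trusses,
                                             seed + 101 * gi + 57)
        for o, i in zip(opts, ipts):
            trusses.append(MuscleTruss(origin=o, insertion=i,
                                       force=g.force_per_truss, group=g.name,
                                       via=g.via_point))
    return trusses


# ---------------------------------------------------------------------------
# head-depressor system
# ---------------------------------------------------------------------------

def _web_rim(center, normal, a, b, n) -> np.ndarray:
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0, 0, 1.0]) if abs(normal[2]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    # half-step offset keeps the rim mirror-symmetric about z = 0 with no
    # points on the midline, so bilateral truss pairing is exact
    th = 2 * np.pi * (np.arange(n) + 0.5) / n
    return (np.asarray(center, float)
            + np.outer(a * np.cos(th), u) + np.outer(b * np.sin(th), v))


def build_depressor_system(skull: SkullModel, ellipse_axes=(40.0, 26.0),
                           circle_radius: float = 30.0, n_sterno: int = 40,
                           n_obliquus: int = 30, pretension: float = 25.0,
                           standoff_frac: float = 0.5,
                           seed: int = 0) -> DepressorSystem:
    """Head-depressor webs and truss arrays.

    ``ellipse_axes`` are the full major/minor axes (mm) and ``circle_radius``
    the circle radius, as printed per taxon; the webs sit caudal to the
    occiput at ``standoff_frac`` x skull length, the circle's normal along x
    and the ellipse's along y (mutually perpendicular).  Sternomastoideus
    trusses (40 by default) run to the circle rim, obliquus capitis trusses
    (30) to the ellipse rim; every truss carries the same pretension
    (25 N by default), so the scalar budget is (40 + 30) x 25 = 1750 N.
    """
    if min(ellipse_axes) <= 0 or circle_radius <= 0:
        raise ValueError("web dimensions must be positive")
    if pretension < 0:
        raise ValueError("pretension must be non-negative")
    from sabrebite.gape import patch_surface

    L = skull.skull_length
    x_web = -0.20 * L - standoff_frac * L
    circle_center = np.array([x_web, -0.05 * L, 0.0])
    ellipse_center = np.array([x_web, 0.05 * L, 0.0])
    webs = [
        AttachmentWeb("circle", circle_center, np.array([1.0, 0, 0]),
                      _web_rim(circle_center, [1, 0, 0], circle_radius,
                               circle_radius, n_sterno),
                      (circle_radius, circle_radius)),
        AttachmentWeb("ellipse", ellipse_center, np.array([0, 1.0, 0]),
                      _web_rim(ellipse_center, [0, 1, 0],
                               0.5 * ellipse_axes[0], 0.5 * ellipse_axes[1],
                               n_obliquus),
                      (0.5 * ellipse_axes[0], 0.5 * ellipse_axes[1])),
    ]
    mvert, mfac, _ = patch_surface(skull, "mastoid_region")
    cent_z = mvert[mfac].mean(axis=1)[:, 2]
    left_faces = mfac[cent_z > 0]
    if len(left_faces) == 0:
        left_faces = mfac
    trusses = []
    mirror = np.array([1.0, 1.0, -1.0])
    for n, web, group, sd in ((n_sterno, webs[0], "sternomastoideus", 11),
                              (n_obliquus, webs[1], "obliquus_capitis", 13)):
        if n % 2:
            raise ValueError(f"{group}: bilateral pairing needs an even "
                             "truss count")
        # pair left-side anchors with left-side rim points (both z-sorted),
        # then mirror the pairs, so loading is exactly bilateral
        anc = sample_patch_points(mvert, left_faces, n // 2, seed + sd)
        anc = anc[np.argsort(anc[:, 2])]
        rim = web.rim_points[web.rim_points[:, 2] > 0]
        rim = rim[np.argsort(rim[:, 2])]
        for a, r in zip(anc, rim):
            trusses.append(MuscleTruss(origin=a, insertion=r,
                                       force=pretension, group=group))
            trusses.append(MuscleTruss(origin=a * mirror, insertion=r * mirror,
                                       force=pretension, group=group))
    return DepressorSystem(webs=webs, trusses=trusses, n_sterno=n_sterno,
                           n_obliquus=n_obliquus, pretension=pretension)
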