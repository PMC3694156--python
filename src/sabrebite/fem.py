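"""Linear-elastic finite-element core.

Element inventory is deliberately small — exactly what the biting simulations
need: four-noded constant-strain tetrahedra (tet4 "bricks") for bone, dentine
and enamel; two-node axial truss elements carrying muscle pretension; 3-D
Euler-Bernoulli beams (jaw-hinge pivot, articular plate stiffeners); rigid
links (kinematic master-slave coupling, used for canine attachment and the
head-depressor attachment webs); and nodal constraints.

Kinematic couplings (rigid links, revolute hinges) are imposed exactly by
master-slave DOF elimination, not penalties: the assembled stiffness is
congruence-transformed K -> T'KT before constrained DOFs are partitioned out.
Pretension is applied as a constant external collinear force pair along the
truss axis (linear analysis, no geometric stiffness), so muscle tension does
not vary with gape by construction.

Units: mm, N, MPa (N/mm^2), N*mm for moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from sabrebite.mesh import TetMesh

DOF_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz")
ALL_DOFS = frozenset(DOF_NAMES)
TRANSLATIONS = ("tx", "ty", "tz")


class UnderConstrainedError(RuntimeError):
    """Raised when the constrained system still has zero-energy modes."""

    def __init__(self, message, n_modes=None):
        super().__init__(message)
        self.n_modes = n_modes


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (E in MPa)."""

    name: str
    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"{self.name}: E must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError(f"{self.name}: nu must lie in [0, 0.5)")

    @property
    def D(self) -> np.ndarray:
        """6x6 constitutive matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


def default_materials() -> dict:
    """Literature-order default properties.

    The comparative analyses in this package are material-relative (ratios,
    linear scalings), so these defaults set the stress scale only; all are
    configurable per run.
    """
    return {
        0: Material("cortical_bone", E=20_000.0, nu=0.30),
        1: Material("dentine", E=21_000.0, nu=0.31),
        2: Material("enamel", E=80_000.0, nu=0.30),
    }


@dataclass
class TrussElement:
    """Axial-only two-node element; ``pretension`` (N) models muscle pull."""

    nodes: tuple
    cross_section: float = 1.0       # mm^2
    E: float = 10.0                  # MPa; soft, muscle-like default
    pretension: float = 0.0          # N
    group: str = ""

    def __post_init__(self):
        if self.cross_section <= 0:
            raise ValueError("truss cross-section must be positive")
        if self.nodes[0] == self.nodes[1]:
            raise ValueError("truss nodes must be distinct")
        if self.pretension < 0:
            raise ValueError("pretension must be non-negative")


@dataclass
class BeamElement:
    """3-D Euler-Bernoulli beam with optional rotational end releases.

    ``releases`` lists (end, axis) pairs with end in {0, 1} and axis in
    {"rx", "ry", "rz"} referring to the beam's local frame (local x along the
    beam); released DOFs are condensed out of the element matrix.
    """

    nodes: tuple
    area: float                      # mm^2
    Iy: float                        # mm^4
    Iz: float                        # mm^4
    J: float                         # mm^4
    E: float
    nu: float = 0.3
    releases: tuple = ()

    def __post_init__(self):
        if min(self.area, self.Iy, self.Iz, self.J) <= 0:
            raise ValueError("beam section properties must be positive")
        if self.nodes[0] == self.nodes[1]:
            raise ValueError("beam nodes must be distinct")


@dataclass
class RigidLink:
    """Slave nodes move as a rigid body with the master node."""

    master: int
    slaves: tuple

    def __post_init__(self):
        self.slaves = tuple(int(s) for s in np.atleast_1d(self.slaves))
        if self.master in self.slaves:
            raise ValueError("master cannot be its own slave")


@dataclass
class Hinge:
    """Revolute coupling: translations and off-axis rotations of ``slave``
    follow ``master``; relative rotation about ``axis`` stays free."""

    master: int
    slave: int
    axis: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n < 1e-12:
            raise ValueError("hinge axis must be nonzero")
        object.__setattr__(self, "axis", a / n)


@dataclass
class Constraint:
    """Fixed degrees of freedom at a node (homogeneous supports)."""

    node: int
    dofs: frozenset

    def __post_init__(self):
        dofs = frozenset(self.dofs)
        if not dofs:
            raise ValueError("constraint must fix at least one DOF")
        unknown = dofs - ALL_DOFS
        if unknown:
            raise ValueError(f"unknown DOFs {sorted(unknown)}")
        object.__setattr__(self, "dofs", dofs)


def von_mises(stress) -> np.ndarray | float:
    """Von Mises equivalent stress.

    Accepts a Voigt 6-vector (xx, yy, zz, xy, yz, zx), a symmetric 3x3 tensor,
    or arrays of either stacked along the first axis.  Rotation-invariant and
    zero for hydrostatic states.
    """
    s = np.asarray(stress, dtype=float)
    single = False
    if s.shape == (6,) or s.shape == (3, 3):
        s = s[None]
        single = True
    if s.ndim == 3 and s.shape[-2:] == (3, 3):
        v = np.stack([s[:, 0, 0], s[:, 1, 1], s[:, 2, 2],
                      s[:, 0, 1], s[:, 1, 2], s[:, 2, 0]], axis=1)
    elif s.ndim == 2 and s.shape[1] == 6:
        v = s
    else:
        raise ValueError("stress must be a 6-vector or 3x3 tensor (or stacks)")
    sx, sy, sz, txy, tyz, tzx = v.T
    vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                 + 3.0 * (txy**2 + tyz**2 + tzx**2))
    return float(vm[0]) if single else vm


def face_traction_loads(mesh: TetMesh, node_set, traction) -> list:
    """Consistent nodal loads for a uniform traction (MPa) on the boundary
    triangles whose vertices all lie in ``node_set``.

    Each triangle assigns a third of (area x traction) to each vertex, so a
    constant-stress state is reproduced exactly by the constant-strain tet.
    Returns ``(node, force, None)`` tuples for ``FEModel.solve(extra_loads=...)``.
    """
    traction = np.asarray(traction, dtype=float)
    members = np.zeros(mesh.n_nodes, dtype=bool)
    members[np.asarray(node_set, dtype=int)] = True
    faces = mesh.boundary_faces()
    faces = faces[members[faces].all(axis=1)]
    if not len(faces):
        raise ValueError("node set spans no boundary triangles")
    v = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    loads = {}
    for f, a in zip(faces, areas):
        for n in f:
            loads[int(n)] = loads.get(int(n), 0.0) + a / 3.0
    return [(n, w * traction, None) for n, w in sorted(loads.items())]


def apply_pretension(truss: TrussElement, coords: np.ndarray):
    """Equivalent nodal load pair for a pretensioned truss.

    Returns ``(node_i, f_i, node_j, f_j)``: equal-magnitude opposite collinear
    forces of the pretension magnitude along the current truss axis, pulling
    the two nodes together.  The scalar force budget of a truss set is
    therefore count x pretension.
    """
    i, j = truss.nodes
    d = coords[j] - coords[i]
    length = np.linalg.norm(d)
    if length < 1e-12:
        raise ValueError("zero-length truss cannot carry pretension")
    d = d / length
    return i, truss.pretension * d, j, -truss.pretension * d


# ---------------------------------------------------------------------------
# element stiffness kernels
# ---------------------------------------------------------------------------

def _tet_stiffness_batch(coords: np.ndarray, tets: np.ndarray, D: np.ndarray):
    """Vectorised tet4 stiffness: returns (M,12,12) matrices, volumes and the
    (M,6,12) strain-displacement matrices for stress recovery."""
    v = coords[tets]                                   # (M,4,3)
    M = len(tets)
    A = np.concatenate([np.ones((M, 4, 1)), v], axis=2)   # (M,4,4)
    vol = np.abs(np.linalg.det(A)) / 6.0
    Ainv = np.linalg.inv(A)                            # rows: 1,x,y,z coefs
    G = Ainv[:, 1:4, :].transpose(0, 2, 1)             # (M,4,3) grad N_i
    B = np.zeros((M, 6, 12))
    for i in range(4):
        gx, gy, gz = G[:, i, 0], G[:, i, 1], G[:, i, 2]
        c = 3 * i
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    Ke = np.einsum("mik,ij,mjl->mkl", B, D, B, optimize=True)
    Ke *= vol[:, None, None]
    return Ke, vol, B


def _truss_stiffness(truss: TrussElement, coords: np.ndarray):
    i, j = truss.nodes
    d = coords[j] - coords[i]
    L = np.linalg.norm(d)
    if L < 1e-12:
        raise ValueError("zero-length truss")
    d = d / L
    k = truss.E * truss.cross_section / L
    dd = k * np.outer(d, d)
    K = np.empty((6, 6))
    K[:3, :3] = dd
    K[3:, 3:] = dd
    K[:3, 3:] = -dd
    K[3:, :3] = -dd
    return K


_LOCAL_ROT = {"rx": 3, "ry": 4, "rz": 5}


def _beam_stiffness(beam: BeamElement, coords: np.ndarray):
    """12x12 global beam stiffness (local DOFs condensed for end releases)."""
    i, j = beam.nodes
    d = coords[j] - coords[i]
    L = np.linalg.norm(d)
    if L < 1e-9:
        raise ValueError("zero-length beam")
    ex = d / L
    # standard triad: local y = Z x x' (so for a beam along a global
    # horizontal axis, local z is global Z and "rz" bends in the horizontal
    # load plane); fall back to the Y reference for near-vertical beams
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    Lam = np.vstack([ex, ey, ez])

    E, nu = beam.E, beam.nu
    G = E / (2 * (1 + nu))
    k = np.zeros((12, 12))
    ax = E * beam.area / L
    k[np.ix_([0, 6], [0, 6])] = ax * np.array([[1, -1], [-1, 1]])
    to = G * beam.J / L
    k[np.ix_([3, 9], [3, 9])] = to * np.array([[1, -1], [-1, 1]])
    for (I, w) in ((beam.Iz, (1, 5, 7, 11)), (beam.Iy, (2, 4, 8, 10))):
        c = E * I / L**3
        m = c * np.array([
            [12, 6 * L, -12, 6 * L],
            [6 * L, 4 * L**2, -6 * L, 2 * L**2],
            [-12, -6 * L, 12, -6 * L],
            [6 * L, 2 * L**2, -6 * L, 4 * L**2],
        ])
        if w == (2, 4, 8, 10):       # bending about local y: rotation signs flip
            S = np.diag([1, -1, 1, -1])
            m = S @ m @ S
        k[np.ix_(w, w)] += m

    if beam.releases:
        rel = sorted({end * 6 + _LOCAL_ROT[ax_] for end, ax_ in beam.releases})
        keep = [q for q in range(12) if q not in rel]
        kaa = k[np.ix_(keep, keep)]
        kab = k[np.ix_(keep, rel)]
        kbb = k[np.ix_(rel, rel)]
        kc = kaa - kab @ np.linalg.pinv(kbb) @ kab.T
        k = np.zeros((12, 12))
        k[np.ix_(keep, keep)] = kc

    T = np.kron(np.eye(4), Lam)
    return T.T @ k @ T


def _skew(r):
    return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    """Static solve output: displacements, recovered stresses, reactions.

    ``displacements`` are nodal translations (mm); ``rotations`` are NaN for
    nodes that carry no rotational DOFs.  ``stress`` holds the per-tet Voigt
    tensor (MPa) and ``vm`` its von Mises scalar.  ``reactions`` maps each
    constrained node to a 6-vector (N, N*mm).
    """

    displacements: np.ndarray
    rotations: np.ndarray
    stress: np.ndarray
    vm: np.ndarray
    reactions: dict
    applied_total: np.ndarray
    residual: float
    truss_forces: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reaction_force_at(self, nodes) -> np.ndarray:
        """Vector sum of translational reactions (N) over a constrained node
        set; the magnitude of this resultant is reported as bite force."""
        nodes = np.atleast_1d(nodes)
        total = np.zeros(3)
        for n in nodes:
            n = int(n)
            if n not in self.reactions:
                raise ValueError(f"node {n} is not constrained")
            total += self.reactions[n][:3]
        return total

    def reaction_total(self) -> np.ndarray:
        if not self.reactions:
            return np.zeros(3)
        return np.sum([r[:3] for r in self.reactions.values()], axis=0)


class FEModel:
    """Assembled bite-simulation model: a labelled tet mesh plus trusses,
    beams, rigid links, hinges, supports and point loads.

    Tet nodes carry 3 translational DOFs; any node touched by a beam, link,
    hinge, rotational support or applied moment is expanded to 6 DOFs.
    ``solve`` performs a direct sparse factorisation of the reduced system and
    recovers element stresses and support reactions.
    """

    def __init__(self, mesh: TetMesh | None = None, materials: dict | None = None):
        self.mesh = mesh
        self.materials = dict(materials) if materials else default_materials()
        self._extra_nodes: list = []
        self.trusses: list = []
        self.beams: list = []
        self.rigid_links: list = []
        self.hinges: list = []
        self.constraints: list = []
        self._loads: list = []       # (node, f3, m3|None)
        if mesh is not None:
            for r in np.unique(mesh.regions):
                if int(r) not in self.materials:
                    raise ValueError(f"no material for region {int(r)}")

    # -- construction ------------------------------------------------------
    @property
    def n_mesh_nodes(self) -> int:
        return 0 if self.mesh is None else self.mesh.n_nodes

    @property
    def coords(self) -> np.ndarray:
        base = (np.empty((0, 3)) if self.mesh is None else self.mesh.nodes)
        if not self._extra_nodes:
            return base
        return np.vstack([base, np.asarray(self._extra_nodes)])

    @property
    def n_nodes(self) -> int:
        return self.n_mesh_nodes + len(self._extra_nodes)

    def add_node(self, xyz) -> int:
        self._extra_nodes.append(np.asarray(xyz, dtype=float))
        return self.n_nodes - 1

    def add_truss(self, truss: TrussElement) -> TrussElement:
        self.trusses.append(truss)
        return truss

    def add_beam(self, beam: BeamElement) -> BeamElement:
        self.beams.append(beam)
        return beam

    def add_rigid_link(self, master: int, slaves) -> RigidLink:
        link = RigidLink(int(master), tuple(np.atleast_1d(slaves)))
        seen = {s for l in self.rigid_links for s in l.slaves}
        dup = seen.intersection(link.slaves)
        if dup:
            raise ValueError(f"node(s) {sorted(dup)} already slaved")
        self.rigid_links.append(link)
        return link

    def add_hinge(self, master: int, slave: int, axis) -> Hinge:
        h = Hinge(int(master), int(slave), np.asarray(axis, dtype=float))
        self.hinges.append(h)
        return h

    def fix(self, nodes, dofs="tx ty tz") -> None:
        if dofs in ("all", "*"):
            dofs = ALL_DOFS
        elif isinstance(dofs, str):
            dofs = frozenset(dofs.split())
        for n in np.atleast_1d(nodes):
            self.constraints.append(Constraint(int(n), frozenset(dofs)))

    def add_load(self, node: int, force=(0, 0, 0), moment=None) -> None:
        self._loads.append((int(node), np.asarray(force, dtype=float),
                            None if moment is None else np.asarray(moment, dtype=float)))

    def clear_loads(self) -> None:
        self._loads = []

    # -- DOF bookkeeping ---------------------------------------------------
    def _rotational_nodes(self) -> set:
        rot = set()
        for b in self.beams:
            rot.update(b.nodes)
        for l in self.rigid_links:
            rot.add(l.master)
            # slaves stay translational unless required elsewhere
        for h in self.hinges:
            rot.update((h.master, h.slave))
        for c in self.constraints:
            if c.dofs & {"rx", "ry", "rz"}:
                rot.add(c.node)
        for n, f, m in self._loads:
            if m is not None:
                rot.add(n)
        return rot

    def _dof_map(self):
        rot = self._rotational_nodes()
        ndof = np.full(self.n_nodes, 3, dtype=int)
        for n in rot:
            ndof[n] = 6
        offsets = np.concatenate([[0], np.cumsum(ndof)])
        return ndof, offsets

    # -- assembly ----------------------------------------------------------
    def _assemble_full(self, ndof, offsets):
        n_full = offsets[-1]
        coords = self.coords
        rows, cols, vals = [], [], []

        if self.mesh is not None and self.mesh.n_tets:
            self._tet_B = {}
            for region in np.unique(self.mesh.regions):
                sel = np.flatnonzero(self.mesh.regions == region)
                D = self.materials[int(region)].D
                Ke, vol, B = _tet_stiffness_batch(coords, self.mesh.tets[sel], D)
                self._tet_B[int(region)] = (sel, B)
                dofs = (offsets[self.mesh.tets[sel]][:, :, None]
                        + np.arange(3)[None, None, :]).reshape(len(sel), 12)
                rows.append(np.repeat(dofs, 12, axis=1).ravel())
                cols.append(np.tile(dofs, (1, 12)).ravel())
                vals.append(Ke.ravel())

        def add_dense(node_list, Ke, per_node):
            dofs = np.concatenate([offsets[n] + np.arange(per_node)
                                   for n in node_list])
            r = np.repeat(dofs, len(dofs))
            c = np.tile(dofs, len(dofs))
            rows.append(r)
            cols.append(c)
            vals.append(Ke.ravel())

        for t in self.trusses:
            add_dense(t.nodes, _truss_stiffness(t, coords), 3)
        for b in self.beams:
            for n in b.nodes:
                if ndof[n] != 6:
                    raise RuntimeError("beam node lacks rotational DOFs")
            add_dense(b.nodes, _beam_stiffness(b, coords), 6)

        if rows:
            K = sp.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(n_full, n_full)).tocsr()
        else:
            K = sp.csr_matrix((n_full, n_full))
        return K

    def _build_transform(self, ndof, offsets):
        """Master-slave reduction matrix T (full x retained) plus the list of
        retained full-DOF ids (auxiliary hinge rotations appended last)."""
        n_full = offsets[-1]
        slave_dofs = {}

        # resolve rigid links topologically (masters may themselves be slaves)
        links = list(self.rigid_links)
        slave_nodes = {s for l in links for s in l.slaves}
        resolved_rows = {}   # full dof -> {full dof or ('aux', k): coeff}
        coords = self.coords

        def node_dofs(n):
            return [offsets[n] + q for q in range(ndof[n])]

        # detect cycles by repeated passes
        pending = links
        guard = 0
        while pending:
            nxt = []
            for l in pending:
                if l.master in slave_nodes and not all(
                        (offsets[l.master] + q) in resolved_rows
                        for q in range(ndof[l.master])):
                    nxt.append(l)
                    continue
                for s in l.slaves:
                    r = coords[s] - coords[l.master]
                    C = -_skew(r)     # u_s = u_m + theta_m x r
                    for i in range(min(3, ndof[s])):
                        row = {offsets[l.master] + i: 1.0}
                        if ndof[l.master] == 6:
                            for jq in range(3):
                                if abs(C[i, jq]) > 1e-15:
                                    row[offsets[l.master] + 3 + jq] = C[i, jq]
                        resolved_rows[offsets[s] + i] = row
                    if ndof[s] == 6:
                        for jq in range(3):
                            resolved_rows[offsets[s] + 3 + jq] = {
                                offsets[l.master] + 3 + jq: 1.0}
            if len(nxt) == len(pending):
                raise ValueError("rigid-link cycle detected")
            pending = nxt
            guard += 1
            if guard > 10000:
                raise ValueError("rigid-link resolution did not terminate")

        n_aux = 0
        aux_ids = []
        for h in self.hinges:
            if ndof[h.master] != 6 or ndof[h.slave] != 6:
                raise RuntimeError("hinge nodes must carry 6 DOFs")
            for i in range(3):
                resolved_rows[offsets[h.slave] + i] = {offsets[h.master] + i: 1.0}
            e = h.axis
            P = np.eye(3) - np.outer(e, e)
            aux = ("aux", n_aux)
            aux_ids.append(aux)
            n_aux += 1
            for i in range(3):
                row = {}
                for jq in range(3):
                    if abs(P[i, jq]) > 1e-15:
                        row[offsets[h.master] + 3 + jq] = P[i, jq]
                if abs(e[i]) > 1e-15:
                    row[aux] = e[i]
                resolved_rows[offsets[h.slave] + 3 + i] = row

        # substitute chained references (slave rows referencing eliminated dofs)
        def expand(row, depth=0):
            if depth > 64:
                raise ValueError("kinematic coupling chain too deep")
            out = {}
            for key, c in row.items():
                if key in resolved_rows:
                    for k2, c2 in expand(resolved_rows[key], depth + 1).items():
                        out[k2] = out.get(k2, 0.0) + c * c2
                else:
                    out[key] = out.get(key, 0.0) + c
            return out

        resolved_rows = {d: expand(r) for d, r in resolved_rows.items()}

        retained = [d for d in range(n_full) if d not in resolved_rows]
        col_of = {d: i for i, d in enumerate(retained)}
        for k, aux in enumerate(aux_ids):
            col_of[aux] = len(retained) + k
        n_ret = len(retained) + n_aux

        rows_, cols_, vals_ = [], [], []
        for d in range(n_full):
            if d in resolved_rows:
                for key, c in resolved_rows[d].items():
                    rows_.append(d)
                    cols_.append(col_of[key])
                    vals_.append(c)
            else:
                rows_.append(d)
                cols_.append(col_of[d])
                vals_.append(1.0)
        T = sp.coo_matrix((vals_, (rows_, cols_)), shape=(n_full, n_ret)).tocsr()
        return T, retained, col_of, set(resolved_rows)

    def _load_vector(self, ndof, offsets, extra_loads=None):
        f = np.zeros(offsets[-1])
        coords = self.coords
        loads = list(self._loads)
        if extra_loads:
            loads.extend(extra_loads)
        for n, force, moment in loads:
            f[offsets[n]:offsets[n] + 3] += force
            if moment is not None:
                if ndof[n] != 6:
                    raise ValueError(f"moment applied at node {n} without "
                                     "rotational DOFs")
                f[offsets[n] + 3:offsets[n] + 6] += moment
        for t in self.trusses:
            if t.pretension > 0:
                i, fi, j, fj = apply_pretension(t, coords)
                f[offsets[i]:offsets[i] + 3] += fi
                f[offsets[j]:offsets[j] + 3] += fj
        return f

    # -- solve -------------------------------------------------------------
    def solve(self, extra_loads=None, check_residual: float = 1e-8) -> SolveResult:
        """Direct sparse static solve; raises UnderConstrainedError with a
        free-mode diagnostic if the constrained stiffness is singular."""
        ndof, offsets = self._dof_map()
        K = self._assemble_full(ndof, offsets)
        T, retained, col_of, eliminated = self._build_transform(ndof, offsets)
        f_full = self._load_vector(ndof, offsets, extra_loads)

        Kr = (T.T @ K @ T).tocsc()
        fr = T.T @ f_full

        fixed_cols = []
        for c in self.constraints:
            for q, name in enumerate(DOF_NAMES[:ndof[c.node]]):
                if name in c.dofs:
                    d = offsets[c.node] + q
                    if d in eliminated:
                        raise ValueError(
                            f"constraint on slaved DOF {name} of node {c.node}")
                    fixed_cols.append(col_of[d])
            missing = c.dofs - set(DOF_NAMES[:ndof[c.node]])
            if missing:
                raise ValueError(
                    f"node {c.node} has no rotational DOFs to fix {sorted(missing)}")
        fixed_cols = np.unique(fixed_cols)
        n_ret = Kr.shape[0]
        free = np.setdiff1d(np.arange(n_ret), fixed_cols)

        Kff = Kr[np.ix_(free, free)].tocsc()
        ff = fr[free]
        try:
            lu = spla.splu(Kff.tocsc(),
                           options=dict(SymmetricMode=True))
            uf = lu.solve(ff)
        except RuntimeError as exc:
            n_modes = self._count_free_modes(Kff)
            raise UnderConstrainedError(
                f"singular stiffness: {n_modes} unconstrained rigid-body/"
                f"mechanism mode(s) remain", n_modes) from exc
        if not np.isfinite(uf).all():
            n_modes = self._count_free_modes(Kff)
            raise UnderConstrainedError(
                f"non-finite solution: {n_modes} free mode(s) remain", n_modes)
        denom = max(np.linalg.norm(ff), 1e-30)
        residual = float(np.linalg.norm(Kff @ uf - ff) / denom)
        for _ in range(2):
            if residual <= check_residual:
                break
            uf = uf + lu.solve(ff - Kff @ uf)   # iterative refinement
            residual = float(np.linalg.norm(Kff @ uf - ff) / denom)
        if residual > max(check_residual, 1e-6):
            n_modes = self._count_free_modes(Kff)
            if n_modes:
                raise UnderConstrainedError(
                    f"ill-conditioned solve (residual {residual:.2e}); "
                    f"{n_modes} near-zero-energy mode(s)", n_modes)

        ur = np.zeros(n_ret)
        ur[free] = uf
        reac_r = Kr @ ur - fr
        u_full = T @ ur

        # nodal fields
        disp = np.zeros((self.n_nodes, 3))
        rota = np.full((self.n_nodes, 3), np.nan)
        for n in range(self.n_nodes):
            disp[n] = u_full[offsets[n]:offsets[n] + 3]
            if ndof[n] == 6:
                rota[n] = u_full[offsets[n] + 3:offsets[n] + 6]

        # stress recovery
        if self.mesh is not None and self.mesh.n_tets:
            stress = np.zeros((self.mesh.n_tets, 6))
            for region, (sel, B) in self._tet_B.items():
                D = self.materials[region].D
                ue = disp[self.mesh.tets[sel]].reshape(len(sel), 12)
                stress[sel] = np.einsum("ij,mjk,mk->mi", D, B, ue,
                                        optimize=True)
            vm = von_mises(stress)
        else:
            stress = np.empty((0, 6))
            vm = np.empty(0)

        reactions = {}
        for c in self.constraints:
            r6 = reactions.setdefault(c.node, np.zeros(6))
            for q, name in enumerate(DOF_NAMES[:ndof[c.node]]):
                if name in c.dofs:
                    r6[q] = reac_r[col_of[offsets[c.node] + q]]

        # pretension force pairs cancel in the global sum by construction
        applied = np.zeros(3)
        for n, force, moment in (list(self._loads) + list(extra_loads or [])):
            applied += force

        truss_forces = np.array([
            self._truss_axial_force(t, disp) for t in self.trusses])

        return SolveResult(disp, rota, stress, vm, reactions, applied,
                           residual, truss_forces)

    def _truss_axial_force(self, t: TrussElement, disp):
        coords = self.coords
        i, j = t.nodes
        d = coords[j] - coords[i]
        L = np.linalg.norm(d)
        d /= L
        elong = (disp[j] - disp[i]) @ d
        return t.E * t.cross_section / L * elong + t.pretension

    def _count_free_modes(self, Kff, tol: float = 1e-8) -> int:
        n = Kff.shape[0]
        if n == 0:
            return 0
        # threshold against the median diagonal stiffness: the matrix maximum
        # is inflated by rigid-link lever arms and would absorb genuinely
        # stiff modes into the "zero" count
        scale = max(float(np.median(Kff.diagonal())), 1e-30)
        if n <= 2000:
            w = np.linalg.eigvalsh(Kff.toarray())
            return int((w < tol * scale).sum())
        try:
            w = spla.eigsh(Kff, k=min(12, n - 1), sigma=-tol * scale,
                           which="LM", return_eigenvectors=False)
            return int((np.abs(w) < tol * scale).sum())
        except Exception:
            return -1

    def count_zero_energy_modes(self, tol: float = 1e-8) -> int:
        """Zero-energy (rigid-body + mechanism) modes of the *constrained*
        system; an unconstrained single tet reports 6."""
        ndof, offsets = self._dof_map()
        K = self._assemble_full(ndof, offsets)
        T, retained, col_of, eliminated = self._build_transform(ndof, offsets)
        Kr = (T.T @ K @ T).tocsc()
        fixed_cols = []
        for c in self.constraints:
            for q, name in enumerate(DOF_NAMES[:ndof[c.node]]):
                if name in c.dofs:
                    fixed_cols.append(col_of[offsets[c.node] + q])
        free = np.setdiff1d(np.arange(Kr.shape[0]), np.unique(fixed_cols))
        return self._count_free_modes(Kr[np.ix_(free, free)], tol)
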