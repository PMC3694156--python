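"""Finite-element core: closed-form oracles and structural invariants.

Oracles are independent of the solver path: uniaxial bar stress F/A,
Euler-Bernoulli tip deflection FL^3/3EI, von Mises closed forms, a penalty
formulation cross-check for rigid links, and analytic equilibrium sums.
"""

import numpy as np
import pytest

from sabrebite.fem import (
    BeamElement,
    Constraint,
    FEModel,
    Material,
    TrussElement,
    UnderConstrainedError,
    apply_pretension,
    face_traction_loads,
    von_mises,
)
from sabrebite.mesh import make_bar_fixture, make_box_mesh, make_cantilever_fixture

BONE = Material("bone", 20_000.0, 0.3)


def _axial_bar(n_div=2, length=10.0, side=1.0):
    """Statically determinate axial bar: free lateral contraction, so the
    closed-form uniform stress state is exactly representable."""
    bar = make_bar_fixture(length, side, n_div)
    model = FEModel(bar, {0: BONE})
    fixed = bar.node_sets["fixed"]
    model.fix(fixed, "tx")
    corner = fixed[np.lexsort(bar.nodes[fixed, :2].T)]
    origin = fixed[np.argmin(np.linalg.norm(bar.nodes[fixed] - 0, axis=1))]
    model.fix(origin, "ty tz")
    other = fixed[np.argmax(bar.nodes[fixed, 1])]
    model.fix(other, "tz")
    return bar, model


class TestClosedFormOracles:
    def test_axial_stress_equals_force_over_area(self):
        """100 N over a 1 mm^2 section gives sigma_xx = 100 MPa in every
        element (constant-strain state is exact for tet4)."""
        bar, model = _axial_bar()
        loads = face_traction_loads(bar, bar.node_sets["loaded"], [100.0, 0, 0])
        res = model.solve(extra_loads=loads)
        assert res.stress[:, 0] == pytest.approx(100.0, rel=1e-2)
        assert np.abs(res.stress[:, 1:]).max() < 1e-6
        assert res.vm == pytest.approx(100.0, rel=1e-2)

    def test_bar_mesh_convergence(self):
        """Tip displacement of the axial bar changes by <2% between the
        4- and 8-division refinements (the state is exact at any refinement)."""
        tips = []
        for nd in (4, 8):
            bar, model = _axial_bar(nd)
            loads = face_traction_loads(bar, bar.node_sets["loaded"], [100.0, 0, 0])
            res = model.solve(extra_loads=loads)
            tips.append(res.displacements[bar.node_sets["loaded"], 0].mean())
        assert abs(tips[1] - tips[0]) / abs(tips[0]) < 0.02

    def test_cantilever_tip_deflection_vs_beam_theory(self):
        """Transverse tip deflection within 15% of FL^3/3EI at the finest
        shipped refinement (tet4 is over-stiff in bending)."""
        L, side, F = 20.0, 2.0, 10.0
        mesh = make_cantilever_fixture(L, side, 6)
        model = FEModel(mesh, {0: BONE})
        model.fix(mesh.node_sets["fixed"], "tx ty tz")
        tip = mesh.node_sets["loaded"]
        for n in tip:
            model.add_load(n, (0, -F / len(tip), 0))
        res = model.solve()
        delta = F * L**3 / (3 * BONE.E * side**4 / 12)
        tipdef = -res.displacements[tip, 1].mean()
        assert tipdef == pytest.approx(delta, rel=0.15)

    def test_cantilever_zero_load_and_material_linearity(self):
        mesh = make_cantilever_fixture(10, 1, 2)
        model = FEModel(mesh, {0: BONE})
        model.fix(mesh.node_sets["fixed"], "tx ty tz")
        res0 = model.solve()
        assert np.abs(res0.displacements).max() == 0.0

        def tipdef(E):
            m = FEModel(mesh, {0: Material("b", E, 0.3)})
            m.fix(mesh.node_sets["fixed"], "tx ty tz")
            for n in mesh.node_sets["loaded"]:
                m.add_load(n, (0, -1.0, 0))
            return m.solve().displacements[mesh.node_sets["loaded"], 1].mean()

        assert tipdef(2 * BONE.E) == pytest.approx(0.5 * tipdef(BONE.E), rel=1e-9)


class TestPatchTest:
    def test_constant_stress_patch(self):
        """Patch test: consistent boundary tractions of an arbitrary constant
        stress state, applied to an irregular (perturbed-interior) mesh with
        minimal supports, reproduce that stress exactly in every element."""
        rng = np.random.default_rng(3)
        mesh = make_box_mesh((2, 2, 2), (2, 2, 2))
        interior = np.flatnonzero(
            (np.abs(mesh.nodes - 1.0) < 0.99).all(axis=1))
        mesh.nodes[interior] += rng.uniform(-0.15, 0.15, (len(interior), 3))
        mesh.orient_positive()
        mesh.validate()

        sigma = np.array([[37.0, 12.0, -5.0],
                          [12.0, -21.0, 8.0],
                          [-5.0, 8.0, 54.0]])
        faces = mesh.boundary_faces()
        v = mesh.nodes[faces]
        area_normals = 0.5 * np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        loads = {}
        for f, an in zip(faces, area_normals):
            t = sigma @ an / 3.0
            for n in f:
                loads[int(n)] = loads.get(int(n), np.zeros(3)) + t
        extra = [(n, f, None) for n, f in loads.items()]

        model = FEModel(mesh, {0: BONE})
        # statically determinate 3-2-1 supports (reactions vanish since the
        # traction field is self-equilibrated)
        model.fix(0, "tx ty tz")
        nx = int(np.argmax(mesh.nodes[:, 0] * (mesh.nodes[:, 1] == 0)
                           * (mesh.nodes[:, 2] == 0)))
        model.fix(nx, "ty tz")
        ny = int(np.argmax(mesh.nodes[:, 1] * (mesh.nodes[:, 0] == 0)
                           * (mesh.nodes[:, 2] == 0)))
        model.fix(ny, "tz")
        res = model.solve(extra_loads=extra)
        expect = np.array([sigma[0, 0], sigma[1, 1], sigma[2, 2],
                           sigma[0, 1], sigma[1, 2], sigma[2, 0]])
        assert res.stress == pytest.approx(
            np.tile(expect, (mesh.n_tets, 1)), abs=1e-6)
        assert res.reaction_total() == pytest.approx(np.zeros(3), abs=1e-6)


class TestEquilibriumAndLinearity:
    def test_reactions_balance_applied_loads(self):
        bar, model = _axial_bar(2)
        loads = face_traction_loads(bar, bar.node_sets["loaded"], [60.0, -20.0, 35.0])
        # transverse components need more support
        model.fix(bar.node_sets["fixed"], "ty tz")
        res = model.solve(extra_loads=loads)
        total_applied = np.sum([f for _, f, _ in loads], axis=0)
        assert res.reaction_total() + total_applied == pytest.approx(
            np.zeros(3), abs=1e-6)

    def test_load_scaling_scales_response(self):
        bar, model = _axial_bar(2)
        base = face_traction_loads(bar, bar.node_sets["loaded"], [50.0, 0, 0])
        double = face_traction_loads(bar, bar.node_sets["loaded"], [100.0, 0, 0])
        r1 = model.solve(extra_loads=base)
        r2 = model.solve(extra_loads=double)
        assert r2.displacements == pytest.approx(2 * r1.displacements, rel=1e-9)
        assert r2.vm == pytest.approx(2 * r1.vm, rel=1e-9)

    def test_frame_invariance(self):
        """Rotating the model and loads rotates displacements and leaves the
        von Mises field unchanged."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [21, -34, 55], degrees=True).as_matrix()
        bar, model = _axial_bar(2)
        loads = face_traction_loads(bar, bar.node_sets["loaded"], [80.0, 0, 0])
        res = model.solve(extra_loads=loads)

        rbar = bar.transformed(rotation=R)
        rmodel = FEModel(rbar, {0: BONE})
        # rebuild the same support pattern in the rotated frame
        fixed = bar.node_sets["fixed"]
        rmodel.fix(fixed, "tx ty tz")
        model2 = FEModel(bar, {0: BONE})
        model2.fix(fixed, "tx ty tz")
        rloads = [(n, R @ f, None) for n, f, _ in loads]
        res_ref = model2.solve(extra_loads=loads)
        res_rot = rmodel.solve(extra_loads=rloads)
        assert res_rot.displacements == pytest.approx(
            res_ref.displacements @ R.T, abs=1e-8)
        assert res_rot.vm == pytest.approx(res_ref.vm, rel=1e-8, abs=1e-8)


class TestVonMises:
    def test_closed_form_identities(self):
        assert von_mises(np.array([100.0, 0, 0, 0, 0, 0])) == pytest.approx(100.0)
        assert von_mises(np.array([0.0, 0, 0, 10.0, 0, 0])) == pytest.approx(
            10 * np.sqrt(3))
        assert von_mises(50.0 * np.eye(3)) == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        A = rng.normal(size=(3, 3))
        S = A + A.T
        R = Rotation.random(random_state=5).as_matrix()
        assert von_mises(R @ S @ R.T) == pytest.approx(von_mises(S), rel=1e-12)


class TestTrussesAndPretension:
    def test_pretension_force_pair_and_budget(self):
        coords = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        t = TrussElement((0, 1), pretension=25.0)
        i, fi, j, fj = apply_pretension(t, coords)
        assert np.allclose(fi, -fj)
        assert np.linalg.norm(fi) == pytest.approx(25.0)
        assert fi @ (coords[1] - coords[0]) > 0      # pulls i toward j
        # head-depressor budgets: 40 and 70 elements at 25 N each
        assert 40 * 25.0 == pytest.approx(1000.0)
        assert 70 * 25.0 == pytest.approx(1750.0)

    def test_zero_pretension_is_zero_load(self):
        bar, model = _axial_bar(1)
        end = int(bar.node_sets["loaded"][0])
        free = model.add_node([12.0, 0.5, 0.5])
        model.fix(free, "tx ty tz")
        model.add_truss(TrussElement((end, free), pretension=0.0))
        res = model.solve()
        assert np.abs(res.displacements).max() == 0.0

    def test_pretensioned_truss_loads_structure(self):
        bar, model = _axial_bar(1)
        model.fix(bar.node_sets["fixed"], "ty tz")
        end = int(bar.node_sets["loaded"][0])
        anchor = model.add_node(bar.nodes[end] + [5.0, 0, 0])
        model.fix(anchor, "tx ty tz")
        model.add_truss(TrussElement((end, anchor), pretension=25.0))
        res = model.solve()
        # the bar is stretched toward the anchor
        assert res.displacements[end, 0] > 0
        # equilibrium: bar-support + anchor reactions balance (pretension pair
        # is internal to the model, so reactions sum to zero)
        assert res.reaction_total() == pytest.approx(np.zeros(3), abs=1e-6)

    def test_zero_length_truss_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero-length"):
            apply_pretension(TrussElement((0, 1), pretension=5.0), coords)


class TestRigidLinksAndDiagnostics:
    def test_rigid_spider_matches_penalty_formulation(self):
        """A rigid spider (free master linked to the loaded face) agrees with
        a penalty formulation: a complete truss distance-graph over the same
        nodes with stiffness 1e6 x bone (a rigid framework)."""
        import itertools

        def build(use_penalty):
            bar = make_bar_fixture(10, 1, 2)
            model = FEModel(bar, {0: BONE})
            model.fix(bar.node_sets["fixed"], "tx ty tz")
            face = [int(n) for n in bar.node_sets["loaded"]]
            center = model.add_node([11.0, 0.5, 0.5])
            if use_penalty:
                for a, b in itertools.combinations(face + [center], 2):
                    model.add_truss(TrussElement((a, b), cross_section=1.0,
                                                 E=1e6 * BONE.E))
            else:
                model.add_rigid_link(center, face)
            model.add_load(center, (100.0, 0, 0))
            return model.solve().displacements[center]

        exact = build(False)
        penalty = build(True)
        assert penalty == pytest.approx(exact, rel=1e-3, abs=1e-7)

    def test_rigid_link_chain_tracks_master(self):
        """A link chain A->B->C is resolved by composition: C moves exactly
        as the rigid-body extension of A, and the chained system equals the
        equivalent single-master system A->{B, C} to machine precision."""
        def build(chained):
            bar = make_bar_fixture(10, 1, 2)
            model = FEModel(bar, {0: BONE})
            model.fix(bar.node_sets["fixed"], "tx ty tz")
            a = int(bar.node_sets["loaded"][
                np.argmin(np.linalg.norm(
                    bar.nodes[bar.node_sets["loaded"]] - [10, 0.5, 0.5], axis=1))])
            b = model.add_node(bar.nodes[a] + [2.0, 1.0, 0])
            c = model.add_node(bar.nodes[a] + [4.0, 0, 1.0])
            # tie the master's rotation so the chain carries pure translation
            model.fix(a, "rx ry rz")
            if chained:
                model.add_rigid_link(a, [b])
                model.add_rigid_link(b, [c])
            else:
                model.add_rigid_link(a, [b, c])
            model.add_load(c, (40.0, 7.0, -3.0))
            res = model.solve()
            return res.displacements[[a, b, c]]

        chain = build(True)
        single = build(False)
        assert chain[2] == pytest.approx(chain[0], abs=1e-12)   # C tracks A
        assert chain[1] == pytest.approx(chain[0], abs=1e-12)
        assert chain == pytest.approx(single, abs=1e-12)

    def test_slave_in_two_links_rejected(self):
        model = FEModel(make_bar_fixture(2, 1, 1), {0: BONE})
        model.add_rigid_link(0, [5])
        with pytest.raises(ValueError, match="slaved"):
            model.add_rigid_link(1, [5])

    def test_unconstrained_tet_reports_six_modes(self):
        from sabrebite.mesh import TetMesh

        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        tet = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.zeros(1))
        model = FEModel(tet, {0: BONE})
        assert model.count_zero_energy_modes() == 6

    def test_fully_fixed_bar_is_nonsingular(self):
        bar, _ = _axial_bar(1)
        model = FEModel(bar, {0: BONE})
        model.fix(bar.node_sets["fixed"], "tx ty tz")
        assert model.count_zero_energy_modes() == 0
        model.solve()   # must not raise

    def test_underconstrained_solve_raises(self):
        bar = make_bar_fixture(4, 1, 1)
        model = FEModel(bar, {0: BONE})
        model.add_load(int(bar.node_sets["loaded"][0]), (1.0, 0, 0))
        with pytest.raises(UnderConstrainedError):
            model.solve()


class TestBeams:
    def test_beam_cantilever_matches_euler_bernoulli(self):
        """A single beam element reproduces FL^3/3EI exactly (cubic element)."""
        model = FEModel()
        a = model.add_node([0, 0, 0])
        b = model.add_node([10.0, 0, 0])
        beam = BeamElement((a, b), area=1.0, Iy=1.0, Iz=1.0, J=1.0, E=1000.0)
        model.add_beam(beam)
        model.fix(a, "all")
        model.add_load(b, (0, -5.0, 0))
        res = model.solve()
        delta = 5.0 * 10**3 / (3 * 1000.0 * 1.0)
        assert res.displacements[b, 1] == pytest.approx(-delta, rel=1e-9)

    def test_end_release_converts_clamped_to_pinned(self):
        """Midspan deflection moves from the clamped-clamped closed form
        FL^3/192EI to the clamped-pinned 7FL^3/768EI when the far support
        rotation is released."""
        L, E, I, F = 10.0, 1000.0, 1.0, 4.0

        def midspan(release):
            model = FEModel()
            a = model.add_node([0, 0, 0])
            m = model.add_node([L / 2, 0, 0])
            b = model.add_node([L, 0, 0])
            model.add_beam(BeamElement((a, m), 1.0, I, I, 1.0, E))
            rel = (((1, "rz"),) if release else ())
            model.add_beam(BeamElement((m, b), 1.0, I, I, 1.0, E, releases=rel))
            model.fix(a, "all")
            model.fix(b, "all")
            model.add_load(m, (0, -F, 0))
            return -model.solve().displacements[m, 1]

        assert midspan(False) == pytest.approx(F * L**3 / (192 * E * I), rel=1e-9)
        assert midspan(True) == pytest.approx(7 * F * L**3 / (768 * E * I), rel=1e-9)
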