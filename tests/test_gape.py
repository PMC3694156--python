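"""Articulation and maximum-gape estimation: metric identities, ICP and
circle-fit oracles, planted-contact recovery, hinge behaviour."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sabrebite.gape import (
    arc_center_ratio,
    build_tmj_hinge,
    extrude_cartilage,
    find_max_gape,
    fit_canine_arc,
    gape_angle,
    icp_register,
    model_gape_angle,
    rotate_mandible,
)
from sabrebite.geometry import rotation_about_axis


class TestGapeAngle:
    def test_right_angle(self):
        assert gape_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_collinear_same_side_is_zero(self):
        assert gape_angle([1, 0, 0], [0, 0, 0], [2, 0, 0]) == pytest.approx(0.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            gape_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-5, 5, (3, 3))
        base = gape_angle(*pts)
        R = Rotation.random(random_state=8).as_matrix()
        t = rng.uniform(-10, 10, 3)
        moved = pts @ R.T + t
        assert gape_angle(*moved) == pytest.approx(base, abs=1e-9)


class TestRotateMandible:
    def test_zero_is_identity(self, skull):
        out = rotate_mandible(skull, 0.0)
        assert np.allclose(out.mandible.nodes, skull.mandible.nodes)

    def test_rotation_roundtrip(self, skull):
        out = rotate_mandible(rotate_mandible(skull, 8.0), -8.0)
        assert np.abs(out.mandible.nodes - skull.mandible.nodes).max() < 1e-9
        assert out.landmarks["lower_mesial_incisor"] == pytest.approx(
            skull.landmarks["lower_mesial_incisor"], abs=1e-9)

    def test_gape_angle_tracks_rotation_about_joint(self, skull):
        """Rotating about an axis through the joint landmark adds the
        rotation angle to the gape metric exactly (landmarks lie in the
        plane perpendicular to the axis)."""
        joint = skull.jaw_joint_mid()
        base = model_gape_angle(skull)
        out = rotate_mandible(skull, 25.0, axis_point=joint,
                              axis_dir=[0, 0, 1.0])
        assert model_gape_angle(out) == pytest.approx(base + 25.0, abs=1e-6)

    def test_out_of_range_angle_rejected(self, skull):
        with pytest.raises(ValueError):
            rotate_mandible(skull, 151.0)

    def test_cranium_untouched(self, skull):
        out = rotate_mandible(skull, 30.0)
        assert np.array_equal(out.cranium.nodes, skull.cranium.nodes)


class TestCartilageOffset:
    def test_sphere_offsets_to_larger_sphere(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        out_v, out_f = extrude_cartilage(s, 1.0)
        r = np.linalg.norm(out_v, axis=1)
        assert r == pytest.approx(11.0, abs=0.05)
        assert np.array_equal(out_f, s.faces)

    def test_zero_thickness_identity(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        out_v, _ = extrude_cartilage(s, 0.0)
        assert np.array_equal(out_v, s.vertices)

    def test_plane_translates_by_thickness(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        out_v, _ = extrude_cartilage((verts, faces), 1.0)
        assert out_v[:, 2] == pytest.approx(1.0)
        assert out_v[:, :2] == pytest.approx(verts[:, :2])


class TestICP:
    def test_identity_for_identical_clouds(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, (40, 3))
        R, t, rms = icp_register(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)
        assert rms[-1] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_transform(self):
        """Target = source rotated 10 deg and translated (1, 2, 3) mm; the
        recovered transform matches to 1e-3."""
        rng = np.random.default_rng(2)
        src = rng.uniform(-10, 10, (80, 3))
        Rp, tp = rotation_about_axis([0, 0, 0], [0.2, 0.5, 1.0], 10.0)
        tp = tp + np.array([1.0, 2.0, 3.0])
        tgt = src @ Rp.T + tp
        R, t, rms = icp_register(src, tgt)
        assert np.abs(R - Rp).max() < 1e-3
        assert np.abs(t - tp).max() < 1e-3
        assert rms[-1] < 1e-6

    def test_rms_non_increasing(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(-5, 5, (60, 3))
        tgt = rng.uniform(-5, 5, (60, 3))
        _, _, rms = icp_register(src, tgt, max_iter=25)
        assert all(rms[i + 1] <= rms[i] + 1e-12 for i in range(len(rms) - 1))

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10),
                                np.zeros(10)])
        tgt = np.random.default_rng(0).uniform(0, 1, (10, 3))
        with pytest.raises(ValueError):
            icp_register(line, tgt)
        with pytest.raises(ValueError):
            icp_register(tgt[:2], tgt)


class TestCircleFit:
    def test_three_exact_points_circumscribed(self):
        th = np.radians([10.0, 140.0, 260.0])
        pts = np.column_stack([7 + 50 * np.cos(th), -3 + 50 * np.sin(th)])
        fit = fit_canine_arc(pts)
        assert fit.center == pytest.approx([7.0, -3.0], abs=1e-6)
        assert fit.radius == pytest.approx(50.0, abs=1e-6)

    def test_fit_invariant_to_point_order(self):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, np.pi, 15))
        pts = np.column_stack([20 * np.cos(th), 20 * np.sin(th)])
        pts += rng.normal(0, 0.2, pts.shape)
        a = fit_canine_arc(pts)
        b = fit_canine_arc(pts[::-1])
        assert a.center == pytest.approx(b.center, abs=1e-6)
        assert a.radius == pytest.approx(b.radius, abs=1e-6)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.linspace(0, 5, 8)])
        with pytest.raises(ValueError, match="collinear"):
            fit_canine_arc(pts)


class TestArcCenterRatio:
    def test_fulcrum_at_center_is_zero(self):
        from sabrebite.gape import ArcFit

        fit = ArcFit(center=np.array([2.0, 3.0]), radius=10.0, rms_residual=0)
        assert arc_center_ratio(fit, [2.0, 3.0]) == pytest.approx(0.0)

    def test_fulcrum_on_circle_is_half(self):
        from sabrebite.gape import ArcFit

        fit = ArcFit(center=np.array([0.0, 0.0]), radius=10.0, rms_residual=0)
        assert arc_center_ratio(fit, [10.0, 0.0]) == pytest.approx(0.5)


class TestMaxGape:
    def test_planted_contact_angle_recovered(self, skull, gape_result):
        """The generator plants a 90-degree bone-contact gape; with the
        default 2-degree soft-tissue back-off the estimate is 88 +- 0.5."""
        assert gape_result.bone_contact_gape_deg == pytest.approx(90.0, abs=0.5)
        assert gape_result.max_gape_deg == pytest.approx(88.0, abs=0.5)
        assert gape_result.max_gape_deg == pytest.approx(
            gape_result.bone_contact_gape_deg
            - gape_result.soft_tissue_backoff_deg, abs=1e-9)

    def test_contact_axis_near_joint_line(self, skull, gape_result):
        """The contact-derived rotation axis lies on the cartilage touch
        line and is parallel to the mediolateral axis."""
        pts = gape_result.rotation_axis_points
        assert np.abs(gape_result.axis_dir[:2]).max() < 0.05
        assert pts[:, 1] == pytest.approx(skull.joint_axis_point[1], abs=0.2)
        assert np.abs(pts[:, 0]).max() < 1.0

    def test_zero_cartilage_same_contact_angle_different_seating(self, skull,
                                                                 gape_result):
        """Without cartilage the mandible seats ~2 mm lower (the cartilage
        space) but the bone-contact gape barely changes."""
        bare = find_max_gape(skull, cartilage_mm=0.0, backoff_deg=2.0)
        assert bare.bone_contact_gape_deg == pytest.approx(
            gape_result.bone_contact_gape_deg, abs=2.5)
        dy = (bare.seating_translation[1]
              - gape_result.seating_translation[1])
        assert dy == pytest.approx(-2.0, abs=0.2)

    def test_gape_monotone_in_joint_clearance(self):
        """Opening clearance at the joint can only increase the achievable
        gape."""
        from sabrebite.synthetic import SkullParams, make_skull_pair

        gapes = []
        for cl in (2.0, 3.0, 4.0):
            m = make_skull_pair(SkullParams(target_tets=2000,
                                            cotyle_clearance=cl))
            gapes.append(find_max_gape(m).max_gape_deg)
        assert gapes[0] <= gapes[1] + 0.05 <= gapes[2] + 0.10


class TestHinge:
    def test_hinge_releases_exactly_one_mode(self, skull):
        """With the hinge attached and the cranium fixed, the only
        zero-energy motion left is mandible rotation about the joint axis."""
        from sabrebite.simulate import BiteSimulation

        sim = BiteSimulation(skull, constrain_canines=False)
        assert sim.model.count_zero_energy_modes() == 1

    def test_hinge_with_bite_constraints_is_solvable(self, skull):
        from sabrebite.simulate import BiteSimulation

        sim = BiteSimulation(skull)
        assert sim.model.count_zero_energy_modes() == 0

    def test_force_along_axis_transmitted(self, skull):
        """A mediolateral force on the mandible passes through the hinge:
        no runaway displacement, reactions balance."""
        from sabrebite.simulate import BiteSimulation

        sim = BiteSimulation(skull)
        node = sim.global_node("mandible", 0)
        sim.model.add_load(node, (0, 0, 50.0))
        res = sim.model.solve()
        assert np.abs(res.displacements).max() < 1.0
        assert res.reaction_total() + [0, 0, 50.0] == pytest.approx(
            np.zeros(3), abs=1e-5)

    def test_spread_attachment_reduces_peak_plate_stress(self, skull):
        """Distributing the joint attachment over the tessellated articular
        plate lowers the peak von Mises stress near the plate compared with
        a single-node pivot carrying the same joint load (the rationale for
        plate tessellation)."""
        from sabrebite.fem import FEModel
        from sabrebite.simulate import BiteSimulation

        def peak_with_attachment(spread):
            h = build_tmj_hinge(skull, spread=spread)
            model = FEModel(skull.cranium)
            occ = skull.cranium.node_sets["occipital_condyle"]
            model.fix(occ, "tx ty tz")
            for side in ("left", "right"):
                axis = model.add_node(h.axis_points[side])
                model.add_rigid_link(axis, h.cranium_attach_nodes[side])
                # the load is a pure force; pin the free node's rotations so
                # the single-node variant is not a mechanism
                model.fix(axis, "rx ry rz")
                model.add_load(axis, (0.0, -400.0, 0.0))
            res = model.solve()
            cent = skull.cranium.tet_centroids()
            near = np.linalg.norm(cent[:, :2], axis=1) < 12.0
            return res.vm[near].max()

        assert peak_with_attachment(True) <= peak_with_attachment(False)
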