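"""Muscle systems: dry-skull forces, projected areas, truss fans, webs."""

import numpy as np
import pytest

from sabrebite.musculature import (
    AttachmentWeb,
    DryskullSpec,
    build_adductor_fans,
    build_depressor_system,
    dry_skull_force,
    projected_patch_area,
    sample_patch_points,
)


class TestDrySkullForce:
    def test_force_is_area_times_tension(self):
        assert dry_skull_force(1000.0, 0.3) == pytest.approx(300.0)

    @pytest.mark.parametrize("area,tension", [(0.0, 0.3), (-5.0, 0.3),
                                              (100.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, area, tension):
        with pytest.raises(ValueError):
            dry_skull_force(area, tension)

    def test_dryskull_spec_forces(self):
        spec = DryskullSpec(areas={"temporalis": 2000.0,
                                   "masseter_complex": 1500.0})
        assert spec.force("temporalis") == pytest.approx(600.0)
        assert spec.force("masseter_complex") == pytest.approx(450.0)


class TestProjectedArea:
    UNIT_SQUARE = (np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                            float),
                   np.array([[0, 1, 2], [0, 2, 3]]))

    def test_unit_square_face_on(self):
        assert projected_patch_area(self.UNIT_SQUARE, [0, 0, 1]) == \
            pytest.approx(1.0)

    def test_patch_parallel_to_normal_is_zero(self):
        assert projected_patch_area(self.UNIT_SQUARE, [1, 0, 0]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_oblique_projection_cosine(self):
        n = np.array([0, 1.0, 1.0])
        assert projected_patch_area(self.UNIT_SQUARE, n) == \
            pytest.approx(np.cos(np.pi / 4), abs=1e-9)

    def test_folded_patch_counts_silhouette_not_sum(self):
        """A patch folded back over itself projects to its silhouette; the
        expected area comes from a rasterisation oracle at 10 um."""
        verts = np.array([
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],      # base square
            [0.5, 0, 0.2], [0.5, 1, 0.2],                    # fold crest
            [0.2, 0, 0.4], [0.2, 1, 0.4],                    # folded-back edge
        ])
        faces = np.array([[0, 1, 2], [0, 2, 3],
                          [1, 4, 5], [1, 5, 2],
                          [4, 6, 7], [4, 7, 5]])
        area = projected_patch_area((verts, faces), [0, 0, 1])

        # rasterisation oracle: 10 um grid point-in-projected-triangle test
        res = 0.01
        xs = np.arange(0.0, 1.0, res) + res / 2
        X, Y = np.meshgrid(xs, xs)
        covered = np.zeros(X.shape, dtype=bool)
        for f in faces:
            a, b, c = verts[f][:, :2]
            d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
            l1 = ((b[1] - c[1]) * (X - c[0]) + (c[0] - b[0]) * (Y - c[1])) / d
            l2 = ((c[1] - a[1]) * (X - c[0]) + (a[0] - c[0]) * (Y - c[1])) / d
            l3 = 1 - l1 - l2
            covered |= (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        oracle = covered.sum() * res**2
        assert area == pytest.approx(oracle, rel=0.02)
        # and strictly less than the summed face areas (the fold overlaps)
        v = verts[faces]
        summed = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1).sum()
        assert area < summed

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ValueError):
            projected_patch_area(self.UNIT_SQUARE, [0, 0, 0])


class TestAdductorFans:
    def test_force_budget_conserved(self, skull):
        fans = build_adductor_fans(skull, spec={"temporalis": 300.0,
                                                "masseter_complex": 200.0},
                                   n_trusses=10, seed=0)
        per_group = {}
        for t in fans:
            per_group.setdefault(t.group, []).append(t.force)
        assert sum(per_group["temporalis"]) == pytest.approx(300.0)
        assert per_group["temporalis"] == pytest.approx([30.0] * 10)
        assert sum(per_group["masseter_complex"]) == pytest.approx(200.0)

    def test_trusses_span_cranium_to_mandible(self, skull):
        """Origins lie on the cranium surface, insertions on the mandible
        surface, within a whisker of the named attachment patch (mirrored
        anchors can land on a neighbouring triangle where the patch edge
        is not perfectly mirror-tessellated)."""
        from sabrebite.geometry import SurfaceDistance
        from sabrebite.gape import patch_surface

        cran = SurfaceDistance(skull.cranium.nodes,
                               skull.cranium.boundary_faces())
        mand = SurfaceDistance(skull.mandible.nodes,
                               skull.mandible.boundary_faces())
        surf = {}
        for name in ("temporalis_origin", "temporalis_insertion",
                     "masseter_origin", "masseter_insertion"):
            v, f, _ = patch_surface(skull, name)
            surf[name] = SurfaceDistance(v, f)
        fans = build_adductor_fans(skull, seed=0)
        for t in fans:
            opatch = ("temporalis_origin" if t.group == "temporalis"
                      else "masseter_origin")
            ipatch = ("temporalis_insertion" if t.group == "temporalis"
                      else "masseter_insertion")
            assert cran.closest(t.origin[None])[0][0] < 1e-6
            assert mand.closest(t.insertion[None])[0][0] < 1e-6
            assert surf[opatch].closest(t.origin[None])[0][0] < 2.0
            assert surf[ipatch].closest(t.insertion[None])[0][0] < 2.0

    def test_fans_bilaterally_symmetric(self, skull):
        fans = build_adductor_fans(skull, seed=0)
        pts = np.array([[t.origin, t.insertion] for t in fans])
        mirrored = pts * np.array([1, 1, -1.0])
        for p in mirrored.reshape(-1, 2, 3):
            gap = np.abs(pts - p).max(axis=(1, 2)).min()
            assert gap < 1e-9

    def test_via_point_bends_line_of_action(self, skull):
        """With a via-point, the pull direction at the insertion is the
        via-to-insertion unit vector, not the origin direction."""
        from sabrebite.musculature import default_adductor_groups

        via = np.array([30.0, 40.0, 0.0])
        groups = default_adductor_groups(
            skull, spec={"temporalis": 100.0, "masseter_complex": 100.0},
            n_trusses=2, via_points={"temporalis": via})
        fans = build_adductor_fans(skull, groups=groups, seed=0)
        t = next(f for f in fans if f.group == "temporalis")
        assert t.via == pytest.approx(via)
        # direction at insertion comes from the via segment
        d = (t.via - t.insertion)
        d = d / np.linalg.norm(d)
        d_direct = t.origin - t.insertion
        d_direct /= np.linalg.norm(d_direct)
        assert not np.allclose(d, d_direct, atol=1e-3)

    def test_missing_patch_fails_with_name(self, skull):
        broken = skull.copy()
        del broken.attachment_patches["temporalis_origin"]
        with pytest.raises(KeyError, match="temporalis_origin"):
            build_adductor_fans(broken, seed=0)


class TestDepressorSystem:
    def test_default_budget_is_1750_n(self, skull):
        """40 + 30 trusses at 25 N pretension each: 1750 N total."""
        dep = build_depressor_system(skull, seed=0)
        assert dep.force_budget == pytest.approx(1750.0)
        assert len(dep.trusses) == 70
        assert all(t.force == pytest.approx(25.0) for t in dep.trusses)
        assert 40 * 25.0 == pytest.approx(1000.0)   # sternomastoideus alone

    def test_webs_perpendicular_and_sized(self, skull):
        dep = build_depressor_system(skull, ellipse_axes=(40.0, 26.0),
                                     circle_radius=30.0, seed=0)
        circle = next(w for w in dep.webs if w.shape == "circle")
        ellipse = next(w for w in dep.webs if w.shape == "ellipse")
        assert circle.normal @ ellipse.normal == pytest.approx(0.0, abs=1e-12)
        assert circle.semi_axes == (30.0, 30.0)
        assert ellipse.semi_axes == (20.0, 13.0)
        r = np.linalg.norm(circle.rim_points - circle.center, axis=1)
        assert r == pytest.approx(30.0, abs=1e-9)

    def test_web_dimensions_scale_with_input(self, skull):
        """Doubling the requested web dimensions doubles the rim geometry
        (dimensions proportional to skull length are the caller's input)."""
        a = build_depressor_system(skull, ellipse_axes=(40, 26),
                                   circle_radius=30, seed=0)
        b = build_depressor_system(skull, ellipse_axes=(80, 52),
                                   circle_radius=60, seed=0)
        for wa, wb in zip(a.webs, b.webs):
            assert np.allclose(wb.rim_points - wb.center,
                               2 * (wa.rim_points - wa.center))

    def test_depressor_pull_is_caudoventral(self, skull):
        """The net depressor force on the cranium points caudally (-x) and
        ventrally (-y): the head-flexor action."""
        dep = build_depressor_system(skull, seed=0)
        F = np.zeros(3)
        for t in dep.trusses:
            d = t.insertion - t.origin          # pull toward the web
            F += t.force * d / np.linalg.norm(d)
        assert F[0] < 0 and F[1] < 0
        assert abs(F[2]) < 1e-6 * np.abs(F).max()

    def test_web_rims_fixed_in_solves(self, skull):
        """Web rim nodes are rigidly linked to the fixed centre node, so
        they do not move in any solve."""
        from sabrebite.simulate import BiteSimulation

        sim = BiteSimulation(skull)
        dep = build_depressor_system(skull, seed=0)
        sim.attach_depressors(dep)
        res = sim.solve()
        n_rim = sum(len(w.rim_points) for w in dep.webs)
        rim_disp = res.displacements[-n_rim - 2:]
        assert np.abs(rim_disp).max() < 1e-12

    def test_bad_dimensions_rejected(self, skull):
        with pytest.raises(ValueError):
            build_depressor_system(skull, circle_radius=-1.0)
        with pytest.raises(ValueError):
            AttachmentWeb("circle", np.zeros(3), [1, 0, 0],
                          np.zeros((4, 3)), (0.0, 1.0))


def test_muscle_csv_dump(tmp_path, skull):
    import csv

    from sabrebite.musculature import write_muscle_csv

    fans = build_adductor_fans(skull, seed=0)
    path = tmp_path / "muscles.csv"
    write_muscle_csv(fans, path)
    with open(path) as f:
        rows = list(csv.DictReader(f))
    assert len(rows) == len(fans)
    assert float(rows[0]["force_n"]) == pytest.approx(fans[0].force)


def test_patch_sampling_seeded_and_on_patch(skull):
    from sabrebite.gape import patch_surface
    from sabrebite.geometry import SurfaceDistance

    v, f, _ = patch_surface(skull, "temporalis_origin")
    a = sample_patch_points(v, f, 20, seed=3)
    b = sample_patch_points(v, f, 20, seed=3)
    assert np.array_equal(a, b)
    d, _, _ = SurfaceDistance(v, f).closest(a)
    assert d.max() < 1e-9
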