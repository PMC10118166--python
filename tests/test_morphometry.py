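"""Skeleton, centerline, parameterization and caliber against analytic oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import tubulometry as tm
from tubulometry.morphometry import skeleton_endpoints


def _label(data, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return tm.LabelVolume(np.asarray(data, dtype=np.uint8), spacing=spacing,
                          origin=origin, label_map={1: "lumen"})


class TestSkeletonize:
    def test_cylinder_skeleton_hugs_the_axis(self, cylinder):
        """Thinning a straight tube leaves voxels within ~1 voxel of the axis."""
        lumen, truth = cylinder
        skel = tm.skeletonize(lumen)
        coords = lumen.world_coordinates(np.argwhere(skel))
        d, _ = cKDTree(truth.points).query(coords)
        assert d.max() <= 1.5  # 1 voxel + half-voxel grid offset

    def test_single_voxel_lumen_is_its_own_skeleton(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1
        skel = tm.skeletonize(_label(data))
        assert skel.sum() == 1 and skel[1, 1, 1]

    def test_hairpin_has_two_endpoints_after_pruning(self, hairpin):
        lumen, _ = hairpin
        skel = tm.skeletonize(lumen)
        assert len(skeleton_endpoints(skel, lumen.spacing)) == 2

    def test_empty_lumen_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tm.skeletonize(_label(np.zeros((3, 3, 3))))

    def test_smaller_components_dropped_with_warning(self):
        data = np.zeros((10, 10, 10))
        data[1, 1, 1:8] = 1
        data[8, 8, 8] = 1
        with pytest.warns(UserWarning, match="largest"):
            skel = tm.skeletonize(_label(data))
        assert not skel[8, 8, 8]


class TestExtractCenterline:
    def test_y_skeleton_keeps_two_longest_limbs(self):
        """Y with limbs 50/40/30 μm: the centerline spans the 50+40 pair.

        Oracle: brute-force shortest paths over every endpoint pair of the
        voxel graph agree (longest pairwise geodesic = 90 μm).
        """
        skel = np.zeros((35, 45, 55), dtype=bool)
        skel[2, 2, 2:53] = True   # +x limb, 50 steps
        skel[2, 2:43, 2] = True   # +y limb, 40 steps
        skel[2:33, 2, 2] = True   # +z limb, 30 steps
        pts = tm.extract_centerline(skel)
        s = tm.parameterize(pts)

        # brute-force oracle: longest pairwise geodesic over the voxel graph
        import networkx as nx
        from tubulometry.morphometry import _skeleton_graph
        g = _skeleton_graph(skel, np.ones(3))
        eps = [n for n in g.nodes if g.degree(n) == 1]
        best = max(
            nx.dijkstra_path_length(g, a, b)
            for i, a in enumerate(eps) for b in eps[i + 1:]
        )
        assert s[-1] == pytest.approx(best)
        # the 26-connected geodesic cuts the junction corner: 49 + √2 + 39
        assert s[-1] == pytest.approx(90.0, rel=0.01)
        ends = {tuple(pts[0]), tuple(pts[-1])}
        assert ends == {(2.0, 2.0, 52.0), (2.0, 42.0, 2.0)}

    def test_straight_line_length_is_n_minus_one(self):
        skel = np.zeros((3, 3, 12), dtype=bool)
        skel[1, 1, 1:11] = True  # 10 voxels
        pts = tm.extract_centerline(skel)
        assert tm.parameterize(pts)[-1] == pytest.approx(9.0)

    def test_hairpin_endpoints_near_analytic_ends(self, hairpin_profiled):
        lumen, truth, centerline, _, _ = hairpin_profiled
        gt_ends = np.array([truth.points[0], truth.points[-1]])
        got_ends = np.array([centerline.points[0], centerline.points[-1]])
        d, _ = cKDTree(gt_ends).query(got_ends)
        assert d.max() <= 2.0 * max(lumen.spacing)

    def test_closed_loop_rejected(self):
        skel = np.zeros((3, 8, 8), dtype=bool)
        skel[1, 1:7, 1] = skel[1, 1:7, 6] = True
        skel[1, 1, 1:7] = skel[1, 6, 1:7] = True  # a square ring
        with pytest.raises(ValueError, match="loop|cycl"):
            tm.extract_centerline(skel)


class TestParameterize:
    def test_cumulative_arc_length(self):
        pts = np.array([[0, 0, 0], [0, 0, 3], [0, 4, 6]], dtype=float)
        np.testing.assert_allclose(tm.parameterize(pts), [0, 3, 8])

    def test_single_point(self):
        np.testing.assert_array_equal(tm.parameterize(np.zeros((1, 3))), [0.0])

    def test_duplicates_collapsed_with_warning(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 2]], dtype=float)
        with pytest.warns(UserWarning, match="duplicate"):
            s = tm.parameterize(pts)
        np.testing.assert_allclose(s, [0, 2])

    @pytest.mark.parametrize("fixture", ["cylinder", "oblique_cylinder", "hairpin"])
    def test_isomap_matches_arc_length_within_one_percent(self, fixture, request):
        """The 1D Isomap embedding of a simple curve is its arc length."""
        _, truth = request.getfixturevalue(fixture)
        pts = truth.points[::4]
        s_arc = tm.parameterize(pts, mode="arc")
        s_iso = tm.parameterize(pts, mode="isomap")
        np.testing.assert_allclose(s_iso, s_arc, atol=0.01 * s_arc[-1])


class TestAlignAtTP:
    def test_midpoint_split(self):
        s = np.linspace(0, 10, 11)
        signed = tm.align_at_tp(s, 5)
        assert signed[0] == -5 and signed[-1] == 5 and signed[5] == 0

    def test_flipping_glomerulus_end_negates(self):
        s = np.linspace(0, 10, 11)
        np.testing.assert_allclose(
            tm.align_at_tp(s, 3, "start"), -tm.align_at_tp(s, 3, "end")
        )

    def test_tp_at_endpoint_warns_but_works(self):
        with pytest.warns(UserWarning, match="endpoint"):
            signed = tm.align_at_tp(np.array([0.0, 1.0, 2.0]), 0)
        np.testing.assert_allclose(signed, [0, 1, 2])

    def test_invalid_index_rejected(self):
        with pytest.raises(IndexError):
            tm.align_at_tp(np.array([0.0, 1.0]), 5)

    def test_hairpin_alignment_matches_anatomy(self, hairpin_profiled):
        """Auto TP and auto neck side recover s ≈ [−100, +300] on the phantom."""
        _, truth, centerline, _, _ = hairpin_profiled
        assert centerline.s[centerline.tp_index] == 0.0
        assert centerline.s[0] == pytest.approx(-100.0, abs=5.0)
        assert centerline.s[-1] == pytest.approx(300.0, abs=10.0)


class TestFindTurningPoint:
    def test_max_curvature_lands_on_the_bend(self, hairpin):
        _, truth = hairpin
        idx = tm.find_turning_point(truth.points)
        s_at = truth.s_signed[idx]
        assert abs(s_at) <= 5.0  # within 5 μm of the analytic apex


class TestCaliber:
    def test_cylinder_diameter_from_distance_transform(self, cylinder):
        lumen, truth = cylinder
        mid = truth.points[len(truth.points) // 4: -len(truth.points) // 4]
        d = tm.local_diameter(lumen, mid)
        assert np.abs(d - 10.0).max() <= 1.0

    def test_thin_line_diameter_bounded_by_two_voxels(self):
        data = np.zeros((3, 3, 12))
        data[1, 1, 1:11] = 1
        d = tm.local_diameter(_label(data), np.array([[1.0, 1.0, 5.0]]))
        assert 0 < d[0] <= 2.0

    def test_diameter_bounded_by_brute_force_inscribed_sphere(self):
        """EDT diameter ≤ brute-force nearest-boundary-voxel diameter + 1 voxel."""
        rng = np.random.default_rng(7)
        data = np.zeros((12, 12, 12))
        data[3:9, 3:9, 3:9] = 1
        data[rng.integers(3, 9, 5), rng.integers(3, 9, 5), rng.integers(3, 9, 5)] = 1
        lab = _label(data)
        inside = np.argwhere(data > 0)
        outside = np.argwhere(data == 0)
        probe = inside[::7].astype(float)
        d_edt = tm.local_diameter(lab, probe)
        tree = cKDTree(outside)
        d_brute = 2.0 * tree.query(probe)[0]
        assert (d_edt <= d_brute + 1.0).all()

    @pytest.mark.parametrize("fixture", ["cylinder", "oblique_cylinder"])
    def test_cross_section_area_matches_circle(self, fixture, request):
        """Plane-sampled area ≈ πr² for axis-aligned and 45°-oblique tubes."""
        lumen, truth = request.getfixturevalue(fixture)
        n = len(truth.points)
        areas = [
            tm.cross_section_area(lumen, truth.points, i)
            for i in range(n // 4, 3 * n // 4, 5)
        ]
        assert np.mean(areas) == pytest.approx(np.pi * 25, rel=0.10)

    def test_saturated_window_flagged_in_solid_block(self):
        data = np.ones((20, 20, 20))
        lab = _label(data)
        pts = np.array([[10.0, 10.0, 10.0]])
        area, sat = tm.cross_section_area(
            lab, pts, 0, tangent=np.array([0.0, 0.0, 1.0]),
            half_width_um=5.0, return_saturated=True,
        )
        assert sat and area == pytest.approx(10.0 * 10.0, rel=0.15)

    def test_point_outside_lumen_snaps_with_warning(self, cylinder):
        lumen, truth = cylinder
        far = truth.points[len(truth.points) // 2] + np.array([8.0, 8.0, 0.0])
        with pytest.warns(UserWarning, match="snap"):
            d = tm.local_diameter(lumen, far[None, :])
        assert d[0] > 0


class TestWholeTubule:
    def test_straight_phantom_length_recovered(self, cylinder):
        lumen, truth = cylinder
        _, _, summary = tm.profile_tubule(lumen)
        assert summary.length_um == pytest.approx(100.0, abs=1.0)

    def test_volume_scales_as_radius_squared_length_constant(self):
        a, _ = tm.synth_tube(tm.TubePhantomSpec(seed=2))
        b, _ = tm.synth_tube(tm.TubePhantomSpec(seed=2, radius_scale=1.75))
        ratio = tm.tubule_volume(b) / tm.tubule_volume(a)
        assert ratio == pytest.approx(1.75**2, rel=0.05)
        _, _, sa = tm.profile_tubule(a)
        _, _, sb = tm.profile_tubule(b)
        assert sb.length_um / sa.length_um == pytest.approx(1.0, abs=0.02)

    def test_empty_lumen_volume_is_zero(self):
        assert tm.tubule_volume(_label(np.zeros((3, 3, 3)))) == 0.0

    def test_translation_leaves_metrics_unchanged(self, cylinder):
        lumen, _ = cylinder
        _, prof_a, sum_a = tm.profile_tubule(lumen)
        moved = tm.LabelVolume(lumen.data.copy(), spacing=lumen.spacing,
                               origin=tuple(o + 37.5 for o in lumen.origin),
                               label_map=dict(lumen.label_map))
        _, prof_b, sum_b = tm.profile_tubule(moved)
        assert sum_b.length_um == pytest.approx(sum_a.length_um, abs=1e-9)
        assert sum_b.mean_diameter_um == pytest.approx(sum_a.mean_diameter_um, abs=1e-9)
        np.testing.assert_allclose(prof_b.area_um2, prof_a.area_um2, atol=1e-9)

    def test_doubling_spacing_doubles_lengths_and_octuples_volume(self, cylinder):
        """Spacing equivariance, exact to float tolerance on identical voxels."""
        lumen, _ = cylinder
        _, prof_a, sum_a = tm.profile_tubule(lumen)
        doubled = tm.LabelVolume(lumen.data.copy(), spacing=tuple(2 * s for s in lumen.spacing),
                                 origin=lumen.origin, label_map=dict(lumen.label_map))
        _, prof_b, sum_b = tm.profile_tubule(doubled)
        assert sum_b.length_um == pytest.approx(2 * sum_a.length_um, rel=1e-9)
        assert sum_b.mean_diameter_um == pytest.approx(2 * sum_a.mean_diameter_um, rel=1e-9)
        assert sum_b.volume_um3 == pytest.approx(8 * sum_a.volume_um3, rel=1e-12)
        np.testing.assert_allclose(prof_b.area_um2, 4 * prof_a.area_um2, rtol=1e-7)

    def test_cross_section_mean_si_recovers_lumen_intensity(self, cylinder):
        """With a noise-free rendering, the section-mean SI equals the lumen
        intensity away from the tube ends."""
        from tubulometry.synth import render_tube_intensity
        lumen, _ = cylinder
        spec = tm.TubePhantomSpec(lumen_intensity=200.0, background_intensity=40.0,
                                  noise_sd=0.0)
        img = render_tube_intensity(lumen, spec)
        _, profile, _ = tm.profile_tubule(lumen, intensity=img)
        mid = profile.iloc[len(profile) // 4: -len(profile) // 4]
        assert mid.mean_si.mean() == pytest.approx(200.0, rel=0.05)

    def test_profile_reports_both_diameter_conventions(self, hairpin_profiled):
        _, _, _, profile, _ = hairpin_profiled
        expected = 2 * np.sqrt(profile.area_um2 / np.pi)
        np.testing.assert_allclose(profile.equiv_diameter_um, expected)
        assert (profile.diameter_um >= 0).all() and (profile.area_um2 >= 0).all()
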