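"""Phantom generator: geometry, marker seeding, sectioning, cohort draws."""

import numpy as np
import pytest

import hippostereo as hs
from hippostereo.phantom import _build_regions

from conftest import make_animal


class TestTrueVolume:
    def test_ellipsoid_closed_form(self):
        e = hs.Ellipsoid(semi_axes=(0.782, 0.782, 0.782))
        assert hs.true_volume(e) == pytest.approx(4 / 3 * np.pi * 0.782**3, rel=1e-12)
        assert round(hs.true_volume(e), 3) == 2.003

    def test_unit_cube_extrusion(self):
        from shapely.geometry import Polygon

        cube = hs.ExtrudedPolygon(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), 0.0, 1.0)
        assert hs.true_volume(cube) == pytest.approx(1.0)

    @pytest.mark.parametrize("axes", [(0.0, 1.0, 1.0), (1.0, -0.5, 1.0)])
    def test_degenerate_ellipsoid_rejected(self, axes):
        with pytest.raises(ValueError):
            hs.Ellipsoid(semi_axes=axes)

    def test_zero_extent_extrusion_rejected(self):
        from shapely.geometry import Polygon

        with pytest.raises(ValueError):
            hs.ExtrudedPolygon(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), 1.0, 1.0)

    def test_scaled_regions_hit_requested_volumes(self):
        regions = _build_regions(1.58, 1.98)
        assert hs.true_volume(regions["DG"]) == pytest.approx(1.58, rel=1e-9)
        assert hs.true_volume(regions["CA3"]) == pytest.approx(1.98, rel=1e-9)

    def test_regions_do_not_overlap(self):
        regions = _build_regions(2.00, 3.15)
        # sample points of one solid never fall inside the other
        pts = hs.seed_markers(regions["DG"], 5000.0, 0).points
        assert not regions["CA3"].shape.contains(pts).any()


class TestSeedMarkers:
    def test_zero_intensity_gives_empty_set(self):
        regions = _build_regions(2.0, 3.0)
        assert len(hs.seed_markers(regions["DG"], 0.0, 1)) == 0

    def test_negative_intensity_rejected(self):
        regions = _build_regions(2.0, 3.0)
        with pytest.raises(ValueError):
            hs.seed_markers(regions["DG"], -1.0, 1)

    def test_all_points_inside_solid(self):
        regions = _build_regions(1.58, 1.98)
        m = hs.seed_markers(regions["DG"], 2000.0, 42)
        assert regions["DG"].shape.contains(m.points).all()

    def test_poisson_mean_matches_intensity_times_volume(self):
        # diabetic DG scenario: 9615 mm^-3 in a 1.58 mm^3 solid -> 15192 expected
        regions = _build_regions(1.58, 1.98)
        expected = 9615.0 * 1.58
        counts = [len(hs.seed_markers(regions["DG"], 9615.0, s)) for s in range(200)]
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 4 * se


class TestSectioning:
    def test_sphere_slab_count(self):
        sphere = hs.RegionSolid("DG", hs.Ellipsoid(semi_axes=(0.05, 0.05, 0.05)))
        animal = hs.AnimalPhantom(
            "s", "Con", {"DG": sphere},
            {"DG": hs.MarkerSet("DG", np.empty((0, 3)), 0.0)},
            {"blood_glucose": 1.0, "plasma_cu": 1.0},
        )
        stack = hs.section_phantom(animal, 0.01)
        assert stack.total_count == 10  # ceil(diameter / t) with aligned start
        assert all(stack.section(i).profile("DG") is not None for i in range(10))

    def test_nonpositive_thickness_rejected(self, control_animal):
        with pytest.raises(ValueError):
            hs.section_phantom(control_animal, 0.0)

    def test_sections_tile_extent_without_gaps(self, control_animal):
        stack = hs.section_phantom(control_animal, 0.010)
        for i in range(stack.total_count - 1):
            lo_next = stack.section(i + 1).z_interval[0]
            assert stack.section(i).z_interval[1] == pytest.approx(lo_next, abs=1e-12)

    @pytest.mark.parametrize("thickness", [0.005, 0.010, 0.007])
    def test_marker_conservation_across_thickness(self, thickness):
        animal = make_animal(nd_dg=1500.0, nd_ca3=800.0, seed=3)
        stack = hs.section_phantom(animal, thickness)
        for region in hs.REGIONS:
            per_slab = sum(
                stack.section(i).markers_in_slab(region).shape[0]
                for i in range(stack.total_count)
            )
            assert per_slab == len(animal.markers[region])

    def test_boundary_marker_goes_to_upper_slab(self):
        solid = hs.RegionSolid("DG", hs.Ellipsoid(semi_axes=(1.0, 1.0, 1.0)))
        # z = 0 sits exactly on the boundary between slab [-t, 0) and [0, t)
        markers = {"DG": hs.MarkerSet("DG", np.array([[0.0, 0.0, 0.0]]), 1.0)}
        stack = hs.SectionStack({"DG": solid}, markers, 0.5, -1.0, 4)
        assert stack.section(2).markers_in_slab("DG").shape[0] == 1
        assert stack.section(1).markers_in_slab("DG").shape[0] == 0

    def test_riemann_sum_converges_to_true_volume(self, control_animal):
        # ~1000 slabs across the DG solid
        extent = np.diff(control_animal.regions["DG"].shape.z_range)[0]
        stack = hs.section_phantom(control_animal, extent / 1000)
        v = hs.riemann_volume(stack, "DG")
        assert abs(v - 2.00) / 2.00 < 0.005


class TestMakeCohort:
    def test_sample_mean_recovers_group_mean(self, default_params):
        # mean of per-group sample means over many seeds stays within 3 SE
        means = []
        for s in range(100):
            cohort = hs.make_cohort(default_params, 10, seed=s, with_markers=False)
            v = [hs.true_volume(a.regions["DG"]) for a in cohort if a.group == "Con"]
            means.append(np.mean(v))
        se = 0.09 / np.sqrt(100 * 10)
        assert abs(np.mean(means) - 2.00) < 3 * se

    def test_zero_sd_is_degenerate(self, default_params):
        p = default_params
        for region in hs.REGIONS:
            for g in hs.GROUPS:
                p.volume[region][g] = (p.volume[region][g][0], 0.0)
                p.density[region][g] = (p.density[region][g][0], 0.0)
        for g in hs.GROUPS:
            p.blood_glucose[g] = (p.blood_glucose[g][0], 0.0)
            p.plasma_cu[g] = (p.plasma_cu[g][0], 0.0)
        cohort = hs.make_cohort(p, 3, seed=1, with_markers=False)
        for a in cohort:
            assert hs.true_volume(a.regions["DG"]) == pytest.approx(
                p.volume["DG"][a.group][0], rel=1e-9
            )
            assert a.covariates["blood_glucose"] == pytest.approx(
                p.blood_glucose[a.group][0]
            )

    def test_copula_hits_zero_correlation_target(self, default_params):
        p = default_params
        p.correlation = np.eye(6)
        cohort = hs.make_cohort(p, 10000, seed=7, with_markers=False)
        t = hs.truth_table([a for a in cohort if a.group == "Con"])
        r = np.corrcoef(t["BG"], t["true_V_DG"])[0, 1]
        assert abs(r) < 0.1

    def test_invalid_inputs_rejected(self, default_params):
        with pytest.raises(ValueError):
            hs.make_cohort(default_params, 0, seed=1)
        bad = default_params
        bad.correlation = np.full((6, 6), 0.99)
        np.fill_diagonal(bad.correlation, 1.0)
        bad.correlation[0, 1] = bad.correlation[1, 0] = -0.99  # impossible jointly
        with pytest.raises(ValueError):
            hs.make_cohort(bad, 2, seed=1)

    def test_cohort_structure(self, default_params):
        cohort = hs.make_cohort(default_params, 2, seed=5, with_markers=False)
        assert len(cohort) == 8
        assert sorted({a.group for a in cohort}) == sorted(hs.GROUPS)


class TestSerialization:
    def test_cohort_json_round_trip(self, default_params):
        cohort = hs.make_cohort(default_params, 1, seed=2)
        back = hs.phantom.cohort_from_json(hs.phantom.cohort_to_json(cohort))
        assert len(back) == len(cohort)
        a, b = cohort[0], back[0]
        assert a.animal_id == b.animal_id
        assert hs.true_volume(a.regions["DG"]) == pytest.approx(
            hs.true_volume(b.regions["DG"])
        )
        np.testing.assert_allclose(a.markers["DG"].points, b.markers["DG"].points)

    def test_stack_json_contains_all_sections(self, control_animal):
        import json

        stack = hs.section_phantom(control_animal, 0.1)
        d = json.loads(hs.phantom.stack_to_json(stack))
        assert d["total_count"] == len(d["sections"]) == stack.total_count
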