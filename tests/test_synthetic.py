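"""Generator: tree growth, pressures, tessellation and rendering."""

import numpy as np
import pytest

from lobulemorph import stats as ST
from lobulemorph import synthetic as Y


def bifurcation_radii(vessels, lobule_radius):
    return np.array([np.linalg.norm(pos) / lobule_radius
                     for pos, n in Y.branch_events(vessels) if n == 2])


class TestVesselTree:
    def test_no_branching_gives_exact_spokes(self):
        p = Y.LobuleParams(n_primary_vessels=6, branch_rate_slope=0.0)
        vessels = Y.build_vessel_tree(p, seed=42)
        assert len(vessels) == 6
        assert Y.branch_events(vessels) == []

    def test_branch_count_rises_linearly_with_radius(self):
        """Bifurcations per ring, counted directly on the tree, rise with R."""
        p = Y.LobuleParams()
        vessels = Y.build_vessel_tree(p, seed=0)
        R = bifurcation_radii(vessels, p.lobule_radius)
        counts, edges = np.histogram(R, bins=np.linspace(0, 1, 11))
        centers = 0.5 * (edges[:-1] + edges[1:])
        fit = ST.fit_linear_ftest(centers, counts)
        assert fit.slope > 0

    def test_same_seed_reproduces_vertices(self):
        v1 = Y.build_vessel_tree(seed=7)
        v2 = Y.build_vessel_tree(seed=7)
        assert len(v1) == len(v2)
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a.centerline, b.centerline)
            np.testing.assert_array_equal(a.radius_profile, b.radius_profile)

    def test_radius_taper_endpoints(self):
        p = Y.LobuleParams()
        vessels = Y.build_vessel_tree(p, seed=0)
        prox = [v.radius_profile[0] for v in vessels if v.parent is None]
        tip_rad = [v.radius_profile[-1] for v in vessels
                   if np.linalg.norm(v.centerline[-1]) > 0.99 * p.lobule_radius]
        assert np.allclose(prox, p.radius_cv, atol=0.2)
        assert np.allclose(tip_rad, p.radius_periphery, atol=0.2)

    @pytest.mark.parametrize("bad", [
        dict(radius_cv=-1.0), dict(radius_periphery=0.0),
        dict(lobule_radius=-5.0), dict(branch_rate_slope=-1.0),
        dict(radius_cv=1.0, radius_periphery=2.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            Y.build_vessel_tree(Y.LobuleParams(**bad), seed=0)


class TestPressures:
    def test_uniform_when_ratio_is_one(self):
        vessels = Y.build_vessel_tree(seed=1)
        out = Y.assign_pressures(vessels, p_periphery=2.0, cv_ratio=1.0,
                                 lobule_radius=500.0, cv_radius=40.0)
        for v in out:
            np.testing.assert_allclose(v.internal_pressure, 2.0)

    def test_root_pressure_is_cv_ratio(self):
        """Pericentral/peripheral pressure ratio 0.7 lands at the tree root."""
        vessels = Y.build_vessel_tree(seed=1)
        out = Y.assign_pressures(vessels, p_periphery=1.0, cv_ratio=0.7,
                                 lobule_radius=500.0, cv_radius=40.0)
        roots = [v for v in out if v.parent is None]
        assert all(np.isclose(v.internal_pressure[0], 0.7) for v in roots)
        # global minimum equals the root (CV) pressure: monotone along paths
        pmin = min(v.internal_pressure.min() for v in out)
        assert np.isclose(pmin, 0.7)
        # tips at the boundary carry the peripheral pressure
        ptip = max(v.internal_pressure.max() for v in out)
        assert np.isclose(ptip, 1.0)

    def test_reversed_gradient_rejected(self):
        vessels = Y.build_vessel_tree(seed=1)
        with pytest.raises(ValueError):
            Y.assign_pressures(vessels, p_periphery=1.0, cv_ratio=1.2)


class TestTessellation:
    def test_equal_targets_give_no_radial_trend(self):
        p = Y.LobuleParams(mean_area_cv=180.0, mean_area_periphery=180.0)
        lob = Y.make_lobule(p, seed=2)
        _, gt = Y.render(lob, noise_sd=0.0)
        areas = Y.cell_areas(lob, gt.masks)
        R = np.linalg.norm(lob.nuclei, axis=1) / p.lobule_radius
        sel = (R > 0.15) & (R < 0.9)
        fit = ST.fit_linear_ftest(R[sel], areas[sel])
        # slope confidence interval includes zero
        assert fit.p_value > 0.05

    def test_zone_cell_area_ratio_matches_targets(self, ten_lobules):
        """Inner/outer mean cell area recovers 170.5/190.1 ~ 0.90 +- 0.05."""
        ratios = []
        for lob, _, gt in ten_lobules[:5]:
            areas = Y.cell_areas(lob, gt.masks)
            R = np.linalg.norm(lob.nuclei, axis=1) / lob.lobule_radius
            pv = (R >= 0.10) & (R <= 0.35)
            pp = (R >= 0.60) & (R <= 0.80)
            ratios.append(areas[pv].mean() / areas[pp].mean())
        assert abs(np.mean(ratios) - 170.5 / 190.1) < 0.05

    def test_one_nucleus_per_cell_and_no_vessel_overlap(self, noise_free_case):
        lob, _, gt = noise_free_case
        # nuclei never intrude into vessel lumens
        assert not np.any(gt.masks.nucleus & gt.masks.vessel)
        # nearest-seed regions tile the non-vessel tissue: every pixel of
        # cytoplasm+nucleus is owned by exactly one nucleus
        areas = Y.cell_areas(lob, gt.masks)
        tissue_px = (gt.masks.hepatocyte | gt.masks.nucleus).sum()
        assert areas.sum() == tissue_px * lob.scale ** 2

    def test_same_seed_reproduces_tessellation(self):
        lob1 = Y.make_lobule(seed=5)
        lob2 = Y.make_lobule(seed=5)
        np.testing.assert_array_equal(lob1.nuclei, lob2.nuclei)


class TestRender:
    def test_noise_free_histogram_is_four_levels(self, noise_free_case):
        lob, img, _ = noise_free_case
        p = lob.params
        levels = {p.intensity_background, p.intensity_vessel,
                  p.intensity_hepatocyte, p.intensity_nucleus}
        assert set(np.unique(img)) == levels

    def test_alpha_profile_is_pixelcounted_vessel_fraction(self, noise_free_case):
        lob, _, gt = noise_free_case
        p = lob.params
        off = p.lobule_radius + p.margin
        n = gt.masks.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        R = np.hypot(yy * p.scale - off, xx * p.scale - off) / p.lobule_radius
        edges = np.linspace(0.0, 1.0, p.n_bins + 1)
        for b in range(p.n_bins):
            ring = (R >= edges[b]) & (R < edges[b + 1])
            assert gt.alpha_profile[b] == gt.masks.vessel[ring].sum() / ring.sum()

    def test_masks_partition_the_image(self, noise_free_case):
        _, _, gt = noise_free_case
        m = gt.masks
        assert not np.any(m.vessel & m.hepatocyte)
        assert not np.any(m.vessel & m.nucleus)
        assert not np.any(m.hepatocyte & m.nucleus)
        total = m.vessel.sum() + m.hepatocyte.sum() + m.nucleus.sum()
        background = m.vessel.size - total
        assert total + background == m.vessel.size

    def test_negative_noise_rejected(self):
        lob = Y.make_lobule(seed=0)
        with pytest.raises(ValueError):
            Y.render(lob, noise_sd=-1.0)

    def test_render_is_bit_deterministic(self):
        _, i1, g1 = Y.simulate_lobule(seed=3)
        _, i2, g2 = Y.simulate_lobule(seed=3)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(g1.masks.as_labels(), g2.masks.as_labels())
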