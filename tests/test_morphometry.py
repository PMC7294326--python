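"""Radial frames, profiles, zonal summaries and the cross-species folds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobulemorph import morphometry as M
from lobulemorph import segmentation as S


def square_frame(half=10.0):
    poly = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    return M.LobuleFrame(cv_centroid=(0.0, 0.0), boundary=poly)


class TestNormalizeRadius:
    def test_centroid_maps_to_zero(self):
        frame = M.LobuleFrame(cv_centroid=(5.0, 5.0), boundary=50.0)
        assert M.normalize_radius((5.0, 5.0), frame) == 0.0

    def test_scalar_mode_boundary_is_one(self):
        frame = M.LobuleFrame(cv_centroid=(0.0, 0.0), boundary=50.0)
        assert np.isclose(M.normalize_radius((50.0, 0.0), frame), 1.0)

    def test_square_corner_and_edge_differ(self):
        """Equal Euclidean distance, different R against a square boundary."""
        frame = square_frame(half=10.0)
        d = 5.0
        r_edge = M.normalize_radius((d, 0.0), frame)
        r_corner = M.normalize_radius((d / np.sqrt(2), d / np.sqrt(2)), frame)
        assert np.isclose(r_edge, d / 10.0)                    # boundary at 10
        assert np.isclose(r_corner, d / (10.0 * np.sqrt(2)))   # at 10*sqrt(2)
        assert r_edge != r_corner

    def test_centroid_outside_polygon_rejected(self):
        poly = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        with pytest.raises(ValueError):
            M.LobuleFrame(cv_centroid=(10.0, 10.0), boundary=poly)


def toy_masks(n=40, scale=1.0):
    hep = np.ones((n, n), dtype=bool)
    empty = np.zeros_like(hep)
    return S.ClassMasks(vessel=empty.copy(), hepatocyte=hep,
                        nucleus=empty.copy(), scale=scale)


class TestRadialProfile:
    def test_all_hepatocyte_masks(self):
        masks = toy_masks(40)
        frame = M.LobuleFrame(cv_centroid=(20.0, 20.0), boundary=15.0)
        prof = M.radial_profile([], [], masks, frame, n_bins=5)
        np.testing.assert_allclose(prof.alpha, 0.0)
        np.testing.assert_allclose(prof.hep_fraction, 1.0)
        # no branch points / nuclei anywhere: per-count metrics are missing
        assert np.all(np.isnan(prof.vessel_area_per_branch))
        assert np.all(np.isnan(prof.hep_area_per_nucleus))

    def test_profile_matches_ground_truth_alpha(self, ten_lobules,
                                                ten_gt_profiles):
        for (_, _, gt), prof in zip(ten_lobules[:3], ten_gt_profiles[:3]):
            np.testing.assert_array_equal(prof.alpha, gt.alpha_profile)

    def test_ring_areas_partition_the_disk(self, noise_free_case,
                                           ten_gt_profiles):
        lob, _, gt = noise_free_case
        prof = ten_gt_profiles[0]
        n = gt.masks.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        off = lob.cv_centroid[0]
        R = np.hypot(yy - off, xx - off) / lob.lobule_radius
        assert prof.ring_area.sum() == (R < 1.0).sum() * lob.scale ** 2

    def test_too_few_bins_rejected(self):
        masks = toy_masks(10)
        frame = M.LobuleFrame(cv_centroid=(5.0, 5.0), boundary=4.0)
        with pytest.raises(ValueError):
            M.radial_profile([], [], masks, frame, n_bins=1)


class TestZonalSummary:
    def make_profile(self, alpha_pv, alpha_pp):
        """Tiny synthetic profile with controlled PV/PP alpha values."""
        edges = np.linspace(0, 1, 11)
        alpha = np.full(10, np.nan)
        alpha[1:4] = alpha_pv
        alpha[6:8] = alpha_pp
        ones = np.ones(10)
        return M.RadialProfile(bin_edges=edges, ring_area=ones,
                               alpha=alpha, hep_fraction=ones * 0.8,
                               branch_count=ones, nucleus_count=ones,
                               vessel_area_per_branch=ones,
                               hep_area_per_nucleus=ones)

    def test_reported_sinusoid_fold(self):
        """PP 10.1% vs PV 19.3% vessel area gives the reported ~1.9 fold."""
        prof = self.make_profile(alpha_pv=19.3, alpha_pp=10.1)
        z = {s.metric: s for s in M.zonal_summary(prof)}["alpha"]
        assert np.isclose(z.fold, 19.3 / 10.1)
        assert M.table1_folds(10.1, 19.3, rounding=1) == 1.9

    def test_equal_zones_give_unit_fold(self):
        prof = self.make_profile(alpha_pv=0.2, alpha_pp=0.2)
        z = {s.metric: s for s in M.zonal_summary(prof)}["alpha"]
        assert np.isclose(z.fold, 1.0)

    def test_hepatocyte_area_fold(self):
        assert M.table1_folds(190.1, 170.5) == 0.90

    def test_overlapping_zones_rejected(self, ten_gt_profiles):
        with pytest.raises(ValueError):
            M.zonal_summary(ten_gt_profiles[0], pv_range=(0.1, 0.5),
                            pp_range=(0.4, 0.8))

    def test_empty_zone_rejected(self, ten_gt_profiles):
        with pytest.raises(ValueError):
            M.zonal_summary(ten_gt_profiles[0], pv_range=(0.101, 0.102),
                            pp_range=(0.6, 0.8))


class TestTable1:
    @pytest.mark.parametrize("pp,pv,expected", [
        (8.8, 13.7, 1.56),        # mouse sinusoid diameter
        (50767.0, 85155.0, 1.68),  # rat total sinusoidal area
    ])
    def test_reported_rows(self, pp, pv, expected):
        assert M.table1_folds(pp, pv) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 1e5))
    def test_identity_fold(self, x):
        assert M.table1_folds(x, x) == 1.0

    def test_zero_pp_rejected(self):
        with pytest.raises(ZeroDivisionError):
            M.table1_folds(0.0, 1.0)

    def test_report_matching_and_flagged_sets(self):
        df = M.table1_report()
        bad = df[~df.matches_printed]
        assert len(df) == 13
        assert len(bad) == 3
        assert set(zip(bad.species, bad.parameter)) == {
            ("rat", "velocity_mm_s"),
            ("pig", "vessel_area_per_branch_um2"),
            ("pig", "pct_area_sinusoids"),
        }
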